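# GPI-anchor biosynthesis gene panel (reconstruction).
# The PIG family (glycosylphosphatidylinositol anchor biosynthesis) plus the
# transamidase subunit GPAA1 and the post-attachment remodeling PGAP genes.
# The exact membership used in the original microarray analysis is not
# published; pass a custom panel file to substitute an alternative list.
PIGA
PIGB
PIGC
PIGF
PIGG
PIGH
PIGK
PIGL
PIGM
PIGN
PIGO
PIGP
PIGQ
PIGS
PIGT
PIGU
PIGV
PIGW
PIGX
PIGY
PIGZ
GPAA1
PGAP1
PGAP2
PGAP3
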