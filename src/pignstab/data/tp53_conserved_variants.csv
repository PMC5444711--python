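position,ref,alt,region,exon_number,type,aa_change,sift
11031,G,A,exon,2,non-synonymous,p.S9N,neutral
11470,C,G,exon,4,non-synonymous,p.P80R,neutral
12379,C,-,exon,5,frameshift_deletion,p.N131fs,NA
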