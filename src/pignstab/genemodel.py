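"""Gene models: exon/intron structure, CDS, GFF3 and FASTA I/O.

All genomic coordinates are 1-based inclusive on the forward strand of the
reference sequence. Exons are stored in genomic order; transcription order
is derived from the strand. Introns are the gaps between consecutive
exons.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass(frozen=True)
class GeneModel:
    """Exon/CDS structure of a single transcript.

    ``exons`` are (start, end) 1-based inclusive, sorted by genomic
    position and non-overlapping. ``cds`` is the genomic extent of the
    coding sequence (start of the start codon to end of the stop codon,
    forward-strand coordinates regardless of gene strand).
    """

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    exons: tuple[tuple[int, int], ...]
    cds: tuple[int, int]
    transcript_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if len(self.exons) < 1:
            raise ValueError("gene model needs at least one exon")
        for (s, e) in self.exons:
            if s > e:
                raise ValueError(f"exon with start > end: {(s, e)}")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if e1 >= s2:
                raise ValueError("exons overlap or are unsorted")
        if not any(s <= self.cds[0] <= e for s, e in self.exons):
            raise ValueError("CDS start is not inside an exon")
        if not any(s <= self.cds[1] <= e for s, e in self.exons):
            raise ValueError("CDS end is not inside an exon")

    # ---- structure ------------------------------------------------------

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Intron intervals in genomic order (gaps between exons)."""
        return tuple(
            (e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        )

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    def exons_tx(self) -> tuple[tuple[int, int], ...]:
        """Exons in transcription order."""
        return self.exons if self.strand == "+" else self.exons[::-1]

    def intron_tx(self, index: int) -> tuple[int, int]:
        """Genomic interval of the intron with 1-based transcription index."""
        if not 1 <= index <= self.n_introns:
            raise ValueError(
                f"intron index {index} out of range 1..{self.n_introns}"
            )
        introns = self.introns
        return introns[index - 1] if self.strand == "+" else introns[-index]

    def intron_tx_index(self, genomic_intron: tuple[int, int]) -> int:
        """Transcription-order index (1-based) of a genomic intron interval."""
        introns = self.introns
        i = introns.index(genomic_intron)
        return i + 1 if self.strand == "+" else len(introns) - i

    # ---- sequence -------------------------------------------------------

    def spliced_transcript(self, genome: str) -> str:
        """Mature transcript sequence (exons joined, minus strand revcomp)."""
        seq = "".join(genome[s - 1 : e] for s, e in self.exons)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq

    def cds_offset_in_transcript(self) -> int:
        """0-based offset of the CDS start codon in the spliced transcript."""
        target = self.cds[0] if self.strand == "+" else self.cds[1]
        pos = 0
        for s, e in self.exons_tx():
            lo, hi = (s, e)
            if lo <= target <= hi:
                within = (target - lo) if self.strand == "+" else (hi - target)
                return pos + within
            pos += hi - lo + 1
        raise ValueError("CDS start not inside any exon")  # pragma: no cover

    def cds_sequence(self, genome: str) -> str:
        """Spliced CDS sequence, start codon through stop codon."""
        tx = self.spliced_transcript(genome)
        off = self.cds_offset_in_transcript()
        length = sum(
            max(0, min(e, self.cds[1]) - max(s, self.cds[0]) + 1)
            for s, e in self.exons
        )
        return tx[off : off + length]

    def protein(self, genome: str) -> str:
        """Translated protein (stop codon excluded)."""
        cds = self.cds_sequence(genome)
        aa = str(Seq(cds).translate())
        return aa[:-1] if aa.endswith("*") else aa

    def validate_cds(self, genome: str) -> None:
        """Check the spliced CDS is a multiple of 3 and ends at a stop codon."""
        cds = self.cds_sequence(genome)
        if len(cds) % 3 != 0:
            raise ValueError(f"spliced CDS length {len(cds)} is not a multiple of 3")
        aa = str(Seq(cds).translate())
        if not aa.endswith("*"):
            raise ValueError("spliced CDS does not end at a stop codon")
        if "*" in aa[:-1]:
            raise ValueError("spliced CDS contains an internal stop codon")


# ---------------------------------------------------------------------------
# GFF3 / FASTA I/O
# ---------------------------------------------------------------------------


def write_gff3(model: GeneModel, path: str | Path) -> None:
    """Write the gene as GFF3 gene/mRNA/exon/CDS features (1-based inclusive)."""
    gid, tid = model.gene_id, model.transcript_id or f"{model.gene_id}.t1"
    lines = ["##gff-version 3"]

    def feat(ftype: str, start: int, end: int, attrs: str) -> str:
        return "\t".join(
            [model.chrom, "pignstab", ftype, str(start), str(end), ".",
             model.strand, ".", attrs]
        )

    lines.append(feat("gene", *model.span, f"ID={gid}"))
    lines.append(feat("mRNA", *model.span, f"ID={tid};Parent={gid}"))
    for i, (s, e) in enumerate(model.exons, start=1):
        lines.append(feat("exon", s, e, f"ID={tid}.exon{i};Parent={tid}"))
    lines.append(feat("CDS", model.cds[0], model.cds[1], f"ID={tid}.cds;Parent={tid}"))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path, gene_id: str | None = None) -> GeneModel:
    """Read one gene model from a GFF3 file (gene/exon/CDS features)."""
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = list(db.features_of_type("gene"))
    if gene_id is not None:
        genes = [g for g in genes if g.id == gene_id]
    if not genes:
        raise ValueError(f"no gene feature found in {path}")
    gene = genes[0]
    exons = sorted(
        (f.start, f.end)
        for f in db.region(seqid=gene.seqid, start=gene.start, end=gene.end)
        if f.featuretype == "exon"
    )
    cds_feats = [
        f
        for f in db.region(seqid=gene.seqid, start=gene.start, end=gene.end)
        if f.featuretype == "CDS"
    ]
    if not cds_feats:
        raise ValueError(f"gene {gene.id} has no CDS feature")
    cds = (min(f.start for f in cds_feats), max(f.end for f in cds_feats))
    mrnas = [
        f
        for f in db.region(seqid=gene.seqid, start=gene.start, end=gene.end)
        if f.featuretype == "mRNA"
    ]
    tid = mrnas[0].id if mrnas else ""
    return GeneModel(
        gene_id=gene.id,
        chrom=gene.seqid,
        strand=gene.strand,
        exons=tuple(exons),
        cds=cds,
        transcript_id=tid,
    )


def write_fasta(seq: str, name: str, path: str | Path) -> None:
    SeqIO.write([SeqRecord(Seq(seq), id=name, description="")], str(path), "fasta")


def read_fasta(path: str | Path, name: str | None = None) -> str:
    """Read one sequence (by name, or the first record) from a FASTA file."""
    for rec in SeqIO.parse(str(path), "fasta"):
        if name is None or rec.id == name:
            return str(rec.seq).upper()
    raise ValueError(f"sequence {name!r} not found in {path}")
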