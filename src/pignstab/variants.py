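"""Paired variant-profile comparison (e.g. TP53 in leukemic vs non-leukemic cells).

Compares Sanger-derived variant lists of two cell populations from the
same patient: global sequence identity, mutation rate per kbp,
intersection of conserved alterations, coding-consequence classification,
and a two-sample t-test on per-amplicon rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
from Bio import Align
from Bio.Seq import Seq
from scipy import stats

VARIANT_TYPES = (
    "synonymous",
    "non-synonymous",
    "frameshift_deletion",
    "frameshift_insertion",
    "intronic",
)


@dataclass(frozen=True)
class VariantRecord:
    """One sequence alteration on a reference (1-based position).

    ``alt == '-'`` denotes a single-base deletion. ``sift`` is a
    pass-through annotation, never computed here.
    """

    position: int
    ref: str
    alt: str
    region: str = "exon"  # 'exon' or 'intron'
    exon_number: int | None = None
    type: str = ""
    aa_change: str = ""
    sift: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position must be >= 1")
        if self.ref == self.alt:
            raise ValueError("ref and alt are identical")
        if self.alt == "-" and self.type not in ("", "frameshift_deletion", "intronic"):
            raise ValueError("deletion symbol requires frameshift/intronic type")

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.position, self.ref, self.alt)


def _check_unique_positions(profile: list[VariantRecord], name: str) -> None:
    seen: set[int] = set()
    for v in profile:
        if v.position in seen:
            raise ValueError(f"duplicate position {v.position} in profile {name}")
        seen.add(v.position)


def sequence_identity(query: str, reference: str) -> float:
    """Percent identity from a global pairwise alignment.

    Scoring: match +1, mismatch 0, linear gap -1 (alignment only);
    identity = matches / alignment columns x 100, gaps counting as
    non-matches.
    """
    if not query or not reference:
        raise ValueError("sequences must be non-empty")
    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=1,
        mismatch_score=0,
        open_gap_score=-1,
        extend_gap_score=-1,
    )
    aln = aligner.align(query.upper(), reference.upper())[0]
    counts = aln.counts()
    return 100.0 * counts.identities / aln.length


def mutation_rate_per_kbp(n_alterations: int, region_length_bp: int) -> float:
    """Alterations per kilobase: 1000 * n / L."""
    if region_length_bp <= 0:
        raise ValueError("region length must be > 0")
    if n_alterations < 0:
        raise ValueError("alteration count must be >= 0")
    return 1000.0 * n_alterations / region_length_bp


def intersect_profiles(
    a: list[VariantRecord], b: list[VariantRecord]
) -> list[VariantRecord]:
    """Alterations conserved between two profiles.

    Records match on exact (position, ref, alt); output is sorted by
    position. Representation-fuzzy indel matching is deliberately not
    attempted (profiles are Sanger-derived point events).
    """
    _check_unique_positions(a, "a")
    _check_unique_positions(b, "b")
    keys_b = {v.key for v in b}
    return sorted((v for v in a if v.key in keys_b), key=lambda v: v.position)


def classify_coding_change(
    v: VariantRecord, cds_sequence: str, cds_map: dict[int, int]
) -> VariantRecord:
    """Classify a variant's coding consequence by mutate-and-translate.

    ``cds_map`` maps genomic position -> 1-based CDS position. A
    substitution compares the reference and mutated codon translations;
    a single-base deletion is a frameshift. Returns a copy of ``v`` with
    ``type`` and ``aa_change`` filled in; positions outside the CDS are
    classified intronic/non-coding.
    """
    cds_pos = cds_map.get(v.position)
    if cds_pos is None:
        return VariantRecord(
            v.position, v.ref, v.alt, region="intron",
            exon_number=v.exon_number, type="intronic",
            aa_change="", sift=v.sift,
        )
    if not 1 <= cds_pos <= len(cds_sequence):
        raise ValueError(f"cds_map position {cds_pos} outside CDS")
    if cds_sequence[cds_pos - 1] != v.ref:
        raise ValueError(
            f"reference mismatch at CDS position {cds_pos}: "
            f"CDS has {cds_sequence[cds_pos - 1]}, variant says {v.ref}"
        )
    codon_number = math.ceil(cds_pos / 3)
    codon_start = (codon_number - 1) * 3
    ref_codon = cds_sequence[codon_start : codon_start + 3]
    ref_aa = str(Seq(ref_codon).translate())

    if v.alt == "-":
        vtype = "frameshift_deletion"
        aa_change = f"p.{ref_aa}{codon_number}fs"
    else:
        offset = (cds_pos - 1) % 3
        alt_codon = ref_codon[:offset] + v.alt + ref_codon[offset + 1 :]
        alt_aa = str(Seq(alt_codon).translate())
        if alt_aa == ref_aa:
            vtype = "synonymous"
            aa_change = f"p.{ref_aa}{codon_number}="
        else:
            vtype = "non-synonymous"
            aa_change = f"p.{ref_aa}{codon_number}{alt_aa}"
    return VariantRecord(
        v.position, v.ref, v.alt, region="exon",
        exon_number=v.exon_number, type=vtype,
        aa_change=aa_change, sift=v.sift,
    )


def compare_rates(
    group_a: list[float], group_b: list[float]
) -> tuple[float, float]:
    """Two-sample pooled-variance t-test on per-amplicon mutation rates."""
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs n >= 2")
    import numpy as np

    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if np.allclose(a.mean(), b.mean()):
            return 0.0, 1.0
        raise ValueError("zero pooled variance with unequal means: t undefined")
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class ProfileSummary:
    n_alterations_total: int
    n_coding: int
    region_length_bp: int
    identity_percent: float | None
    rate_per_kbp: float


def summarize_profile(
    profile: list[VariantRecord],
    region_length_bp: int,
    identity_percent: float | None = None,
) -> ProfileSummary:
    n_total = len(profile)
    n_coding = sum(1 for v in profile if v.region == "exon")
    return ProfileSummary(
        n_alterations_total=n_total,
        n_coding=n_coding,
        region_length_bp=region_length_bp,
        identity_percent=identity_percent,
        rate_per_kbp=mutation_rate_per_kbp(n_total, region_length_bp),
    )


# ---- I/O -----------------------------------------------------------------

_CSV_COLUMNS = ["position", "ref", "alt", "region", "exon_number", "type", "aa_change", "sift"]


def read_variants_csv(path: str | Path) -> list[VariantRecord]:
    df = pd.read_csv(path, dtype={"ref": str, "alt": str})
    out = []
    for r in df.itertuples():
        exon_number = getattr(r, "exon_number", None)
        if pd.isna(exon_number):
            exon_number = None
        out.append(
            VariantRecord(
                position=int(r.position),
                ref=str(r.ref),
                alt=str(r.alt),
                region=str(getattr(r, "region", "exon")),
                exon_number=None if exon_number is None else int(exon_number),
                type=str(getattr(r, "type", "") or ""),
                aa_change=str(getattr(r, "aa_change", "") or ""),
                sift=str(getattr(r, "sift", "") or ""),
            )
        )
    return out


def write_variants_csv(profile: list[VariantRecord], path: str | Path) -> None:
    pd.DataFrame([
        {c: getattr(v, c) for c in _CSV_COLUMNS} for v in profile
    ]).to_csv(path, index=False)


def read_variants_vcf(path: str | Path) -> list[VariantRecord]:
    """Minimal VCF import: CHROM POS REF ALT; '<DEL>'/'-' ALT becomes a deletion."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 5:
            raise ValueError(f"malformed VCF line: {line!r}")
        pos, ref, alt = int(fields[1]), fields[3], fields[4]
        if alt in ("<DEL>", "-"):
            alt = "-"
        out.append(VariantRecord(position=pos, ref=ref, alt=alt))
    return out


def conserved_tp53_variants() -> list[VariantRecord]:
    """The packaged conserved TP53 alterations (leukemic and non-leukemic)."""
    ref = resources.files("pignstab.data") / "tp53_conserved_variants.csv"
    with resources.as_file(ref) as path:
        return read_variants_csv(path)
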