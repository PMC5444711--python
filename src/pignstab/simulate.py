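"""Synthetic data generators for every pipeline stage.

Each generator emulates the statistical structure one analysis stage
assumes, so the whole pipeline is testable without external downloads:

* :func:`gen_expression_cohort` — a latent-factor expression cohort: each
  sample carries a latent "instability" factor ``z`` (subtype-shifted
  standard normal); panel genes load on ``z`` with per-gene loadings
  drawn uniform in [0.5, 1] and a panel-level sign; background genes are
  pure noise. This is the simplest structure that reproduces both a
  subtype-dependent panel heat map and a signed cross-panel PC1
  correlation.
* :func:`gen_gene_model` — a toy multi-exon gene with canonical GT..AG
  splice sites and a valid, internally stop-free CDS.
* :func:`gen_junction_file` — annotated exon-exon junctions plus novel
  partial-retention junctions for requested events.
* :func:`gen_cfc_counts` — binomial colony counts for selective and
  control plates.
* :func:`gen_variant_profiles` — paired variant profiles as
  shared-plus-private unions.

All randomness flows from the explicit ``seed`` of each spec; identical
spec + seed give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .cohort import (
    SUBTYPES,
    ExpressionCohort,
    GenePanel,
    cin70_panel,
    gpi_panel,
    overlapping_genes,
)
from .genemodel import GeneModel
from .gpi import CFCAssay, CFCReplicate
from .junctions import JunctionRecord
from .retention import RetentionEvent
from .variants import VariantRecord, conserved_tp53_variants

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}


# ---------------------------------------------------------------------------
# Expression cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic expression cohort.

    ``n_per_group`` maps subtype label -> sample count; ``latent_effect``
    maps subtype -> shift of the latent instability factor;
    ``panel_loading_sign`` maps panel name -> +1/-1 loading sign.
    """

    n_per_group: Mapping[str, int]
    latent_effect: Mapping[str, float]
    panel_loading_sign: Mapping[str, int]
    noise_sd: float = 1.0
    n_background_genes: int = 100
    baseline_mean: float = 8.0  # log2-scale expression baseline
    seed: int = 0
    subtype_labels: tuple[str, ...] = SUBTYPES

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        for label in self.subtype_labels:
            if self.n_per_group.get(label, 0) < 2:
                raise ValueError(f"need >= 2 samples for subtype {label!r}")
        for name, sign in self.panel_loading_sign.items():
            if sign not in (+1, -1):
                raise ValueError(f"panel sign for {name!r} must be +1 or -1")
        if self.n_background_genes < 0:
            raise ValueError("n_background_genes must be >= 0")


def gen_expression_cohort(
    spec: CohortSpec, panels: Sequence[GenePanel]
) -> ExpressionCohort:
    """Generate a log2-scale gene-by-sample cohort with latent structure.

    Per sample: ``z = latent_effect[subtype] + N(0, 1)``. Panel gene *i*
    of panel *P*: ``mu_i + sign(P) * lambda_i * z + N(0, noise_sd)`` with
    ``lambda_i ~ U(0.5, 1)``. Background genes are ``mu_i + N(0, noise_sd)``.
    """
    shared = overlapping_genes(panels)
    if shared:
        raise ValueError(f"panels overlap on gene(s): {shared[:5]}")
    for p in panels:
        if p.name not in spec.panel_loading_sign:
            raise ValueError(f"no loading sign given for panel {p.name!r}")

    rng = np.random.default_rng(spec.seed)
    labels: list[str] = []
    for subtype in spec.subtype_labels:
        labels.extend([subtype] * spec.n_per_group[subtype])
    n = len(labels)
    samples = [f"S{i + 1:03d}" for i in range(n)]

    shifts = np.array([spec.latent_effect.get(s, 0.0) for s in labels])
    z = shifts + rng.standard_normal(n)

    blocks: list[np.ndarray] = []
    gene_names: list[str] = []
    loadings: dict[str, float] = {}
    for panel in panels:
        p = len(panel)
        lam = rng.uniform(0.5, 1.0, size=p)
        mu = spec.baseline_mean + rng.standard_normal(p)
        sign = spec.panel_loading_sign[panel.name]
        expr = (
            mu[:, None]
            + sign * lam[:, None] * z[None, :]
            + rng.normal(0.0, spec.noise_sd, size=(p, n))
        )
        blocks.append(expr)
        gene_names.extend(panel.genes)
        loadings.update(dict(zip(panel.genes, lam)))
    if spec.n_background_genes:
        mu = spec.baseline_mean + rng.standard_normal(spec.n_background_genes)
        expr = mu[:, None] + rng.normal(
            0.0, spec.noise_sd, size=(spec.n_background_genes, n)
        )
        blocks.append(expr)
        gene_names.extend(f"BG{i + 1:04d}" for i in range(spec.n_background_genes))

    matrix = pd.DataFrame(np.vstack(blocks), index=gene_names, columns=samples)
    cohort = ExpressionCohort(matrix, pd.Series(labels, index=samples, name="subtype"))
    cohort.latent_factor = pd.Series(z, index=samples)  # type: ignore[attr-defined]
    cohort.loadings = pd.Series(loadings)  # type: ignore[attr-defined]
    return cohort


# -- the calibrated cohort preset -------------------------------------------

#: Group sizes of the emulated microarray cohort: 11 normal controls,
#: 18 RA, 19 RARS, and 18 RAEB1/2 patients (split evenly), n = 66.
PAPERLIKE_GROUP_SIZES: dict[str, int] = {
    "Control": 11,
    "RA": 18,
    "RARS": 19,
    "RAEB1": 9,
    "RAEB2": 9,
}

#: Latent-factor shifts by subtype: instability rises with risk stratum.
PAPERLIKE_LATENT_EFFECT: dict[str, float] = {
    "Control": 0.0,
    "RA": 0.8,
    "RARS": 0.8,
    "RAEB1": 3.0,
    "RAEB2": 3.0,
}

#: Noise level calibrated by a pre-build sweep (200 replicates per
#: candidate) so the mean cross-panel PC1 Pearson r at n = 66 matches the
#: target below. See docs/methods.md.
PAPERLIKE_NOISE_SD = 5.75

#: Calibration target for the mean cross-panel correlation.
PAPERLIKE_TARGET_R = -0.41


def paperlike_cohort_spec(seed: int = 0) -> CohortSpec:
    """The calibrated 66-sample cohort preset (see module docstring)."""
    return CohortSpec(
        n_per_group=PAPERLIKE_GROUP_SIZES,
        latent_effect=PAPERLIKE_LATENT_EFFECT,
        panel_loading_sign={"CIN70": +1, "GPI": -1},
        noise_sd=PAPERLIKE_NOISE_SD,
        n_background_genes=100,
        seed=seed,
    )


def paperlike_panels() -> tuple[GenePanel, GenePanel]:
    """The packaged CIN70 and GPI panels used by the preset."""
    return cin70_panel(), gpi_panel()


# ---------------------------------------------------------------------------
# Toy gene models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ToyGeneSpec:
    exon_lengths: tuple[int, ...]
    intron_lengths: tuple[int, ...]
    strand: str = "+"
    cds_start_offset: int = 0
    gc_fraction: float = 0.5
    seed: int = 0
    gene_id: str = "toygene"
    chrom: str = "chrS"

    def __post_init__(self) -> None:
        if len(self.exon_lengths) < 2:
            raise ValueError("need >= 2 exons")
        if len(self.intron_lengths) != len(self.exon_lengths) - 1:
            raise ValueError("need exactly one fewer intron than exons")
        if any(l < 1 for l in self.exon_lengths + self.intron_lengths):
            raise ValueError("all lengths must be >= 1")
        if any(l < 4 for l in self.intron_lengths):
            raise ValueError("introns must be >= 4 nt to fit GT..AG")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")
        if not 0 <= self.gc_fraction <= 1:
            raise ValueError("gc_fraction must be in [0, 1]")
        if not 0 <= self.cds_start_offset < self.exon_lengths[0]:
            raise ValueError("cds_start_offset must fall inside the first exon")


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=n, p=p))


def _nonstop_codons(rng: np.random.Generator, n: int) -> str:
    """n random sense codons (no TAA/TAG/TGA)."""
    out = []
    while len(out) < n:
        codon = "".join(rng.choice(_BASES, size=3))
        if codon not in _STOPS:
            out.append(codon)
    return "".join(out)


def gen_gene_model(spec: ToyGeneSpec) -> tuple[GeneModel, str]:
    """Generate a toy gene model and its genomic (forward) sequence.

    The sequence is built in transcription orientation — exons of random
    composition, introns written as ``GT`` + C/G interior + ``AG`` so any
    retained fragment is free of in-frame stop codons — then mirrored to
    the forward strand for minus-strand genes. The CDS starts ``ATG`` at
    ``cds_start_offset`` nt into the first exon and ends at a generated
    in-frame ``TAA`` in the last exon; the annotated CDS translates with
    no internal stop by construction.
    """
    rng = np.random.default_rng(spec.seed)
    exon_seqs = [_random_bases(rng, l, spec.gc_fraction) for l in spec.exon_lengths]
    intron_seqs = [
        "GT" + "".join(rng.choice(["C", "G"], size=l - 4)) + "AG"
        for l in spec.intron_lengths
    ]

    # CDS placement on the spliced transcript (transcription coordinates)
    spliced_len = sum(spec.exon_lengths)
    cds_start = spec.cds_start_offset  # 0-based in transcript
    avail = spliced_len - cds_start
    cds_len = avail - (avail % 3)
    last_exon_start_tx = spliced_len - spec.exon_lengths[-1]
    # stop codon must lie fully inside the last exon
    if cds_len < 6 or cds_start + cds_len - 3 < last_exon_start_tx:
        raise ValueError("CDS cannot be placed: exons too short")
    coding = "ATG" + _nonstop_codons(rng, cds_len // 3 - 2) + "TAA"

    # write CDS back into exon sequences via the spliced->exon map
    spliced = list("".join(exon_seqs))
    spliced[cds_start : cds_start + cds_len] = list(coding)
    rebuilt, pos = [], 0
    for l in spec.exon_lengths:
        rebuilt.append("".join(spliced[pos : pos + l]))
        pos += l

    # assemble transcription-oriented genomic sequence and coordinates
    tx_seq_parts: list[str] = []
    exon_coords_tx: list[tuple[int, int]] = []
    cursor = 1
    for i, ex in enumerate(rebuilt):
        exon_coords_tx.append((cursor, cursor + len(ex) - 1))
        tx_seq_parts.append(ex)
        cursor += len(ex)
        if i < len(intron_seqs):
            tx_seq_parts.append(intron_seqs[i])
            cursor += len(intron_seqs[i])
    tx_seq = "".join(tx_seq_parts)
    total = len(tx_seq)

    # transcript position of CDS end (1-based, transcription coords)
    def tx_to_genomic_txstrand(tpos0: int) -> int:
        """0-based spliced position -> 1-based tx-oriented genomic position."""
        remaining = tpos0
        for (s, e), l in zip(exon_coords_tx, spec.exon_lengths):
            if remaining < l:
                return s + remaining
            remaining -= l
        raise IndexError(tpos0)

    cds_g_start_tx = tx_to_genomic_txstrand(cds_start)
    cds_g_end_tx = tx_to_genomic_txstrand(cds_start + cds_len - 1)

    if spec.strand == "+":
        forward = tx_seq
        exons = tuple(exon_coords_tx)
        cds = (cds_g_start_tx, cds_g_end_tx)
    else:
        forward = str(Seq(tx_seq).reverse_complement())
        mirror = lambda p: total - p + 1
        exons = tuple(
            sorted((mirror(e), mirror(s)) for s, e in exon_coords_tx)
        )
        cds = (mirror(cds_g_end_tx), mirror(cds_g_start_tx))

    model = GeneModel(
        gene_id=spec.gene_id,
        chrom=spec.chrom,
        strand=spec.strand,
        exons=exons,
        cds=cds,
        transcript_id=f"{spec.gene_id}.t1",
    )
    model.validate_cds(forward)
    return model, forward


# ---------------------------------------------------------------------------
# Junction files
# ---------------------------------------------------------------------------


def junction_for_event(model: GeneModel, event: RetentionEvent) -> JunctionRecord:
    """The novel splice junction implied by a partial retention event."""
    gstart, gend = model.intron_tx(event.intron_index)
    intron_len = gend - gstart + 1
    if event.fragment_length >= intron_len:
        raise ValueError(
            f"fragment length {event.fragment_length} >= intron length {intron_len}"
        )
    # which genomic end of the intron carries the fragment?
    at_genomic_start = (event.retained_end == "5prime") == (model.strand == "+")
    if at_genomic_start:
        donor = gstart + event.fragment_length - 1
        # acceptor = start of the genomically-following exon
        acceptor = gend + 1
    else:
        donor = gstart - 1
        acceptor = gend - event.fragment_length + 1
    return JunctionRecord(
        chrom=model.chrom,
        donor=donor,
        acceptor=acceptor,
        strand=model.strand,
        unique_reads=event.supporting_reads,
        dialect="",
    )


def annotated_junctions(model: GeneModel, reads: int = 50) -> list[JunctionRecord]:
    """One annotated exon-exon junction per intron."""
    return [
        JunctionRecord(
            chrom=model.chrom,
            donor=s - 1,
            acceptor=e + 1,
            strand=model.strand,
            unique_reads=reads,
            dialect="",
        )
        for s, e in model.introns
    ]


def gen_junction_file(
    model: GeneModel,
    events: Sequence[RetentionEvent],
    reads_per_event: int = 10,
    include_annotated: bool = True,
    annotated_reads: int = 50,
) -> list[JunctionRecord]:
    """Junction records for a gene: annotated junctions plus event junctions.

    Each event yields one novel junction whose internal endpoint lies
    ``fragment_length`` nt inside the retained intron; its read count is
    ``reads_per_event`` (an event's own ``supporting_reads`` wins if set).
    """
    out: list[JunctionRecord] = []
    if include_annotated:
        out.extend(annotated_junctions(model, reads=annotated_reads))
    for ev in events:
        reads = ev.supporting_reads or reads_per_event
        ev = replace(ev, supporting_reads=reads)
        out.append(junction_for_event(model, ev))
    return out


def make_retention_event(
    model: GeneModel,
    intron_index: int,
    fragment_length: int,
    retained_end: str = "5prime",
    supporting_reads: int = 0,
) -> RetentionEvent:
    """Construct a retention event with its genomic fragment interval."""
    gstart, gend = model.intron_tx(intron_index)
    if fragment_length >= gend - gstart + 1:
        raise ValueError("fragment length >= intron length")
    at_genomic_start = (retained_end == "5prime") == (model.strand == "+")
    if at_genomic_start:
        fragment = (gstart, gstart + fragment_length - 1)
    else:
        fragment = (gend - fragment_length + 1, gend)
    return RetentionEvent(
        intron_index=intron_index,
        retained_end=retained_end,
        fragment_length=fragment_length,
        fragment=fragment,
        supporting_reads=supporting_reads,
    )


# ---------------------------------------------------------------------------
# CFC colony counts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CFCSpec:
    true_frequency: float
    cells_plated_selective: int = 1_000_000
    cells_plated_control: int = 2_000
    control_plating_efficiency: float = 0.1
    replicates: int = 3
    population: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.true_frequency <= 1:
            raise ValueError("true_frequency must be in [0, 1]")
        if not 0 < self.control_plating_efficiency <= 1:
            raise ValueError("control_plating_efficiency must be in (0, 1]")
        if min(self.cells_plated_selective, self.cells_plated_control, self.replicates) < 1:
            raise ValueError("all counts must be >= 1")


def gen_cfc_counts(spec: CFCSpec) -> CFCAssay:
    """Binomial colony counts: selective plates select the deficient fraction."""
    rng = np.random.default_rng(spec.seed)
    reps = []
    for _ in range(spec.replicates):
        sel = rng.binomial(
            spec.cells_plated_selective,
            spec.true_frequency * spec.control_plating_efficiency,
        )
        ctrl = rng.binomial(spec.cells_plated_control, spec.control_plating_efficiency)
        reps.append(
            CFCReplicate(
                cells_plated_selective=spec.cells_plated_selective,
                colonies_selective=int(sel),
                cells_plated_control=spec.cells_plated_control,
                colonies_control=int(ctrl),
            )
        )
    return CFCAssay(spec.population, reps)


# ---------------------------------------------------------------------------
# Paired variant profiles
# ---------------------------------------------------------------------------

#: Default region: ~2,300 bp spanning the sequenced exons and flanking
#: introns of the comparison gene.
DEFAULT_REGION_LENGTH_BP = 2300


def gen_variant_profiles(
    shared: Sequence[VariantRecord] | None = None,
    private_a: Sequence[VariantRecord] = (),
    private_b: Sequence[VariantRecord] = (),
    region_length_bp: int = DEFAULT_REGION_LENGTH_BP,
    seed: int = 0,
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Paired profiles as shared ∪ private unions, sorted by position.

    ``shared`` defaults to the packaged conserved TP53 alterations.
    """
    if shared is None:
        shared = conserved_tp53_variants()
    profiles = []
    for name, private in (("a", private_a), ("b", private_b)):
        prof = sorted([*shared, *private], key=lambda v: v.position)
        seen: set[int] = set()
        for v in prof:
            if v.position in seen:
                raise ValueError(f"duplicate position {v.position} in profile {name}")
            seen.add(v.position)
        profiles.append(prof)
    return profiles[0], profiles[1]


def gen_random_private_variants(
    n: int,
    region_start: int,
    region_length_bp: int,
    exclude_positions: Sequence[int] = (),
    exon_fraction: float = 0.6,
    seed: int = 0,
) -> list[VariantRecord]:
    """n random substitution variants inside a region, avoiding given positions."""
    rng = np.random.default_rng(seed)
    taken = set(exclude_positions)
    out: list[VariantRecord] = []
    while len(out) < n:
        pos = int(rng.integers(region_start, region_start + region_length_bp))
        if pos in taken:
            continue
        taken.add(pos)
        ref, alt = rng.choice(_BASES, size=2, replace=False)
        region = "exon" if rng.random() < exon_fraction else "intron"
        out.append(VariantRecord(position=pos, ref=str(ref), alt=str(alt), region=region))
    return sorted(out, key=lambda v: v.position)
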