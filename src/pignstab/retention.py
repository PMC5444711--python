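"""Partial intron-retention detection and consequence prediction.

A partial intron retention leaves a splice junction with one endpoint at
an annotated exon boundary and the other strictly inside the adjacent
intron: the transcript keeps a fragment of the intron abutting one of its
splice sites. Retention of a fragment whose length is not a multiple of
three shifts the reading frame, typically introducing a premature
termination codon (PTC) and a truncated protein; a PTC far enough
upstream of the last exon-exon junction additionally marks the transcript
as a likely nonsense-mediated-decay (NMD) substrate (50-nt rule).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from Bio.Seq import Seq
from Bio.SeqUtils import molecular_weight

from .genemodel import GeneModel
from .junctions import JunctionRecord

WATER_DA = 18.0153
NMD_RULE_NT = 50

JUNCTION_CLASSES = (
    "annotated",
    "partial_retention_5prime",
    "partial_retention_3prime",
    "exon_skip",
    "intronic",
    "other",
)


@dataclass(frozen=True)
class RetentionEvent:
    """A called partial intron retention.

    ``intron_index`` is 1-based in transcription order; ``retained_end``
    says which end of the intron the fragment abuts in transcript
    orientation; ``fragment`` is the retained genomic interval (1-based
    inclusive, forward strand).
    """

    intron_index: int
    retained_end: str  # '5prime' or '3prime'
    fragment_length: int
    fragment: tuple[int, int]
    supporting_reads: int = 0

    def __post_init__(self) -> None:
        if self.retained_end not in ("5prime", "3prime"):
            raise ValueError(f"retained_end must be 5prime/3prime, got {self.retained_end!r}")
        if self.fragment_length < 1:
            raise ValueError("fragment_length must be >= 1")
        if self.fragment[1] - self.fragment[0] + 1 != self.fragment_length:
            raise ValueError("fragment interval does not match fragment_length")


@dataclass(frozen=True)
class ConsequencePrediction:
    frameshift: bool
    inserted_nt: int
    ptc_codon_index: int | None  # 1-based codon of the first premature stop
    truncated_protein_length: int
    truncated_mass_kda: float
    full_mass_kda: float
    nmd_sensitive: bool
    non_stop: bool = False


# ---------------------------------------------------------------------------
# Junction classification
# ---------------------------------------------------------------------------


def classify_junction(j: JunctionRecord, model: GeneModel) -> str:
    """Classify a junction against a gene model.

    Classes are defined in transcription orientation: a
    ``partial_retention_5prime`` junction retains the fragment abutting
    the intron's transcriptional 5' (donor-side) splice site.
    """
    cls, _ = classify_junction_detail(j, model)
    return cls


def classify_junction_detail(
    j: JunctionRecord, model: GeneModel
) -> tuple[str, RetentionEvent | None]:
    """As :func:`classify_junction`, returning the implied retention event."""
    if j.chrom != model.chrom:
        warnings.warn(f"junction on {j.chrom}, gene on {model.chrom}", stacklevel=2)
        return "other", None
    span = model.span
    if j.donor < span[0] or j.acceptor > span[1]:
        warnings.warn("junction outside gene span", stacklevel=2)
        return "other", None

    exon_ends = {e: i for i, (_, e) in enumerate(model.exons)}
    exon_starts = {s: i for i, (s, _) in enumerate(model.exons)}
    introns = model.introns

    def intron_containing(pos: int) -> int | None:
        for i, (s, e) in enumerate(introns):
            if s <= pos <= e:
                return i
        return None

    donor_end = exon_ends.get(j.donor)
    acceptor_start = exon_starts.get(j.acceptor)

    if donor_end is not None and acceptor_start is not None:
        if acceptor_start == donor_end + 1:
            return "annotated", None
        if acceptor_start > donor_end + 1:
            return "exon_skip", None
        return "other", None

    donor_in = intron_containing(j.donor)
    acceptor_in = intron_containing(j.acceptor)

    # donor inside intron k, acceptor = start of exon k+1:
    # the fragment at the genomic 5' end of the intron is retained.
    if donor_in is not None and acceptor_start == donor_in + 1:
        gstart, gend = introns[donor_in]
        length = j.donor - gstart + 1
        end = "5prime" if model.strand == "+" else "3prime"
        event = RetentionEvent(
            intron_index=model.intron_tx_index((gstart, gend)),
            retained_end=end,
            fragment_length=length,
            fragment=(gstart, j.donor),
            supporting_reads=j.unique_reads,
        )
        return f"partial_retention_{end}", event

    # donor = end of exon k, acceptor inside intron k:
    # the fragment at the genomic 3' end of the intron is retained.
    if acceptor_in is not None and donor_end == acceptor_in:
        gstart, gend = introns[acceptor_in]
        length = gend - j.acceptor + 1
        end = "3prime" if model.strand == "+" else "5prime"
        event = RetentionEvent(
            intron_index=model.intron_tx_index((gstart, gend)),
            retained_end=end,
            fragment_length=length,
            fragment=(j.acceptor, gend),
            supporting_reads=j.unique_reads,
        )
        return f"partial_retention_{end}", event

    if donor_in is not None and donor_in == acceptor_in:
        return "intronic", None
    return "other", None


def call_retentions(
    junctions: list[JunctionRecord],
    model: GeneModel,
    min_reads: int = 2,
    min_len: int = 1,
    max_len: int | None = None,
) -> list[RetentionEvent]:
    """Call partial retention events from junction evidence.

    Junctions classified as partial retentions with at least ``min_reads``
    unique reads and fragment length within ``[min_len, max_len]``
    (``max_len`` defaults to intron length - 1, which always holds by
    construction) yield events; identical events are merged with summed
    read support. Events are sorted by intron index, then length.
    """
    merged: dict[tuple, RetentionEvent] = {}
    for j in junctions:
        cls, event = classify_junction_detail(j, model)
        if event is None or not cls.startswith("partial_retention"):
            continue
        if event.fragment_length < min_len:
            continue
        if max_len is not None and event.fragment_length > max_len:
            continue
        key = (event.intron_index, event.retained_end, event.fragment)
        if key in merged:
            old = merged[key]
            merged[key] = RetentionEvent(
                intron_index=old.intron_index,
                retained_end=old.retained_end,
                fragment_length=old.fragment_length,
                fragment=old.fragment,
                supporting_reads=old.supporting_reads + event.supporting_reads,
            )
        else:
            merged[key] = event
    events = [e for e in merged.values() if e.supporting_reads >= min_reads]
    return sorted(events, key=lambda e: (e.intron_index, e.fragment_length))


# ---------------------------------------------------------------------------
# Transcript reconstruction and consequence prediction
# ---------------------------------------------------------------------------


def aberrant_transcript(
    model: GeneModel, genome: str, event: RetentionEvent
) -> tuple[str, list[int], int]:
    """Reconstruct the retention transcript.

    Returns ``(sequence, coord_map, last_junction_pos)`` where
    ``coord_map[i]`` is the 1-based genomic origin of transcript base
    ``i`` (0-based), and ``last_junction_pos`` is the 1-based transcript
    coordinate of the last exonic base 5' of the final splice junction.
    """
    gstart, gend = model.intron_tx(event.intron_index)
    fs, fe = event.fragment
    if not (gstart <= fs <= fe <= gend):
        raise ValueError("event fragment does not lie inside its intron")
    if event.fragment_length >= gend - gstart + 1:
        raise ValueError("fragment must be shorter than the intron")

    # segments in transcription order: exons 1..k, fragment, exons k+1..m
    k = event.intron_index
    exons_tx = model.exons_tx()
    segments = list(exons_tx[:k]) + [(fs, fe)] + list(exons_tx[k:])

    pieces: list[str] = []
    coord_map: list[int] = []
    for s, e in segments:
        if model.strand == "+":
            pieces.append(genome[s - 1 : e])
            coord_map.extend(range(s, e + 1))
        else:
            pieces.append(str(Seq(genome[s - 1 : e]).reverse_complement()))
            coord_map.extend(range(e, s - 1, -1))
    seq = "".join(pieces)
    last_exon_len = segments[-1][1] - segments[-1][0] + 1
    last_junction_pos = len(seq) - last_exon_len
    return seq, coord_map, last_junction_pos


def normal_transcript(model: GeneModel, genome: str) -> tuple[str, int]:
    """Spliced reference transcript and its last exon-exon junction position."""
    seq = model.spliced_transcript(genome)
    exons_tx = model.exons_tx()
    last_exon_len = exons_tx[-1][1] - exons_tx[-1][0] + 1
    return seq, len(seq) - last_exon_len


def predict_consequence(
    transcript: str,
    cds_offset: int,
    last_junction_pos: int,
    inserted_nt: int,
    annotated_protein: str,
) -> ConsequencePrediction:
    """Translate an aberrant transcript and predict the protein outcome.

    ``cds_offset`` is the 0-based transcript position of the start codon;
    ``annotated_protein`` is the reference protein (for the full mass and
    the premature/normal stop distinction). A stop is premature when the
    resulting protein is shorter than the reference protein extended by
    any in-frame insertion; a PTC more than 50 nt upstream of the last
    exon-exon junction flags the transcript as NMD-sensitive.
    """
    if not 0 <= cds_offset < len(transcript):
        raise ValueError("cds_offset outside transcript")
    frameshift = inserted_nt % 3 != 0
    coding = transcript[cds_offset:]
    coding = coding[: len(coding) - len(coding) % 3]
    aa = str(Seq(coding).translate())
    stop_idx = aa.find("*")  # 0-based codon index of first stop

    non_stop = stop_idx == -1
    protein = aa if non_stop else aa[:stop_idx]
    if non_stop:
        warnings.warn("no stop codon before transcript end (non-stop)", stacklevel=2)

    expected_len = len(annotated_protein) + inserted_nt // 3 if not frameshift else None
    if non_stop:
        ptc_codon_index = None
        premature = False
    else:
        premature = (
            len(protein) < expected_len
            if expected_len is not None
            else len(protein) < len(annotated_protein) + inserted_nt / 3
        )
        ptc_codon_index = stop_idx + 1 if premature else None

    nmd = False
    if ptc_codon_index is not None:
        stop_start_1based = cds_offset + (ptc_codon_index - 1) * 3 + 1
        nmd = stop_start_1based < last_junction_pos - NMD_RULE_NT

    return ConsequencePrediction(
        frameshift=frameshift,
        inserted_nt=inserted_nt,
        ptc_codon_index=ptc_codon_index,
        truncated_protein_length=len(protein),
        truncated_mass_kda=protein_mw(protein) if protein else 0.0,
        full_mass_kda=protein_mw(annotated_protein),
        nmd_sensitive=nmd,
        non_stop=non_stop,
    )


def consequence_for_event(
    model: GeneModel, genome: str, event: RetentionEvent
) -> ConsequencePrediction:
    """End-to-end prediction for a called retention event."""
    ref_protein = model.protein(genome)
    seq, coord_map, last_junction = aberrant_transcript(model, genome, event)
    cds_start_genomic = model.cds[0] if model.strand == "+" else model.cds[1]
    cds_offset = coord_map.index(cds_start_genomic)
    return predict_consequence(
        seq, cds_offset, last_junction, event.fragment_length, ref_protein
    )


def protein_mw(aa_sequence: str) -> float:
    """Average molecular mass of a protein in kDa (residues + one water)."""
    if not aa_sequence:
        raise ValueError("empty protein sequence")
    try:
        da = molecular_weight(aa_sequence, seq_type="protein")
    except ValueError as exc:
        bad = sorted(set(aa_sequence) - set("ACDEFGHIKLMNPQRSTVWY"))
        raise ValueError(f"unknown residue(s) {bad} in protein sequence") from exc
    return da / 1000.0
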