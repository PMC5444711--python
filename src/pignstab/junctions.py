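"""Splice-junction records and file dialects.

Internal convention: a junction is stored by its flanking *exonic* bases,
1-based — ``donor`` is the last exonic base of the upstream (genomically
left) side, ``acceptor`` the first exonic base of the downstream side,
so ``donor < acceptor`` always holds and the excised interval is
``donor+1 .. acceptor-1``.

Two on-disk dialects are supported:

``sj_tab``
    The STAR ``SJ.out.tab`` layout: chrom, first intronic base, last
    intronic base (both 1-based), strand code (0 undefined / 1 ``+`` /
    2 ``-``), motif code, annotated flag, unique reads, multi reads,
    overhang.

``bed12``
    12-column BED; each pair of consecutive blocks implies one junction
    (0-based half-open block coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

_STRAND_CODE = {"0": ".", "1": "+", "2": "-"}
_CODE_STRAND = {".": 0, "+": 1, "-": 2}


@dataclass(frozen=True)
class JunctionRecord:
    chrom: str
    donor: int  # last exonic base, upstream side (1-based)
    acceptor: int  # first exonic base, downstream side (1-based)
    strand: str  # '+', '-' or '.'
    unique_reads: int = 0
    dialect: str = ""

    def __post_init__(self) -> None:
        if self.donor >= self.acceptor:
            raise ValueError(
                f"donor {self.donor} must be < acceptor {self.acceptor}"
            )
        if self.unique_reads < 0:
            raise ValueError("unique_reads must be >= 0")

    @property
    def intron(self) -> tuple[int, int]:
        """The excised genomic interval, 1-based inclusive."""
        return self.donor + 1, self.acceptor - 1


class JunctionParseError(ValueError):
    pass


def read_junctions(path: str | Path, dialect: str) -> list[JunctionRecord]:
    """Parse a junction file, normalizing coordinates to the internal convention."""
    if dialect == "sj_tab":
        return _read_sj_tab(path)
    if dialect == "bed12":
        return _read_bed12(path)
    raise ValueError(f"unknown junction dialect {dialect!r}")


def _read_sj_tab(path: str | Path) -> list[JunctionRecord]:
    out: list[JunctionRecord] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 9:
            raise JunctionParseError(
                f"{path}:{lineno}: expected 9 tab-separated columns, got {len(fields)}"
            )
        try:
            istart, iend = int(fields[1]), int(fields[2])
            strand = _STRAND_CODE[fields[3]]
            unique = int(fields[6])
        except (ValueError, KeyError) as exc:
            raise JunctionParseError(f"{path}:{lineno}: {exc}") from exc
        out.append(
            JunctionRecord(
                chrom=fields[0],
                donor=istart - 1,
                acceptor=iend + 1,
                strand=strand,
                unique_reads=unique,
                dialect="sj_tab",
            )
        )
    return out


def _read_bed12(path: str | Path) -> list[JunctionRecord]:
    out: list[JunctionRecord] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("track", "browser", "#")):
            continue
        fields = line.split("\t")
        if len(fields) < 12:
            raise JunctionParseError(
                f"{path}:{lineno}: expected 12 BED columns, got {len(fields)}"
            )
        try:
            chrom_start = int(fields[1])
            score = int(float(fields[4]))
            strand = fields[5] if fields[5] in "+-" else "."
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            starts = [int(x) for x in fields[11].rstrip(",").split(",")]
        except ValueError as exc:
            raise JunctionParseError(f"{path}:{lineno}: {exc}") from exc
        if len(sizes) != len(starts):
            raise JunctionParseError(
                f"{path}:{lineno}: blockSizes/blockStarts length mismatch"
            )
        for (s1, z1), s2 in zip(zip(starts, sizes), starts[1:]):
            # 0-based half-open blocks -> 1-based flanking exonic bases
            donor = chrom_start + s1 + z1  # last base of block 1, 1-based
            acceptor = chrom_start + s2 + 1  # first base of block 2, 1-based
            out.append(
                JunctionRecord(
                    chrom=fields[0],
                    donor=donor,
                    acceptor=acceptor,
                    strand=strand,
                    unique_reads=score,
                    dialect="bed12",
                )
            )
    return out


def write_junctions(
    records: list[JunctionRecord],
    path: str | Path,
    dialect: str,
    flank: int = 20,
) -> None:
    """Write junctions in the named dialect.

    For ``bed12`` each junction becomes one two-block line with ``flank``
    nt anchors (clipped at the chromosome start).
    """
    lines: list[str] = []
    if dialect == "sj_tab":
        for j in records:
            istart, iend = j.intron
            lines.append(
                "\t".join(
                    [
                        j.chrom,
                        str(istart),
                        str(iend),
                        str(_CODE_STRAND[j.strand]),
                        "0",  # motif code: not tracked
                        "0",  # annotated flag: not tracked
                        str(j.unique_reads),
                        "0",
                        str(flank),
                    ]
                )
            )
    elif dialect == "bed12":
        for i, j in enumerate(records):
            left = min(flank, j.donor)  # keep chromStart >= 0
            chrom_start = j.donor - left  # 0-based
            block2_start = j.acceptor - 1 - chrom_start
            chrom_end = j.acceptor - 1 + flank
            lines.append(
                "\t".join(
                    [
                        j.chrom,
                        str(chrom_start),
                        str(chrom_end),
                        f"JUNC{i + 1:05d}",
                        str(j.unique_reads),
                        j.strand if j.strand in "+-" else "+",
                        str(chrom_start),
                        str(chrom_end),
                        "0,0,0",
                        "2",
                        f"{left},{flank}",
                        f"0,{block2_start}",
                    ]
                )
            )
    else:
        raise ValueError(f"unknown junction dialect {dialect!r}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
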