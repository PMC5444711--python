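"""GPI-anchor-protein deficiency frequency from selective CFC assays.

In a proaerolysin-selection colony-forming-cell (CFC) assay, GPI-AP
deficient clones survive selection. The deficiency frequency of a
replicate is the ratio of plating efficiencies with and without
selection:

    f = (colonies_selective / cells_plated_selective)
        / (colonies_control / cells_plated_control)

the standard mutant-frequency estimator for selective clonogenic assays.
Replicates are summarized as median and min-max range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from statistics import median

import pandas as pd

#: GPI-AP deficiency frequency in a normal population (fractional, = 0.002%).
NORMAL_BACKGROUND_FREQUENCY = 2e-5


@dataclass(frozen=True)
class CFCReplicate:
    cells_plated_selective: int
    colonies_selective: int
    cells_plated_control: int
    colonies_control: int

    def __post_init__(self) -> None:
        for name in (
            "cells_plated_selective",
            "colonies_selective",
            "cells_plated_control",
            "colonies_control",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.colonies_selective > self.cells_plated_selective:
            raise ValueError("selective colonies exceed cells plated")
        if self.colonies_control > self.cells_plated_control:
            raise ValueError("control colonies exceed cells plated")


@dataclass
class CFCAssay:
    population: str
    replicates: list[CFCReplicate] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.replicates:
            raise ValueError("assay needs at least one replicate")


@dataclass(frozen=True)
class FrequencyEstimate:
    population: str
    frequencies: tuple[float, ...]
    median: float
    min: float
    max: float
    n_replicates: int


def deficiency_frequency(rep: CFCReplicate) -> float:
    """Per-replicate GPI-AP deficiency frequency (ratio of plating efficiencies)."""
    if rep.cells_plated_selective == 0 or rep.cells_plated_control == 0:
        raise ValueError("cells plated must be > 0")
    if rep.colonies_control == 0:
        raise ValueError("zero control colonies: plating efficiency undefined")
    f = (rep.colonies_selective / rep.cells_plated_selective) / (
        rep.colonies_control / rep.cells_plated_control
    )
    if f > 1.0:
        warnings.warn(f"frequency {f:.3g} > 1 clipped to 1", stacklevel=2)
        f = 1.0
    return f


def summarize(assay: CFCAssay) -> FrequencyEstimate:
    """Median and min-max range of per-replicate deficiency frequencies."""
    freqs = tuple(deficiency_frequency(r) for r in assay.replicates)
    return FrequencyEstimate(
        population=assay.population,
        frequencies=freqs,
        median=float(median(freqs)),
        min=min(freqs),
        max=max(freqs),
        n_replicates=len(freqs),
    )


def fold_over(a: FrequencyEstimate, b: FrequencyEstimate) -> float:
    """Ratio of median frequencies a / b (e.g. leukemic over non-leukemic)."""
    if b.median <= 0:
        raise ValueError("denominator median must be > 0")
    return a.median / b.median


def fold_over_background(
    a: FrequencyEstimate, background: float = NORMAL_BACKGROUND_FREQUENCY
) -> float:
    """Ratio of the median frequency over a scalar background frequency."""
    if background <= 0:
        raise ValueError("background frequency must be > 0")
    return a.median / background


# ---- I/O -----------------------------------------------------------------


def read_assays(path: str | Path) -> list[CFCAssay]:
    """Read replicate counts from CSV with columns population,
    cells_selective, colonies_selective, cells_control, colonies_control."""
    df = pd.read_csv(path)
    assays = []
    for population, grp in df.groupby("population", sort=False):
        reps = [
            CFCReplicate(
                int(r.cells_selective),
                int(r.colonies_selective),
                int(r.cells_control),
                int(r.colonies_control),
            )
            for r in grp.itertuples()
        ]
        assays.append(CFCAssay(str(population), reps))
    return assays


def write_assay(assay: CFCAssay, path: str | Path) -> None:
    rows = [
        {
            "population": assay.population,
            "cells_selective": r.cells_plated_selective,
            "colonies_selective": r.colonies_selective,
            "cells_control": r.cells_plated_control,
            "colonies_control": r.colonies_control,
        }
        for r in assay.replicates
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def estimates_table(estimates: list[FrequencyEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "population": e.population,
                "median": e.median,
                "min": e.min,
                "max": e.max,
                "n": e.n_replicates,
            }
            for e in estimates
        ]
    )
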