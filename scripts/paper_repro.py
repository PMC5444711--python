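#!/usr/bin/env python
"""Optional real-accession reproduction (requires network access).

Downloads the GSE4619 series matrix and GPL570 probe annotation from GEO,
scores the cohort with the packaged CIN70 and GPI panels, and reports the
cross-panel PC1 Pearson correlation and the random-forest importance rank
of PIGN for MDS risk stratification. Optionally fetches the PIGN
reference protein (NP_036393) from NCBI to report the full and
38-nt-retention truncated masses.

This script is not part of the test suite: it needs ~50 MB of downloads
and GEO/NCBI availability. Run it from the repository root:

    python scripts/paper_repro.py --workdir scratch/repro
"""

from __future__ import annotations

import argparse
import gzip
import io
import urllib.request
from pathlib import Path

import numpy as np
import pandas as pd

from pignstab import panels
from pignstab.cohort import ExpressionCohort, cin70_panel, gpi_panel
from pignstab.retention import protein_mw

SERIES_MATRIX_URL = (
    "https://ftp.ncbi.nlm.nih.gov/geo/series/GSE4nnn/GSE4619/matrix/"
    "GSE4619_series_matrix.txt.gz"
)
GPL570_ANNOT_URL = (
    "https://ftp.ncbi.nlm.nih.gov/geo/platforms/GPLnnn/GPL570/annot/GPL570.annot.gz"
)
PIGN_PROTEIN_URL = (
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
    "?db=protein&id=NP_036393.2&rettype=fasta&retmode=text"
)


def fetch(url: str, dest: Path) -> Path:
    if not dest.exists():
        print(f"downloading {url}")
        urllib.request.urlretrieve(url, dest)
    return dest


def load_series_matrix(path: Path) -> tuple[pd.DataFrame, pd.Series]:
    """Expression table (probes x samples) and per-sample title strings."""
    titles = None
    with gzip.open(path, "rt") as fh:
        lines = fh.read().splitlines()
    table_start = lines.index("!series_matrix_table_begin")
    table_end = lines.index("!series_matrix_table_end")
    for line in lines[:table_start]:
        if line.startswith("!Sample_title"):
            titles = [t.strip('"') for t in line.split("\t")[1:]]
    matrix = pd.read_csv(
        io.StringIO("\n".join(lines[table_start + 1 : table_end])),
        sep="\t",
        index_col=0,
    )
    return matrix, pd.Series(titles, index=matrix.columns)


def subtype_from_title(title: str) -> str | None:
    t = title.upper()
    if "RAEB1" in t or "RAEB-1" in t or "RAEB 1" in t:
        return "RAEB1"
    if "RAEB2" in t or "RAEB-2" in t or "RAEB 2" in t:
        return "RAEB2"
    if "RARS" in t:
        return "RARS"
    if "RA" in t:
        return "RA"
    if "CONTROL" in t or "NORMAL" in t or "HEALTHY" in t:
        return "Control"
    return None


def probe_to_symbol(annot_path: Path) -> pd.Series:
    with gzip.open(annot_path, "rt", errors="replace") as fh:
        lines = [l for l in fh.read().splitlines() if not l.startswith(("#", "^", "!"))]
    table = pd.read_csv(io.StringIO("\n".join(lines)), sep="\t", dtype=str)
    table = table.dropna(subset=["Gene symbol"])
    return table.set_index("ID")["Gene symbol"].str.split("///").str[0].str.strip()


def collapse_by_symbol(matrix: pd.DataFrame, symbols: pd.Series) -> pd.DataFrame:
    """Keep, per gene symbol, the probe with the highest variance."""
    matrix = matrix.loc[matrix.index.intersection(symbols.index)]
    sym = symbols.loc[matrix.index]
    variances = matrix.var(axis=1)
    best = variances.groupby(sym).idxmax()
    collapsed = matrix.loc[best]
    collapsed.index = best.index
    return collapsed


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--workdir", type=Path, default=Path("scratch/repro"))
    parser.add_argument("--trees", type=int, default=500)
    parser.add_argument("--seeds", type=int, default=20)
    parser.add_argument("--skip-protein", action="store_true")
    args = parser.parse_args()
    args.workdir.mkdir(parents=True, exist_ok=True)

    matrix_gz = fetch(SERIES_MATRIX_URL, args.workdir / "GSE4619_series_matrix.txt.gz")
    annot_gz = fetch(GPL570_ANNOT_URL, args.workdir / "GPL570.annot.gz")

    matrix, titles = load_series_matrix(matrix_gz)
    subtypes = titles.map(subtype_from_title).dropna()
    matrix = matrix[subtypes.index]
    print(f"samples with recognized subtype: {len(subtypes)}")
    print(subtypes.value_counts().to_string())

    symbols = probe_to_symbol(annot_gz)
    by_symbol = collapse_by_symbol(matrix, symbols)
    cohort = ExpressionCohort(by_symbol, subtypes)

    cin, gpi = cin70_panel(), gpi_panel()
    score_cin = panels.panel_pc1(cohort, cin)
    score_gpi = panels.panel_pc1(cohort, gpi)
    r, p = panels.panel_correlation(score_cin, score_gpi)
    print(f"\ncross-panel PC1 Pearson r = {r:.4f} (p = {p:.4g}, n = {cohort.n_samples})")

    ranks = []
    for seed in range(args.seeds):
        imp = panels.rf_risk_importance(cohort, gpi, n_trees=args.trees, seed=seed)
        ranks.append(imp.rank_of("PIGN"))
    ranks.sort()
    print(f"PIGN importance rank over {args.seeds} seeds: median "
          f"{ranks[len(ranks) // 2]}, all {ranks}")

    if not args.skip_protein:
        fasta = fetch(PIGN_PROTEIN_URL, args.workdir / "pign_protein.fa")
        protein = "".join(
            l.strip() for l in fasta.read_text().splitlines() if not l.startswith(">")
        )
        print(f"\nPIGN protein: {len(protein)} aa, {protein_mw(protein):.1f} kDa")


if __name__ == "__main__":
    main()
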