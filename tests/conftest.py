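import numpy as np
import pandas as pd
import pytest

from pignstab import simulate as sim
from pignstab.cohort import ExpressionCohort, GenePanel


@pytest.fixture(scope="session")
def toy_gene():
    """A 3-exon plus-strand toy gene with a long first intron."""
    spec = sim.ToyGeneSpec(
        exon_lengths=(60, 90, 120), intron_lengths=(250, 80), seed=1
    )
    return sim.gen_gene_model(spec)


@pytest.fixture(scope="session")
def toy_gene_minus():
    """The minus-strand mirror of :func:`toy_gene` (same spec, strand '-')."""
    spec = sim.ToyGeneSpec(
        exon_lengths=(60, 90, 120), intron_lengths=(250, 80), strand="-", seed=1
    )
    return sim.gen_gene_model(spec)


@pytest.fixture()
def small_cohort():
    """A 4-sample, 3-gene cohort for exact-arithmetic checks."""
    matrix = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [2.0, 1.0, 4.0, 3.0], [5.0, 5.0, 6.0, 4.0]],
        index=["GA", "GB", "GC"],
        columns=["s1", "s2", "s3", "s4"],
    )
    labels = pd.Series(
        ["Control", "Control", "RAEB2", "RAEB2"], index=matrix.columns
    )
    return ExpressionCohort(matrix, labels)


@pytest.fixture(scope="session")
def separable_cohort():
    """One perfectly class-separating gene plus 9 noise genes, n = 60."""
    rng = np.random.default_rng(42)
    n = 60
    samples = [f"S{i:03d}" for i in range(n)]
    labels = pd.Series(["RA"] * 30 + ["RAEB2"] * 30, index=samples)
    X = rng.normal(size=(10, n))
    X[0, :30] = rng.normal(-3.0, 0.3, 30)
    X[0, 30:] = rng.normal(3.0, 0.3, 30)
    matrix = pd.DataFrame(X, index=[f"G{i}" for i in range(10)], columns=samples)
    panel = GenePanel("toy10", tuple(f"G{i}" for i in range(10)))
    return ExpressionCohort(matrix, labels), panel
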