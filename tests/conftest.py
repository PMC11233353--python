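import numpy as np
import pandas as pd
import pytest

from tetragwas.genotypes import DosageMatrix, MARKER_COLUMNS
from tetragwas.simulate import SimConfig, simulate_population


def make_dosage_matrix(values, chrom="chr01", start_pos=100, spacing=1000):
    """Small DosageMatrix from a literal (markers x samples) array."""
    values = np.asarray(values, float)
    m, n = values.shape
    markers = pd.DataFrame(
        [(f"m{i}", chrom, start_pos + i * spacing, "A", "G", "TEST")
         for i in range(m)], columns=MARKER_COLUMNS)
    return DosageMatrix(values, [f"S{j}" for j in range(n)], markers)


@pytest.fixture(scope="session")
def small_panel():
    """Structured panel, small enough for per-test use."""
    return simulate_population(SimConfig(n_samples=150, n_chrom=2,
                                         n_markers_per_chrom=300, seed=11))


@pytest.fixture(scope="session")
def unstructured_panel():
    """Single-population panel (no admixture LD) for LD-decay checks."""
    return simulate_population(SimConfig(n_samples=200, n_subpops=1, fst=0.0,
                                         n_chrom=1, n_markers_per_chrom=500,
                                         missing_rate=0.02, seed=7))
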