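import numpy as np
import pandas as pd
import pytest


def _write_metal(path, rows):
    header = "MarkerName\tChr\tPos\tEffect_allele\tOther_allele\tEAF\tBeta\tSE\tN\n"
    with open(path, "w") as fh:
        fh.write(header)
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")
    return path


@pytest.fixture
def metal_writer(tmp_path):
    """Write a METAL-style summary-statistics file and return its path."""

    def write(name, rows):
        return _write_metal(tmp_path / name, rows)

    return write


@pytest.fixture
def small_pair(metal_writer):
    """Two harmonizable three-variant stratum files (one swapped allele pair)."""
    f1 = metal_writer("s1.txt", [
        ("rs1", 1, 1_000_000, "A", "G", 0.25, 0.05, 0.01, 50000),
        ("rs2", 1, 2_000_000, "C", "T", 0.40, -0.02, 0.012, 50000),
        ("rs3", 2, 500_000, "G", "C", 0.10, 0.10, 0.02, 50000),
    ])
    f2 = metal_writer("s2.txt", [
        ("rs1", 1, 1_000_000, "A", "G", 0.26, 0.01, 0.011, 48000),
        ("rs2", 1, 2_000_000, "T", "C", 0.61, 0.03, 0.013, 48000),  # swapped
        ("rs3", 2, 500_000, "G", "C", 0.11, 0.09, 0.021, 48000),
    ])
    return f1, f2


@pytest.fixture
def harmonized_null_frame():
    """A 200-variant harmonized frame simulated under no GxS."""
    rng = np.random.default_rng(11)
    n = 200
    se = 0.01
    return pd.DataFrame({
        "marker": [f"rs{i}" for i in range(n)],
        "chr": np.repeat([str(c) for c in range(1, 5)], n // 4),
        "pos": np.tile(np.arange(1, n // 4 + 1) * 2_000_000, 4),
        "beta1": rng.normal(0, se, n),
        "se1": se,
        "beta2": rng.normal(0, se, n),
        "se2": se,
    })
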