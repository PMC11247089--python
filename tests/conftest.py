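import numpy as np
import pandas as pd
import pytest

from circaclock import CohortConfig, generate_cohort


def brute_force_spearman(x, y) -> float:
    """Independent rank-correlation oracle: average-tie ranks computed by
    explicit grouping, then the Pearson formula on the rank vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)

    def avg_ranks(v):
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    return float((rx * ry).sum() / denom)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Small noiseless cohort with exact planted geometry (one sample per
    hour over one day)."""
    cfg = CohortConfig(
        n_genes_per_group=5, n_background=3, n_samples=24,
        noise_sd=0.0, phase_jitter_sd_h=0.0, seed=42,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def noisy_cohort():
    """Moderately noisy cohort used by recovery-style tests."""
    cfg = CohortConfig(
        n_genes_per_group=20, n_background=40, n_samples=24,
        noise_sd=0.25, phase_jitter_sd_h=0.5, seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def tiny_matrix_file(tmp_path):
    """3-gene x 4-sample already-log2 TSV on disk."""
    df = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0], [5.5, 5.0, 6.0, 6.5]],
        index=["Per3", "Arntl", "Tef"], columns=["s1", "s2", "s3", "s4"],
    )
    path = tmp_path / "matrix.tsv"
    df.index.name = "gene"
    df.to_csv(path, sep="\t")
    return path
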