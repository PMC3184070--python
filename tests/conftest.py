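import numpy as np
import pandas as pd
import pytest

from gcls.genome_io import GenomeLayout


@pytest.fixture
def layout_1mb() -> GenomeLayout:
    return GenomeLayout({"chr1": 1_000_000})


@pytest.fixture
def layout_two_chroms() -> GenomeLayout:
    return GenomeLayout({"chr1": 1_000_000, "chr2": 500_000})


def make_tags(chrom, positions, strands=None) -> pd.DataFrame:
    positions = np.asarray(positions, dtype=np.int64)
    if strands is None:
        strands = ["+"] * len(positions)
    df = pd.DataFrame({"chrom": chrom, "pos": positions, "strand": list(strands)})
    return df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def uniform_tags(n: int, size: int, rng: np.random.Generator,
                 chrom: str = "chr1") -> pd.DataFrame:
    pos = rng.integers(0, size, n)
    strand = np.where(rng.random(n) < 0.5, "+", "-")
    return make_tags(chrom, pos, strand)


def intervals(chrom, pairs) -> pd.DataFrame:
    return pd.DataFrame({"chrom": chrom,
                         "start": [p[0] for p in pairs],
                         "end": [p[1] for p in pairs]})


def two_gaussian_points(n_per_cluster: int, seed: int,
                        mu1=(2.0, 2.0), mu2=(3.5, 2.0), sd: float = 0.25):
    """Two isotropic clusters in (log_d, log_w); cluster 1 (small gaps) is
    the merge-candidate (Type 1) population."""
    rng = np.random.default_rng(seed)
    log_d = np.r_[rng.normal(mu1[0], sd, n_per_cluster),
                  rng.normal(mu2[0], sd, n_per_cluster)]
    log_w = np.r_[rng.normal(mu1[1], sd, n_per_cluster),
                  rng.normal(mu2[1], sd, n_per_cluster)]
    points = pd.DataFrame({"peak_index": np.arange(2 * n_per_cluster),
                           "log_d": log_d, "log_w": log_w})
    labels = np.r_[np.ones(n_per_cluster, bool), np.zeros(n_per_cluster, bool)]
    return points, labels
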