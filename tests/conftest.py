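import numpy as np
import pandas as pd
import pytest

from clonetracer.simulate import SimConfig, simulate_patient


@pytest.fixture(scope="session")
def small_patient():
    """One simulated patient reused by read-only tests."""
    cfg = SimConfig(
        seed=11,
        n_clusters=4,
        n_samples_tissue=5,
        n_samples_fluid=1,
        muts_per_cluster=60,
        purity_range=(0.3, 0.8),
    )
    return simulate_patient(cfg)


def make_cluster_counts(
    centroids: np.ndarray, n_per_cluster: int, depth: int, rho: float, seed: int
) -> pd.DataFrame:
    """Binomial read counts for K clusters at given per-sample CCF centroids.

    Pure diploid (n_t = n_n = 2, multiplicity 1), so expected VAF is
    centroid * rho / 2.  Returns the long variant table the clustering
    routines consume, with true cluster labels in a 'true_cluster' column.
    """
    rng = np.random.default_rng(seed)
    K, S = centroids.shape
    rows = []
    for k in range(K):
        for i in range(n_per_cluster):
            vid = f"v{k:02d}_{i:04d}"
            for s in range(S):
                f = centroids[k, s] * rho / 2.0
                d = depth
                a = rng.binomial(d, min(f, 1.0))
                rows.append(
                    {
                        "variant_id": vid,
                        "sample_id": f"s{s}",
                        "alt_count": a,
                        "depth": d,
                        "n_chr": 1,
                        "n_locus_t": 2,
                        "is_indel": False,
                        "true_cluster": k,
                    }
                )
    return pd.DataFrame(rows)
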