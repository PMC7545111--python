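"""Multi-sample Dirichlet-process mixture clustering of mutations by CCF.

Mutations are modeled as draws from an unknown number of subclones, each with
a per-sample cancer cell fraction.  The sampler is a truncated stick-breaking
Gibbs sampler over binomial read counts: cluster weights follow a
stick-breaking prior with concentration ``conc_param``; each cluster's
location is a per-sample CCF on a discrete grid in [0, max_burden]; a
variant's alt count in sample s given cluster location theta is
Binomial(depth, f) with

    f = theta * m * rho_s / (rho_s * n_t + n_n * (1 - rho_s))

using the variant's own multiplicity m and locus copy number.  Locations are
sampled by grid Gibbs (exact discrete conditional), assignments by categorical
Gibbs.  Assignments are summarized as the modal posterior cluster over kept
iterations; centroids as the per-sample posterior median location.

Defaults mirror the published analysis settings: 10,000 iterations with 9,000
burn-in, conc_param = 1, cluster_conc = 5, density_smooth = 0.001,
max_burden = 1.5.  ``cluster_conc`` is interpreted as a prior pseudo-count
smoothing the location grid posterior, and ``density_smooth`` as the kernel
bandwidth used only when reporting posterior location densities; both are
interpretations of opaque legacy parameters, documented in the methods note.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd


class ClusteringError(ValueError):
    pass


@dataclass
class ClusteringParams:
    n_iter: int = 10_000
    burn_in: int = 9_000
    conc_param: float = 1.0
    cluster_conc: float = 5.0
    density_smooth: float = 0.001
    max_burden: float = 1.5
    truncation: int = 20
    grid_step: float = 0.01
    merge_tol: float = 0.05  # centroids closer than this in every sample merge
    seed: int = 0

    def validate(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ClusteringError("burn_in must be smaller than n_iter")
        if self.truncation < 1:
            raise ClusteringError("truncation must be >= 1")
        if self.max_burden <= 0 or self.grid_step <= 0:
            raise ClusteringError("max_burden and grid_step must be positive")


@dataclass
class MutationCluster:
    cluster_id: int
    ccf_centroid: dict[str, float]
    n_mutations: int
    n_indels: int
    member_ids: list = field(default_factory=list)


def select_samples_for_clustering(purity: dict[str, float], threshold: float = 0.15) -> list[str]:
    """Samples eligible for clustering: estimated tumor purity strictly above 15%."""
    included = [s for s, rho in purity.items() if rho > threshold]
    if not included:
        raise ClusteringError("no sample exceeds the purity threshold; clustering impossible")
    return included


def _pivot_counts(
    variants: pd.DataFrame, samples: list[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, pd.Index]:
    sub = variants[variants.sample_id.isin(samples)]
    alt = sub.pivot(index="variant_id", columns="sample_id", values="alt_count")[samples]
    dep = sub.pivot(index="variant_id", columns="sample_id", values="depth")[samples]
    mult = sub.pivot(index="variant_id", columns="sample_id", values="n_chr")[samples]
    n_t = sub.pivot(index="variant_id", columns="sample_id", values="n_locus_t")[samples]
    ids = alt.index
    return (
        alt.values.astype(float),
        dep.values.astype(float),
        mult.values.astype(float),
        n_t.values.astype(float),
        ids,
    )


def run_dp_clustering(
    variants: pd.DataFrame,
    purity: dict[str, float],
    params: Optional[ClusteringParams] = None,
    samples: Optional[list[str]] = None,
) -> tuple[list[MutationCluster], pd.DataFrame]:
    """Cluster mutations across samples by CCF.

    ``variants`` is a long table carrying alt_count, depth, n_chr, n_locus_t
    and is_indel per (variant_id, sample_id); ``purity`` maps sample to rho.
    Returns retained clusters (empty ones dropped, relabeled by descending
    mean centroid) and a per-variant assignment table with posterior
    probabilities of the modal cluster.
    """
    params = params or ClusteringParams()
    params.validate()
    if samples is None:
        samples = select_samples_for_clustering(purity)
    if not samples:
        raise ClusteringError("at least one included sample required")
    if variants.empty:
        raise ClusteringError("no variants to cluster")

    alt, dep, mult, n_t, ids = _pivot_counts(variants, samples)
    V, S = alt.shape
    if V == 0:
        raise ClusteringError("no variants to cluster")
    if V < 10:
        raise ClusteringError(f"too few variants to cluster ({V} < 10)")

    rho = np.array([purity[s] for s in samples])
    denom = rho[None, :] * n_t + 2.0 * (1 - rho[None, :])  # V x S
    slope = mult * rho[None, :] / denom  # f = slope * theta

    grid = np.arange(0.0, params.max_burden + 1e-9, params.grid_step)
    G = grid.size
    K = params.truncation
    rng = np.random.default_rng(params.seed)

    # Precompute log-likelihood tensor L[v, s, g] once (binomial kernel).
    f = np.clip(slope[:, :, None] * grid[None, None, :], 1e-9, 1 - 1e-9)
    L = alt[:, :, None] * np.log(f) + (dep - alt)[:, :, None] * np.log1p(-f)
    Lf = L.reshape(V, S * G)  # flattened view for fast gathers

    # prior pseudo-counts on the location grid (cluster_conc interpretation)
    log_prior = np.log(np.full(G, params.cluster_conc / G))
    log_prior -= log_prior.max()

    theta_idx = rng.integers(0, G, size=(K, S))
    z = rng.integers(0, K, size=V)

    kept_z = np.empty((params.n_iter - params.burn_in, V), dtype=np.int16)
    kept_theta = np.empty((params.n_iter - params.burn_in, K, S), dtype=np.float32)

    flat_offsets = np.arange(S) * G

    for it in range(params.n_iter):
        # --- stick-breaking weights given assignment counts
        counts = np.bincount(z, minlength=K)
        tail = np.concatenate([np.cumsum(counts[::-1])[::-1][1:], [0]])
        v_stick = rng.beta(1.0 + counts, params.conc_param + tail)
        v_stick = np.clip(v_stick, 1e-12, 1 - 1e-12)
        log_w = np.log(v_stick) + np.concatenate([[0.0], np.cumsum(np.log1p(-v_stick))[:-1]])

        # --- assignments: logp[v,k] = log w_k + sum_s L[v,s,theta_k[s]]
        gather = theta_idx + flat_offsets[None, :]  # K x S flat indices
        ll = Lf[:, gather.ravel()].reshape(V, K, S).sum(axis=2)
        logp = ll + log_w[None, :]
        gumb = rng.gumbel(size=(V, K))
        z = np.argmax(logp + gumb, axis=1)

        # --- locations: exact grid conditional per (cluster, sample)
        onehot = np.zeros((V, K))
        onehot[np.arange(V), z] = 1.0
        for s in range(S):
            Ls = onehot.T @ L[:, s, :]  # K x G
            post = Ls + log_prior[None, :]
            post -= post.max(axis=1, keepdims=True)
            gumb = rng.gumbel(size=(K, G))
            theta_idx[:, s] = np.argmax(post + gumb, axis=1)

        if it >= params.burn_in:
            j = it - params.burn_in
            kept_z[j] = z
            kept_theta[j] = grid[theta_idx]

    # --- summaries -----------------------------------------------------------
    n_kept = kept_z.shape[0]
    modal = np.empty(V, dtype=int)
    modal_post = np.empty(V)
    for v in range(V):
        c = np.bincount(kept_z[:, v], minlength=K)
        modal[v] = int(np.argmax(c))
        modal_post[v] = c[modal[v]] / n_kept

    centroids = np.median(kept_theta, axis=0)  # K x S

    # convergence heuristic: centroid drift of occupied components over the
    # last 10% of kept draws (empty sticks wander freely under the prior)
    tail_n = max(1, n_kept // 10)
    occ = np.unique(modal)
    drift = np.abs(
        np.median(kept_theta[-tail_n:, occ, :], axis=0) - centroids[occ]
    ).max()
    converged = bool(drift <= 0.05)
    if not converged:
        warnings.warn(f"possible non-convergence: centroid drift {drift:.3f} in final draws")

    is_indel = (
        variants[variants.sample_id == samples[0]]
        .set_index("variant_id")
        .is_indel.reindex(ids)
        .fillna(False)
        .astype(bool)
    )

    # Merge occupied components whose centroids are indistinguishable (within
    # merge_tol in every sample): the truncated sampler can park one subclone
    # across several sticks, which a peak-merging pass resolves -- the analogue
    # of reading clusters off a smoothed posterior density.
    occupied = sorted(set(modal), key=lambda k: -centroids[k].mean())
    group_of: dict[int, int] = {}
    group_centroid: dict[int, np.ndarray] = {}
    group_size: dict[int, int] = {}
    for k in occupied:
        size_k = int((modal == k).sum())
        placed = False
        for g in group_centroid:
            if np.all(np.abs(group_centroid[g] - centroids[k]) <= params.merge_tol):
                n0, n1 = group_size[g], size_k
                group_centroid[g] = (group_centroid[g] * n0 + centroids[k] * n1) / (n0 + n1)
                group_size[g] = n0 + n1
                group_of[k] = g
                placed = True
                break
        if not placed:
            group_of[k] = k
            group_centroid[k] = centroids[k].copy()
            group_size[k] = size_k
    merged = np.array([group_of[k] for k in modal])
    groups = sorted(group_centroid, key=lambda g: -group_centroid[g].mean())

    clusters: list[MutationCluster] = []
    assign_rows = []
    for new_id, k in enumerate(groups):
        members = ids[merged == k]
        clusters.append(
            MutationCluster(
                cluster_id=new_id,
                ccf_centroid={s: float(group_centroid[k][j]) for j, s in enumerate(samples)},
                n_mutations=len(members),
                n_indels=int(is_indel.loc[members].sum()),
                member_ids=list(members),
            )
        )
        for v in members:
            assign_rows.append((v, new_id))
    assignment = pd.DataFrame(assign_rows, columns=["variant_id", "cluster_id"]).set_index(
        "variant_id"
    )
    assignment["posterior"] = pd.Series(modal_post, index=ids)
    assignment.attrs["converged"] = converged
    return clusters, assignment.reset_index()


def filter_clusters(clusters: list[MutationCluster]) -> list[MutationCluster]:
    """Drop clusters with across-sample mean CCF < 0.02 or over 50% indels.

    Both boundaries are non-strict for retention: a cluster at mean CCF
    exactly 0.02, or with exactly 50% indels, is kept.
    """
    kept = []
    for c in clusters:
        mean_ccf = float(np.mean(list(c.ccf_centroid.values())))
        indel_frac = c.n_indels / c.n_mutations if c.n_mutations else 0.0
        if mean_ccf < 0.02 or indel_frac > 0.5:
            continue
        kept.append(c)
    if not kept:
        raise ClusteringError("all clusters removed by filters; no tree possible")
    return kept


def posthoc_sample_ccfs(
    clusters: list[MutationCluster],
    ccf_variants: pd.DataFrame,
    sample_id: str,
) -> dict[int, float]:
    """Cluster CCFs in a sample excluded from clustering (e.g. low-purity fluid).

    Computed post hoc as the mean per-variant CCF of the cluster's members in
    that sample.
    """
    sub = ccf_variants[ccf_variants.sample_id == sample_id].set_index("variant_id")
    out = {}
    for c in clusters:
        members = [m for m in c.member_ids if m in sub.index]
        out[c.cluster_id] = float(sub.loc[members, "ccf"].mean()) if members else float("nan")
    return out


def clusters_to_frame(clusters: list[MutationCluster]) -> pd.DataFrame:
    """Cluster table: one row per cluster, per-sample CCF columns."""
    rows = []
    for c in clusters:
        row = {"cluster_id": c.cluster_id, "n_mutations": c.n_mutations, "n_indels": c.n_indels}
        row.update({f"ccf_{s}": v for s, v in c.ccf_centroid.items()})
        rows.append(row)
    return pd.DataFrame(rows)
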