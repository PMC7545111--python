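"""Synthetic multi-sample tumor cohorts with known clonal evolution.

Generates patients that mimic lethal metastatic prostate cancer studied by deep
targeted sequencing: a branching clone tree rooted at the MRCA of all tumor
cells, ~10 samples per patient spread over prostate, local organs, distant
metastases and body fluids, targeted depth around 785x, and a few hundred to a
couple of thousand mutations per patient.  Every stochastic quantity is drawn
from a single seeded generator, so output is byte-identical for a fixed seed.

The generative model per variant v (cluster k, multiplicity m, locus copy
number ``n_t`` tumor / ``n_n`` normal) in sample s with purity ``rho``::

    E[VAF] = m * rho * ccf[s, k] / (rho * n_t + n_n * (1 - rho))
    alt ~ Binomial(depth, E[VAF]),   depth ~ NegBin(mean, dispersion)

Cancer cell fractions are assigned top-down on the tree so that, in every
sample, a parent's CCF always equals or exceeds the sum of its children's CCFs
(the subclone nesting the downstream inference relies on).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

AUTOSOMES = [f"chr{i}" for i in range(1, 23)]
CHROM_LEN = 100_000_000  # one synthetic segment-bearing chromosome arm each

TISSUE_CLASSES = ("prostate", "local_organ", "lymph_node", "bone", "visceral", "fluid")
DISTANT_CLASSES = ("lymph_node", "bone", "visceral")

_BASES = np.array(list("ACGT"))


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass
class SimConfig:
    """Parameters of one synthetic patient.

    Defaults are the study conditions the generator emulates: ~5 mutation
    clusters, depth 785x, a few hundred mutations per cluster, purities up to
    0.9, fluids as low-purity mixtures of metastatic compositions.
    """

    n_clusters: int = 5
    n_samples_tissue: int = 8
    n_samples_fluid: int = 2
    muts_per_cluster: float = 140.0
    mean_depth: float = 785.0
    depth_dispersion: float = 20.0  # negative-binomial size; larger = tighter
    purity_range: tuple[float, float] = (0.2, 0.9)
    fluid_purity_range: tuple[float, float] = (0.01, 0.2)
    ploidy_class: str = "diploid"  # or "tetraploid"
    clock_fraction: float = 0.25
    indel_fraction: float = 0.05
    dominant_lineage: bool = True
    polyclonal_rate: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_clusters < 1:
            raise ConfigurationError("n_clusters must be >= 1")
        if self.n_samples_tissue < 1:
            raise ConfigurationError("need at least one tissue sample")
        if self.n_samples_fluid < 0:
            raise ConfigurationError("n_samples_fluid must be >= 0")
        if self.muts_per_cluster <= 0:
            raise ConfigurationError("muts_per_cluster must be positive")
        if self.mean_depth <= 0:
            raise ConfigurationError("mean_depth must be positive")
        lo, hi = self.purity_range
        if not (0 < lo <= hi <= 1):
            raise ConfigurationError("purity_range must lie within (0, 1]")
        flo, fhi = self.fluid_purity_range
        if not (0 < flo <= fhi <= 1):
            raise ConfigurationError("fluid_purity_range must lie within (0, 1]")
        for name in ("clock_fraction", "indel_fraction", "polyclonal_rate"):
            x = getattr(self, name)
            if not (0 <= x <= 1):
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.ploidy_class not in ("diploid", "tetraploid"):
            raise ConfigurationError("ploidy_class must be 'diploid' or 'tetraploid'")


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated patient, used by recovery tests."""

    parent: dict[int, Optional[int]]  # cluster -> parent cluster, root -> None
    root: int
    clone_fraction: pd.DataFrame  # samples x clusters, fraction of ALL cells
    ccf_true: pd.DataFrame  # samples x clusters, CCF (tumor-cell units)
    purity_true: pd.Series  # per sample
    ploidy_true: pd.Series  # per sample
    assignment: pd.Series  # variant_id -> cluster
    multiplicity: pd.Series  # variant_id -> n_chr
    segments_true: pd.DataFrame
    dominant_branch: Optional[int]  # designated metastatic branch head cluster
    fluid_mixtures: dict[str, dict[str, float]] = field(default_factory=dict)

    def children(self, k: int) -> list[int]:
        return sorted(c for c, p in self.parent.items() if p == k)

    def descendants(self, k: int) -> set[int]:
        out, stack = set(), [k]
        while stack:
            n = stack.pop()
            for c in self.children(n):
                if c not in out:
                    out.add(c)
                    stack.append(c)
        return out

    def ancestors(self, k: int) -> list[int]:
        out = []
        p = self.parent[k]
        while p is not None:
            out.append(p)
            p = self.parent[p]
        return out


def _random_tree(n_clusters: int, rng: np.random.Generator) -> dict[int, Optional[int]]:
    """Random attachment with a forced truncal root (cluster 0).

    Attachment weight grows with node depth, which favors chains with
    occasional branches -- the shape of observed prostate-cancer clone trees.
    """
    parent: dict[int, Optional[int]] = {0: None}
    depth = {0: 0}
    for k in range(1, n_clusters):
        cands = list(parent)
        w = np.array([1.0 + depth[c] for c in cands])
        p = int(rng.choice(cands, p=w / w.sum()))
        parent[k] = p
        depth[k] = depth[p] + 1
    return parent


def _topo_order(parent: dict[int, Optional[int]]) -> list[int]:
    order, seen = [], set()

    def visit(k):
        if k in seen:
            return
        p = parent[k]
        if p is not None:
            visit(p)
        seen.add(k)
        order.append(k)

    for k in parent:
        visit(k)
    return order


def _assign_ccfs(
    parent: dict[int, Optional[int]],
    allowed: set[int],
    rng: np.random.Generator,
    presence_prob: float = 0.75,
    forced: Optional[set[int]] = None,
) -> dict[int, float]:
    """Top-down CCF assignment guaranteeing parent >= sum(children) per sample.

    Clusters in ``forced`` (e.g. the seeded metastatic lineage) are always
    present with a substantial share; other allowed children are present with
    ``presence_prob`` and draw their share from a gamma split.
    """
    forced = forced or set()
    ccf = {k: 0.0 for k in parent}
    ccf[0] = 1.0
    for k in _topo_order(parent):
        if ccf[k] <= 0:
            continue
        kids = [c for c, p in parent.items() if p == k and c in allowed]
        kids = [c for c in kids if c in forced or rng.random() < presence_prob]
        if not kids:
            continue
        # gamma weights for children plus a retained parent-own share;
        # forced children get a boosted weight so they stay at high CCF
        w = np.array(
            [rng.gamma(6.0, 1.0) if c in forced else rng.gamma(2.0, 1.0) for c in kids]
            + [rng.gamma(2.0, 1.0)]
        )
        w /= w.sum()
        for c, frac in zip(kids, w[:-1]):
            ccf[c] = ccf[k] * float(frac)
    return ccf


def _tissue_layout(n: int, rng: np.random.Generator) -> list[str]:
    """Split tissue samples over prostate / local organs / distant sites."""
    n_prost = max(1, n // 3)
    n_local = 1 if n >= 5 else 0
    n_dist = n - n_prost - n_local
    classes = ["prostate"] * n_prost + ["local_organ"] * n_local
    for i in range(n_dist):
        classes.append(DISTANT_CLASSES[i % len(DISTANT_CLASSES)])
    return classes


def _draw_contexts(
    n: int, clock: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Trinucleotide contexts, ref and alt for SNVs.

    Clock mutations are C>T in CpG context (middle C, 3' G).  Non-clock
    mutations avoid that context class.
    """
    five = _BASES[rng.integers(0, 4, size=n)]
    ref = np.empty(n, dtype="<U1")
    alt = np.empty(n, dtype="<U1")
    three = np.empty(n, dtype="<U1")
    for i in range(n):
        if clock[i]:
            ref[i], alt[i], three[i] = "C", "T", "G"
        else:
            r = _BASES[rng.integers(0, 4)]
            a = _BASES[rng.integers(0, 4)]
            while a == r:
                a = _BASES[rng.integers(0, 4)]
            t = _BASES[rng.integers(0, 4)]
            while r == "C" and a == "T" and t == "G":  # keep clock class exclusive
                t = _BASES[rng.integers(0, 4)]
            ref[i], alt[i], three[i] = r, a, t
    ctx = np.char.add(np.char.add(five, ref), three)
    return ctx, ref, alt


def _nb_depths(n: int, mean: float, size: float, rng: np.random.Generator) -> np.ndarray:
    p = size / (size + mean)
    d = rng.negative_binomial(size, p, size=n)
    return np.maximum(d, 1)


def _make_segments(ploidy_class: str, rng: np.random.Generator) -> pd.DataFrame:
    """Clonal copy-number segments: one segment per autosome."""
    base = 2 if ploidy_class == "diploid" else 4
    rows = []
    for chrom in AUTOSOMES:
        cn = base
        u = rng.random()
        if u < 0.15:
            cn = base - 1
        elif u < 0.30:
            cn = base + 1
        major = cn if (cn > 0 and rng.random() < 0.2) else max(1, int(np.ceil(cn / 2)))
        major = min(max(major, int(np.ceil(cn / 2))), cn) if cn > 0 else 0
        rows.append((chrom, 0, CHROM_LEN, cn, major, cn - major))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "cn_total", "major", "minor"])


def simulate_patient(
    config: SimConfig,
) -> tuple[SyntheticTruth, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate one patient.

    Returns ``(truth, variants, segments, metadata)`` where ``variants`` is a
    long table (one row per variant per sample) with read counts, ``segments``
    holds per-sample copy-number segments with CNVkit-style log-ratios, and
    ``metadata`` describes each sample (tissue class, purity class, timing).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    parent = _random_tree(config.n_clusters, rng)
    clusters = sorted(parent)
    segments = _make_segments(config.ploidy_class, rng)
    ploidy = float(
        (segments.cn_total * (segments.end - segments.start)).sum()
        / (segments.end - segments.start).sum()
    )

    truth = SyntheticTruth(
        parent=parent,
        root=0,
        clone_fraction=pd.DataFrame(),
        ccf_true=pd.DataFrame(),
        purity_true=pd.Series(dtype=float),
        ploidy_true=pd.Series(dtype=float),
        assignment=pd.Series(dtype=int),
        multiplicity=pd.Series(dtype=int),
        segments_true=segments,
        dominant_branch=None,
    )

    # designated metastatic branch: the child of the first multi-child node
    # (or of the root) with the largest subtree
    dominant = None
    if config.dominant_lineage and config.n_clusters > 1:
        first_branch = 0
        for k in _topo_order(parent):
            if len(truth.children(k)) >= 2:
                first_branch = k
                break
        kids = truth.children(first_branch) or truth.children(0)
        dominant = max(kids, key=lambda c: (len(truth.descendants(c)), -c))
    truth.dominant_branch = dominant

    # ---- samples ------------------------------------------------------------
    tissue_classes = _tissue_layout(config.n_samples_tissue, rng)
    sample_ids = [f"s{i:02d}_{tc}" for i, tc in enumerate(tissue_classes)]
    lo, hi = config.purity_range
    purities = {sid: float(rng.uniform(lo, hi)) for sid in sample_ids}

    ccf_rows = {}
    for sid, tc in zip(sample_ids, tissue_classes):
        if tc in DISTANT_CLASSES and dominant is not None:
            allowed = {0, dominant} | truth.descendants(dominant) | set(truth.ancestors(dominant))
            forced = {dominant} | set(truth.ancestors(dominant))
            ccf = _assign_ccfs(parent, allowed, rng, forced=forced)
        else:
            ccf = _assign_ccfs(parent, set(clusters), rng)
        # polyclonal seeding: a terminal cluster from a different branch, CCF < 0.5
        if tc in DISTANT_CLASSES and dominant is not None and rng.random() < config.polyclonal_rate:
            lineage = {dominant} | truth.descendants(dominant) | set(truth.ancestors(dominant))
            outside = [k for k in clusters if k not in lineage and not truth.descendants(k)]
            if outside:
                t = int(rng.choice(outside))
                chain = [t]
                d = truth.parent[t]
                while d is not None and ccf[d] <= 0:
                    chain.append(d)
                    d = truth.parent[d]
                if d is not None:
                    kids_sum = sum(ccf[c] for c in truth.children(d))
                    headroom = ccf[d] - kids_sum
                    if headroom > 0.12:
                        c2 = float(rng.uniform(0.1, min(0.45, headroom - 0.01)))
                        for node in chain:
                            ccf[node] = c2
        ccf_rows[sid] = ccf

    # fluids: convex mixtures of 1-3 distant-metastasis compositions
    met_ids = [s for s, t in zip(sample_ids, tissue_classes) if t in DISTANT_CLASSES]
    if not met_ids:  # fall back to any tissue sample
        met_ids = sample_ids
    flo, fhi = config.fluid_purity_range
    fluid_ids = []
    for j in range(config.n_samples_fluid):
        sid = f"f{j:02d}_fluid"
        fluid_ids.append(sid)
        n_mix = int(rng.integers(1, min(3, len(met_ids)) + 1))
        chosen = list(rng.choice(met_ids, size=n_mix, replace=False))
        w = rng.dirichlet(np.ones(n_mix))
        ccf = {k: float(sum(wi * ccf_rows[m][k] for wi, m in zip(w, chosen))) for k in clusters}
        ccf_rows[sid] = ccf
        purities[sid] = float(rng.uniform(flo, fhi))
        truth.fluid_mixtures[sid] = {m: float(wi) for m, wi in zip(chosen, w)}

    all_ids = sample_ids + fluid_ids
    all_classes = tissue_classes + ["fluid"] * len(fluid_ids)

    ccf_df = pd.DataFrame(
        {k: [ccf_rows[s][k] for s in all_ids] for k in clusters}, index=all_ids
    )
    clone_frac = ccf_df.copy()
    for k in clusters:
        for c in truth.children(k):
            clone_frac[k] = clone_frac[k] - ccf_df[c]
    clone_frac = clone_frac.clip(lower=0).mul(pd.Series(purities)[all_ids], axis=0)

    truth.clone_fraction = clone_frac
    truth.ccf_true = ccf_df
    truth.purity_true = pd.Series(purities)[all_ids]
    truth.ploidy_true = pd.Series(ploidy, index=all_ids)

    # ---- variants -----------------------------------------------------------
    n_per_cluster = rng.poisson(config.muts_per_cluster, size=config.n_clusters)
    n_per_cluster = np.maximum(n_per_cluster, 1)
    n_var = int(n_per_cluster.sum())
    cluster_of = np.repeat(clusters, n_per_cluster)

    seg_idx = rng.integers(0, len(segments), size=n_var)
    chrom = segments.chrom.values[seg_idx]
    pos = rng.integers(1, CHROM_LEN, size=n_var)
    is_indel = rng.random(n_var) < config.indel_fraction
    clock = (~is_indel) & (rng.random(n_var) < config.clock_fraction)
    ctx, ref, alt = _draw_contexts(n_var, clock, rng)

    cn_total = segments.cn_total.values[seg_idx]
    major = segments.major.values[seg_idx]
    # multiplicity: truncal variants on amplified segments may sit on all major
    # copies (pre-amplification); subclonal variants are single-copy
    mult = np.ones(n_var, dtype=int)
    truncal = cluster_of == 0
    on_amp = major > 1
    hit = truncal & on_amp & (rng.random(n_var) < 0.5)
    mult[hit] = major[hit]

    var_ids = np.array([f"v{i:05d}" for i in range(n_var)])
    # indel alleles: simple 1-bp insertion or deletion
    ref_out = ref.astype(object).copy()
    alt_out = alt.astype(object).copy()
    for i in np.where(is_indel)[0]:
        if rng.random() < 0.5:
            alt_out[i] = ref[i] + _BASES[rng.integers(0, 4)]
        else:
            ref_out[i] = ref[i] + _BASES[rng.integers(0, 4)]
            alt_out[i] = ref[i]

    truth.assignment = pd.Series(cluster_of, index=var_ids)
    truth.multiplicity = pd.Series(mult, index=var_ids)

    rows = []
    for sid in all_ids:
        rho = purities[sid]
        ccf_v = ccf_df.loc[sid].values[cluster_of]
        denom = rho * cn_total + 2.0 * (1 - rho)
        f = np.clip(mult * rho * ccf_v / denom, 0.0, 1.0)
        depth = _nb_depths(n_var, config.mean_depth, config.depth_dispersion, rng)
        alt_n = rng.binomial(depth, f)
        rows.append(
            pd.DataFrame(
                {
                    "variant_id": var_ids,
                    "sample_id": sid,
                    "chrom": chrom,
                    "pos": pos,
                    "ref": ref_out,
                    "alt": alt_out,
                    "alt_count": alt_n,
                    "depth": depth,
                    "is_indel": is_indel,
                    "context": ctx,
                }
            )
        )
    variants = pd.concat(rows, ignore_index=True)

    # per-sample segment tables with log-ratios from the mixture model
    seg_rows = []
    for sid in all_ids:
        rho = purities[sid]
        obs = (rho * segments.cn_total + 2 * (1 - rho)) / (rho * ploidy + 2 * (1 - rho))
        seg = segments.copy()
        seg.insert(0, "sample_id", sid)
        seg["logR"] = np.log2(obs.clip(lower=1e-6))
        seg_rows.append(seg)
    seg_df = pd.concat(seg_rows, ignore_index=True)

    metadata = pd.DataFrame(
        {
            "sample_id": all_ids,
            "tissue_class": all_classes,
            "preservation": ["frozen" if tc != "prostate" else "FFPE" for tc in all_classes],
            "days_prior_to_death": rng.integers(0, 1500, size=len(all_ids)),
            "purity_true": [purities[s] for s in all_ids],
        }
    )
    return truth, variants, seg_df, metadata


def simulate_cn_sample(
    rho: float,
    ploidy_class: str = "diploid",
    n_segments: int = 500,
    nonneutral_fraction: float = 0.35,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Forward-simulate one sample's segment log-ratios for ploidy fitting.

    Returns ``(sample_segments, reference_profile, true_mean_ploidy)``: the
    sample carries noisy log2 ratios of the tumor/normal mixture against the
    sample's average ploidy; the reference holds the true clonal integer copy
    numbers.  ``nonneutral_fraction`` controls how much of the genome deviates
    from the baseline copy number (2 or 4 by ploidy class).
    """
    rng = np.random.default_rng(seed)
    base = 2 if ploidy_class == "diploid" else 4
    seg_len = 1_000_000
    cn = np.full(n_segments, base)
    k = int(round(nonneutral_fraction * n_segments))
    idx = rng.choice(n_segments, size=k, replace=False)
    # balanced single-copy gain/loss spectrum with rare two-copy events, so a
    # diploid (tetraploid) genome keeps mean ploidy near 2 (4)
    cn[idx] = base + rng.choice([-2, -1, 1, 2], size=k, p=[0.05, 0.45, 0.45, 0.05])
    cn = np.maximum(cn, 0)
    psi = float(cn.mean())
    obs = (rho * cn + 2 * (1 - rho)) / (rho * psi + 2 * (1 - rho))
    logr = np.log2(np.clip(obs, 1e-6, None)) + rng.normal(0, noise_sd, size=n_segments)
    chroms = [AUTOSOMES[i % len(AUTOSOMES)] for i in range(n_segments)]
    starts = [(i // len(AUTOSOMES)) * seg_len for i in range(n_segments)]
    sample = pd.DataFrame(
        {"chrom": chroms, "start": starts, "end": np.array(starts) + seg_len, "logR": logr}
    )
    reference = pd.DataFrame(
        {"chrom": chroms, "start": starts, "end": np.array(starts) + seg_len, "cn_total": cn}
    )
    return sample, reference, psi


def make_noise_fluid_sample(
    n_variants: int, depth: float, error_rate: float, seed: int
) -> pd.DataFrame:
    """Pure-noise body-fluid read counts: alt ~ Binomial(depth, error_rate).

    Emulates fluid samples showing only a sequencing-noise background, with no
    tumor signal at any cluster; used to exercise the noise-vs-signal
    qualification rule.
    """
    if n_variants < 0:
        raise ConfigurationError("n_variants must be >= 0")
    rng = np.random.default_rng(seed)
    if n_variants == 0:
        return pd.DataFrame(
            columns=["variant_id", "sample_id", "chrom", "pos", "ref", "alt",
                     "alt_count", "depth", "is_indel", "context"]
        )
    d = _nb_depths(n_variants, depth, 20.0, rng)
    alt_n = rng.binomial(d, error_rate)
    clock = np.zeros(n_variants, dtype=bool)
    ctx, ref, alt = _draw_contexts(n_variants, clock, rng)
    return pd.DataFrame(
        {
            "variant_id": [f"v{i:05d}" for i in range(n_variants)],
            "sample_id": "noise_fluid",
            "chrom": "chr1",
            "pos": np.arange(1, n_variants + 1),
            "ref": ref,
            "alt": alt,
            "alt_count": alt_n,
            "depth": d,
            "is_indel": False,
            "context": ctx,
        }
    )
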