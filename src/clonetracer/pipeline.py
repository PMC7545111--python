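"""End-to-end pipeline: filters -> purity -> CCF -> clustering -> fine-tune ->
re-CCF -> tree -> dissemination -> timing.

Each stage writes its outputs into the run directory, and a manifest records
every effective parameter, the seed and the completed stages, so two runs
with identical config and seed produce identical tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as ctio
from .clustering import (
    ClusteringParams,
    MutationCluster,
    clusters_to_frame,
    filter_clusters,
    posthoc_sample_ccfs,
    run_dp_clustering,
    select_samples_for_clustering,
)
from .dissemination import (
    DISTANT_CLASSES,
    classify_seeding,
    compose_sample,
    detect_intermixture,
    detect_subclones_in_fluid,
    find_dominant_lineage,
)
from .phylogeny import CloneTree, TreeBuildParams, enumerate_trees, select_tree, to_newick
from .timing import count_cpg_transitions, label_phases, phase_durations
from .variants import ccf_table, estimate_purity, fine_tune_purity

log = logging.getLogger("clonetracer")

STAGES = [
    "filters",
    "purity",
    "ccf",
    "clustering",
    "fine_tune",
    "re_ccf",
    "tree",
    "dissemination",
    "timing",
]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: str):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    variants: str | pd.DataFrame
    segments: str | pd.DataFrame
    metadata: str | pd.DataFrame
    output_dir: str = "results/run"
    seed: int = 0
    ploidy_class: str = "diploid"
    purity_threshold: float = 0.15
    presence_threshold: float = 0.02
    clustering: ClusteringParams = field(default_factory=ClusteringParams)
    tree: TreeBuildParams = field(default_factory=TreeBuildParams)
    log_level: str = "INFO"

    def validate(self) -> None:
        self.clustering.validate()
        self.tree.validate()
        for attr in ("variants", "segments", "metadata"):
            v = getattr(self, attr)
            if isinstance(v, str) and not Path(v).exists():
                raise FileNotFoundError(f"{attr} input does not exist: {v}")


@dataclass
class PipelineResult:
    purity: dict[str, float]
    purity_final: dict[str, float]
    clusters: list[MutationCluster]
    cluster_table: pd.DataFrame
    assignment: pd.DataFrame
    ccf_variants: pd.DataFrame
    tree: CloneTree
    n_admissible_trees: int
    compositions: list
    intermixture: Optional[pd.DataFrame]
    seeding_calls: list
    seeding_summary: dict
    dominant_lineage: Optional[int]
    fluid_detection: dict[str, pd.DataFrame]
    timing: Optional[pd.DataFrame]
    manifest: dict


def _load(x, reader):
    return reader(x) if isinstance(x, str) else x.copy()


def estimate_cohort_purity(
    variants: pd.DataFrame,
    segments: Optional[pd.DataFrame],
    metadata: Optional[pd.DataFrame],
    ploidy_class: str = "diploid",
) -> dict[str, float]:
    """Blind per-sample purity for a patient's cohort of samples.

    Pools a truncal proxy (SNVs with supporting reads in every tissue sample)
    restricted to copy-neutral segments, then inverts the KDE mode of its
    VAFs.  Samples with no usable VAFs (pure noise fluids) get purity 0.01.
    """
    if metadata is not None:
        tissue_ids = set(metadata.sample_id[metadata.tissue_class != "fluid"])
    else:
        tissue_ids = set(variants.sample_id.unique())
    snvs = variants[~variants.is_indel.astype(bool)]
    called = snvs[(snvs.alt_count >= 2) & (snvs.sample_id.isin(tissue_ids))]
    n_called = called.groupby("variant_id").sample_id.nunique()
    truncal_proxy = set(n_called.index[n_called >= max(1, len(tissue_ids))])
    baseline_cn = 2 if ploidy_class == "diploid" else 4
    mode_sel = "rightmost" if ploidy_class == "diploid" else "global"
    seg_by_sample = (
        {s: g for s, g in segments.groupby("sample_id")}
        if segments is not None and "sample_id" in segments.columns
        else {}
    )
    purity: dict[str, float] = {}
    for sid, g in variants.groupby("sample_id"):
        snv = g[(~g.is_indel.astype(bool)) & (g.depth > 0)]
        pool = snv[snv.variant_id.isin(truncal_proxy)]
        segs = seg_by_sample.get(sid)
        if segs is not None and not pool.empty:
            neutral = pd.Series(False, index=pool.index)
            for _, seg in segs[segs.cn_total == baseline_cn].iterrows():
                neutral |= (
                    (pool.chrom == seg.chrom)
                    & (seg.start < pool.pos)
                    & (pool.pos <= seg.end)
                )
            if neutral.sum() >= 20:
                pool = pool[neutral]
        if len(pool) < 20:
            pool = snv
        vafs = (pool.alt_count / pool.depth).values
        try:
            est = estimate_purity(vafs, ploidy_class, mode_selection=mode_sel)
            purity[sid] = est.rho
        except Exception:  # noqa: BLE001 - fluid/noise samples may have no usable VAFs
            purity[sid] = 0.01
    return purity


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "parameters": {
            "ploidy_class": config.ploidy_class,
            "purity_threshold": config.purity_threshold,
            "presence_threshold": config.presence_threshold,
            "clustering": dataclasses.asdict(config.clustering),
            "tree": dataclasses.asdict(config.tree),
        },
        "stages": [],
    }

    def complete(stage: str, t0: float) -> None:
        manifest["stages"].append({"stage": stage, "seconds": round(time.time() - t0, 3)})
        log.info("stage %s done (%.2fs)", stage, time.time() - t0)

    def fail(stage: str, exc: Exception):
        manifest["failed_stage"] = stage
        manifest["cause"] = str(exc)
        ctio.write_json(manifest, outdir / "manifest.json")
        raise PipelineError(stage, str(exc)) from exc

    variants = _load(config.variants, ctio.read_variants)
    segments = _load(config.segments, ctio.read_segments)
    metadata = _load(config.metadata, lambda p: pd.read_csv(p, sep="\t"))
    tissue_of = dict(zip(metadata.sample_id, metadata.tissue_class))

    # ---- stage 1: filters ---------------------------------------------------
    t0 = time.time()
    try:
        calls = variants[["variant_id", "sample_id"]].copy()
        calls["called"] = variants.alt_count >= 2
        from .variants import filter_recurrent_calls

        keep = filter_recurrent_calls(calls)
        variants = variants[variants.variant_id.isin(keep)].reset_index(drop=True)
        if variants.empty:
            raise ValueError("no variant called in two or more samples")
    except Exception as e:  # noqa: BLE001
        fail("filters", e)
    complete("filters", t0)

    # ---- stage 2: purity ----------------------------------------------------
    # Truncal mutations are, by definition, present in every tumor sample, so
    # the VAF mode is taken over a truncal proxy: SNVs with supporting reads
    # in all tissue samples, restricted to copy-neutral segments (variants on
    # gained or lost segments sit at shifted VAF levels that smear the clonal
    # peak).  The rightmost substantial KDE peak is used for diploid samples
    # since no cluster can sit above the clonal peak; for tetraploid samples
    # multiplicity-2 shoulders sit above it, so the global mode is kept there.
    t0 = time.time()
    purity: dict[str, float] = {}
    try:
        purity = estimate_cohort_purity(variants, segments, metadata, config.ploidy_class)
    except Exception as e:  # noqa: BLE001
        fail("purity", e)
    complete("purity", t0)

    # ---- stage 3: CCF -------------------------------------------------------
    t0 = time.time()
    try:
        ccf_vars = ccf_table(variants, purity, segments, config.ploidy_class)
    except Exception as e:  # noqa: BLE001
        fail("ccf", e)
    complete("ccf", t0)

    # ---- stage 4: clustering ------------------------------------------------
    t0 = time.time()
    try:
        params = dataclasses.replace(config.clustering, seed=config.seed)
        included = select_samples_for_clustering(purity, config.purity_threshold)
        clusters, assignment = run_dp_clustering(ccf_vars, purity, params, included)
    except Exception as e:  # noqa: BLE001
        fail("clustering", e)
    complete("clustering", t0)

    # ---- stage 5: fine-tune purity to center the truncal cluster at CCF 1 ---
    t0 = time.time()
    purity_final = dict(purity)
    try:
        assign = assignment.set_index("variant_id").cluster_id
        truncal_id = max(
            clusters, key=lambda c: float(np.mean(list(c.ccf_centroid.values())))
        ).cluster_id
        truncal_members = [c for c in clusters if c.cluster_id == truncal_id][0].member_ids
        for sid in included:
            sub = ccf_vars[
                (ccf_vars.sample_id == sid) & (ccf_vars.variant_id.isin(truncal_members))
            ]
            t_ccf = float(sub.ccf.mean())
            if t_ccf > 0:
                from .variants import PurityEstimate

                est = PurityEstimate(rho=purity[sid], ploidy=2.0, method="kde_mode")
                purity_final[sid] = fine_tune_purity(est, t_ccf).rho
    except Exception as e:  # noqa: BLE001
        fail("fine_tune", e)
    complete("fine_tune", t0)

    # ---- stage 6: re-compute CCFs once with fine-tuned purities -------------
    t0 = time.time()
    try:
        ccf_vars = ccf_table(variants, purity_final, segments, config.ploidy_class)
        # cluster centroids after fine-tuning: mean member CCF per sample
        for c in clusters:
            for sid in list(c.ccf_centroid):
                sub = ccf_vars[
                    (ccf_vars.sample_id == sid) & (ccf_vars.variant_id.isin(c.member_ids))
                ]
                c.ccf_centroid[sid] = float(sub.ccf.mean())
        clusters = filter_clusters(clusters)
    except Exception as e:  # noqa: BLE001
        fail("re_ccf", e)
    complete("re_ccf", t0)

    # ---- stage 7: clone tree ------------------------------------------------
    t0 = time.time()
    try:
        sample_order = sorted(included)
        ccf_matrix = np.array(
            [[c.ccf_centroid[s] for s in sample_order] for c in clusters]
        )
        ids = [c.cluster_id for c in clusters]
        trees = enumerate_trees(ccf_matrix, config.tree, cluster_ids=ids)
        mean_ccf = {c.cluster_id: float(np.mean(list(c.ccf_centroid.values()))) for c in clusters}
        tree = select_tree(trees, mean_ccf=mean_ccf)
    except Exception as e:  # noqa: BLE001
        fail("tree", e)
    complete("tree", t0)

    # ---- stage 8: dissemination --------------------------------------------
    t0 = time.time()
    try:
        retained = {c.cluster_id: c for c in clusters}
        compositions = []
        all_sample_ccfs: dict[str, dict[int, float]] = {}
        for sid in metadata.sample_id:
            tc = tissue_of.get(sid, "prostate")
            if sid in included:
                cc = {cid: retained[cid].ccf_centroid[sid] for cid in retained}
            else:
                cc = posthoc_sample_ccfs(list(retained.values()), ccf_vars, sid)
            all_sample_ccfs[sid] = cc
            compositions.append(
                compose_sample(sid, tc, cc, tree, config.presence_threshold)
            )
        tissue_comps = [c for c in compositions if c.tissue_class != "fluid"]
        has_local = any(c.tissue_class in ("prostate", "local_organ") for c in tissue_comps)
        intermixture = detect_intermixture(tissue_comps, tree) if has_local else None
        has_mets = any(c.tissue_class in DISTANT_CLASSES for c in tissue_comps)
        if has_mets:
            seeding_calls, seeding_summary = classify_seeding(tissue_comps, tree)
            dominant = find_dominant_lineage(tissue_comps, tree)
        else:
            seeding_calls, seeding_summary, dominant = [], {}, None
        memberships = {cid: c.member_ids for cid, c in retained.items()}
        fluid_detection = {}
        for sid in metadata.sample_id[metadata.tissue_class == "fluid"]:
            fl = ccf_vars[ccf_vars.sample_id == sid]
            if not fl.empty:
                fluid_detection[sid] = detect_subclones_in_fluid(fl, memberships)
    except Exception as e:  # noqa: BLE001
        fail("dissemination", e)
    complete("dissemination", t0)

    # ---- stage 9: timing ----------------------------------------------------
    t0 = time.time()
    timing_df = None
    try:
        seeded = set()
        for c in tissue_comps:
            if c.tissue_class in DISTANT_CLASSES:
                seeded |= set(c.clusters_present)
        phases = label_phases(tree, seeded)
        uniq = variants.drop_duplicates("variant_id")
        counts, _ = count_cpg_transitions(
            uniq, assignment.set_index("variant_id").cluster_id, phases
        )
        if sum(c.n_clock for c in counts) > 0:
            timing_df = phase_durations(counts)
    except Exception as e:  # noqa: BLE001
        fail("timing", e)
    complete("timing", t0)

    # ---- outputs ------------------------------------------------------------
    cluster_table = clusters_to_frame(clusters)
    ctio.write_tsv(cluster_table, outdir / "clusters.tsv")
    ctio.write_tsv(assignment, outdir / "assignments.tsv")
    ctio.write_tsv(
        ccf_vars[["variant_id", "sample_id", "vaf", "n_chr", "n_mut", "ccf"]],
        outdir / "ccf.tsv",
    )
    ctio.write_json(
        {"root": tree.root, "parent": {str(k): v for k, v in tree.parent.items()},
         "n_admissible": len(trees)},
        outdir / "tree.json",
    )
    (outdir / "tree.nwk").write_text(
        to_newick(tree, {c.cluster_id: c.n_mutations for c in clusters}) + "\n"
    )
    if timing_df is not None:
        ctio.write_tsv(timing_df, outdir / "timing.tsv")
    ctio.write_json(manifest, outdir / "manifest.json")

    return PipelineResult(
        purity=purity,
        purity_final=purity_final,
        clusters=clusters,
        cluster_table=cluster_table,
        assignment=assignment,
        ccf_variants=ccf_vars,
        tree=tree,
        n_admissible_trees=len(trees),
        compositions=compositions,
        intermixture=intermixture,
        seeding_calls=seeding_calls,
        seeding_summary=seeding_summary,
        dominant_lineage=dominant,
        fluid_detection=fluid_detection,
        timing=timing_df,
        manifest=manifest,
    )
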