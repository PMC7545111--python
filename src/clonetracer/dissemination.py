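"""Lineage-level analyses over a selected clone tree.

Covers four questions asked of a patient's tree and per-sample cluster CCFs:
which subclones each tissue region contains (and which are terminal there),
whether lineages are spatially intermixed in the prostate and local organs,
whether distant metastases were seeded mono- or polyclonally, whether one
lineage dominates all metastases, and how well body-fluid DNA represents the
tissue subclones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .phylogeny import CloneTree

LOCAL_CLASSES = ("prostate", "local_organ")
DISTANT_CLASSES = ("lymph_node", "bone", "visceral")


@dataclass
class SampleComposition:
    sample_id: str
    tissue_class: str
    clusters_present: dict[int, float]  # cluster -> CCF
    terminal_clusters: list[int]
    proportion_class: dict[int, str]  # cluster -> "high" | "low"


@dataclass
class SeedingCall:
    sample_id: str
    mode: str  # monoclonal | polyclonal | indeterminate
    contributing_branches: list[int] = field(default_factory=list)


def compose_sample(
    sample_id: str,
    tissue_class: str,
    cluster_ccfs: dict[int, float],
    tree: CloneTree,
    presence_threshold: float = 0.02,
) -> SampleComposition:
    """Which subclones a sample contains.

    A cluster is present iff its CCF is at least ``presence_threshold``;
    terminal clusters are present clusters with no present descendant; a
    present cluster is "high proportion" iff its CCF strictly exceeds 0.5.
    """
    present = {
        k: float(v)
        for k, v in cluster_ccfs.items()
        if np.isfinite(v) and v >= presence_threshold
    }
    terminal = [
        k for k in present if not any(d in present for d in tree.descendants(k))
    ]
    prop = {k: ("high" if v > 0.5 else "low") for k, v in present.items()}
    return SampleComposition(
        sample_id=sample_id,
        tissue_class=tissue_class,
        clusters_present=present,
        terminal_clusters=sorted(terminal),
        proportion_class=prop,
    )


def _lineage_count(comp: SampleComposition, tree: CloneTree) -> int:
    """Number of distinct maximal branches represented: terminal clusters are
    pairwise incomparable, so each identifies one maximal branch."""
    return len(comp.terminal_clusters)


def detect_intermixture(
    compositions: list[SampleComposition], tree: CloneTree
) -> pd.DataFrame:
    """Per prostate/local sample: count of distinct lineages present, and an
    intermixture flag (two or more lineages spatially co-occurring)."""
    local = [c for c in compositions if c.tissue_class in LOCAL_CLASSES]
    if not local:
        raise ValueError("no prostate or local-organ sample supplied")
    rows = [
        {
            "sample_id": c.sample_id,
            "lineage_count": _lineage_count(c, tree),
            "intermixed": _lineage_count(c, tree) >= 2,
        }
        for c in local
    ]
    return pd.DataFrame(rows)


def classify_seeding(
    compositions: list[SampleComposition], tree: CloneTree
) -> tuple[list[SeedingCall], dict]:
    """Mono- vs polyclonal seeding of each distant metastasis.

    A metastasis is polyclonal iff its present clusters span two or more
    branches in no ancestor-descendant relation (>= 2 terminal clusters).
    Patient-level metastasis-to-metastasis polyclonal seeding is reported as
    indeterminate when only one metastatic sample exists.
    """
    mets = [c for c in compositions if c.tissue_class in DISTANT_CLASSES]
    if not mets:
        raise ValueError("no distant metastatic sample supplied")
    calls = []
    for c in mets:
        if not c.clusters_present:
            calls.append(SeedingCall(c.sample_id, "indeterminate"))
            continue
        mode = "polyclonal" if len(c.terminal_clusters) >= 2 else "monoclonal"
        calls.append(SeedingCall(c.sample_id, mode, list(c.terminal_clusters)))
    summary = {
        "n_metastases": len(mets),
        "n_polyclonal": sum(1 for c in calls if c.mode == "polyclonal"),
        "patient_polyclonal_seeding": (
            "indeterminate"
            if len(mets) < 2
            else ("yes" if any(c.mode == "polyclonal" for c in calls) else "no")
        ),
    }
    return calls, summary


def find_dominant_lineage(
    compositions: list[SampleComposition], tree: CloneTree
) -> Optional[int]:
    """The deepest tree node whose branch is represented in every metastasis.

    A node qualifies when every distant metastasis contains the node itself or
    one of its descendants.  Returns the deepest qualifying non-truncal node
    (the head of the shared metastatic lineage), or None when metastases share
    nothing below the trunk -- i.e. independent seedings from separate
    branches.
    """
    mets = [c for c in compositions if c.tissue_class in DISTANT_CLASSES]
    if not mets:
        raise ValueError("no distant metastatic sample supplied")
    present_sets = [set(c.clusters_present) for c in mets]

    def depth(k: int) -> int:
        return len(tree.ancestors(k))

    best, best_depth = None, 0
    for k in tree.parent:
        if k == tree.root:
            continue
        branch = {k} | tree.descendants(k)
        if all(ps & branch for ps in present_sets):
            d = depth(k)
            if best is None or d > best_depth or (d == best_depth and k < best):
                best, best_depth = k, d
    return best


def detect_subclones_in_fluid(
    fluid_ccfs: pd.DataFrame,
    memberships: dict[int, list],
    min_alt_reads: int = 2,
) -> pd.DataFrame:
    """Which tissue-defined subclones are detectable in a body-fluid sample.

    ``fluid_ccfs`` holds the fluid sample's per-variant rows (variant_id,
    alt_count, ccf, is_indel).  Per cluster: detected fraction = share of the
    cluster's SNV members with positive CCF in the fluid -- operationalized as
    at least ``min_alt_reads`` supporting reads, guarding against single-read
    sequencing error.  A cluster is detected iff that fraction is >= 0.5; its
    fluid CCF is the mean over the detected members.  Clusters with no SNV
    members are flagged undefined.
    """
    sub = fluid_ccfs.set_index("variant_id")
    rows = []
    for cid, members in memberships.items():
        snvs = [
            m for m in members if m in sub.index and not bool(sub.loc[m, "is_indel"])
        ]
        if not snvs:
            rows.append(
                {"cluster_id": cid, "n_snvs": 0, "detected_fraction": np.nan,
                 "detected": False, "fluid_ccf": np.nan, "undefined": True}
            )
            continue
        hit = sub.loc[snvs, "alt_count"].values >= min_alt_reads
        frac = float(hit.mean())
        detected = frac >= 0.5
        fluid_ccf = float(sub.loc[np.array(snvs)[hit], "ccf"].mean()) if hit.any() else 0.0
        rows.append(
            {"cluster_id": cid, "n_snvs": len(snvs), "detected_fraction": frac,
             "detected": detected, "fluid_ccf": fluid_ccf if detected else np.nan,
             "undefined": False}
        )
    return pd.DataFrame(rows)


def match_fluid_to_tissue(
    fluid_detection: pd.DataFrame,
    tissue_ccfs: dict[str, dict[int, float]],
) -> pd.DataFrame:
    """Rank tissue samples by similarity of subclonal composition to a fluid.

    Similarity is 1 minus the normalized L1 distance over the union of
    detected clusters (normalized by the sum of element-wise maxima, so an
    identical composition scores 1 and disjoint compositions score 0).
    """
    det = fluid_detection[fluid_detection.detected]
    if det.empty:
        raise ValueError("no clusters detected in fluid; matching impossible")
    fluid_vec = dict(zip(det.cluster_id, det.fluid_ccf))
    rows = []
    for sid, tvec in tissue_ccfs.items():
        keys = sorted(set(fluid_vec) | {k for k, v in tvec.items() if v and v > 0})
        a = np.array([fluid_vec.get(k, 0.0) for k in keys])
        b = np.array([tvec.get(k, 0.0) if np.isfinite(tvec.get(k, 0.0)) else 0.0 for k in keys])
        denom = np.maximum(a, b).sum()
        sim = 1.0 - (np.abs(a - b).sum() / denom if denom > 0 else 1.0)
        rows.append({"sample_id": sid, "similarity": float(sim)})
    out = pd.DataFrame(rows).sort_values("similarity", ascending=False, kind="mergesort")
    return out.reset_index(drop=True)
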