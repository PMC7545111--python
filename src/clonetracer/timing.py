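"""Chronological timing of disease phases from clock-like mutations.

C>T substitutions at CpG dinucleotides accrue at a near-constant rate over a
patient's lifetime (the deamination clock, mutational signature 1), so the
share of such mutations on each segment of the clone tree is a proxy for the
share of elapsed time.  Tree segments are grouped into three phases: the
trunk until the first intra-prostatic branch, the stretch between the first
branch and the first metastatic seeding event, and everything after seeding
until sampling.  Raw clock-mutation counts replace signature deconvolution,
which is unstable at low mutation counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd
from scipy import stats

from .phylogeny import CloneTree

PHASES = ("trunk_to_branch", "branch_to_seeding", "seeding_to_sampling")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class PhaseCounts:
    phase: str
    n_clock: int
    n_total: int


def is_clock_mutation(ref: str, alt: str, context: str) -> bool:
    """C>T at a CpG site, counted on either strand.

    Forward strand: middle base C, alt T, 3' neighbor G.  The reverse-strand
    representation (G>A with 5' neighbor C) canonicalizes to the same event by
    reverse complement.
    """
    if len(ref) != 1 or len(alt) != 1 or len(context) != 3:
        return False
    if ref == "C" and alt == "T":
        return context[2] == "G"
    if ref == "G" and alt == "A":
        return context[0] == "C"
    return False


def label_phases(
    tree: CloneTree, seeded_clusters: set[int]
) -> dict[int, str]:
    """Assign each cluster to a disease phase.

    First branch = shallowest node with two or more children among retained
    clusters; first seeding = shallowest non-trunk node whose cluster is
    present in at least one distant metastasis (the trunk itself is present
    in every metastasis by definition, so it cannot date the seeding event).
    Clusters on side branches that never seeded any metastasis are labeled
    'off_metastatic_lineage' and reported separately.
    """
    def depth(k: int) -> int:
        return len(tree.ancestors(k))

    branch_nodes = [k for k in tree.parent if len(tree.children(k)) >= 2]
    first_branch = min(branch_nodes, key=depth) if branch_nodes else None

    if first_branch is None:
        trunk = {k for k in tree.parent if tree.parent[k] is None}
    else:
        trunk = {first_branch} | set(tree.ancestors(first_branch))
    seeded = [k for k in tree.parent if k in seeded_clusters and k not in trunk]
    first_seed = min(seeded, key=depth) if seeded else None

    labels: dict[int, str] = {}
    for k in tree.parent:
        anc_self = {k} | set(tree.ancestors(k))
        if first_branch is None:
            on_trunk = tree.parent[k] is None
        else:
            on_trunk = k == first_branch or k in set(tree.ancestors(first_branch))
        if on_trunk:
            labels[k] = "trunk_to_branch"
            continue
        if first_seed is not None:
            if k == first_seed or (k in set(tree.ancestors(first_seed))):
                labels[k] = "branch_to_seeding"
            elif first_seed in anc_self:
                labels[k] = "seeding_to_sampling"
            else:
                labels[k] = "off_metastatic_lineage"
        else:
            labels[k] = "off_metastatic_lineage"
    return labels


def count_cpg_transitions(
    variants: pd.DataFrame,
    assignment: pd.Series,
    phase_labels: dict[int, str],
) -> tuple[list[PhaseCounts], int]:
    """Clock-mutation counts per phase.

    ``variants`` holds one row per variant (variant_id, ref, alt, context,
    is_indel); ``assignment`` maps variant_id to cluster.  Variants with
    missing contexts are skipped and their count returned alongside.
    """
    per_phase = {p: [0, 0] for p in PHASES}
    skipped = 0
    uniq = variants.drop_duplicates("variant_id").set_index("variant_id")
    for vid, row in uniq.iterrows():
        if vid not in assignment.index:
            continue
        phase = phase_labels.get(assignment.loc[vid])
        if phase not in per_phase:
            continue
        ctx = row.get("context")
        if not isinstance(ctx, str) or len(ctx) != 3:
            skipped += 1
            continue
        if row.get("is_indel", False):
            per_phase[phase][1] += 1
            continue
        per_phase[phase][1] += 1
        if is_clock_mutation(str(row.ref), str(row.alt), ctx):
            per_phase[phase][0] += 1
    counts = [PhaseCounts(p, c[0], c[1]) for p, c in per_phase.items()]
    return counts, skipped


def phase_durations(
    counts: list[PhaseCounts], alpha: float = 0.05
) -> pd.DataFrame:
    """Proportion of elapsed time per phase with exact binomial intervals.

    Under the constant-rate clock assumption the expected clock count of a
    phase is proportional to its duration, so proportions of total clock
    count estimate proportions of time.  Each phase gets a Clopper-Pearson
    interval for its share of the total.
    """
    total = sum(c.n_clock for c in counts)
    if total == 0:
        raise ValueError("no clock mutations: timing is undefined")
    rows = []
    for c in counts:
        lo, hi = _clopper_pearson(c.n_clock, total, alpha)
        rows.append(
            {
                "phase": c.phase,
                "n_clock": c.n_clock,
                "n_total": c.n_total,
                "proportion": c.n_clock / total,
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    return pd.DataFrame(rows)


def _clopper_pearson(k: int, n: int, alpha: float) -> tuple[float, float]:
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi
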