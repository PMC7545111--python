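#!/usr/bin/env python
"""Disease-phase timing and capture-panel design on the cohort.

Timing: per patient, count C>T-at-CpG clock mutations on each tree phase
(trunk to first branch, branch to first seeding, seeding to sampling) and
report the proportions of elapsed time with exact binomial intervals.

Panel: re-derive a targeted capture panel from each patient's clustered
variants (per-cluster sampling, 60/110 nt flanks, merged regions), the
procedure that produced the deep-sequencing design.  Writes
results/timing.tsv and results/panel_summary.tsv.
"""

import json
from pathlib import Path

import pandas as pd

from clonetracer.panel import design_panel
from clonetracer.phylogeny import CloneTree
from clonetracer.timing import count_cpg_transitions, label_phases, phase_durations

COHORT = Path("results/cohort")
RUNS = Path("results/runs")


def main() -> None:
    timing_rows, panel_rows = [], []
    for pdir in sorted(COHORT.iterdir()):
        run = RUNS / pdir.name
        if not (run / "tree.json").exists():
            continue
        tree_obj = json.loads((run / "tree.json").read_text())
        tree = CloneTree(
            root=int(tree_obj["root"]),
            parent={int(k): v for k, v in tree_obj["parent"].items()},
        )
        variants = pd.read_csv(pdir / "variants.tsv", sep="\t")
        assign = (
            pd.read_csv(run / "assignments.tsv", sep="\t")
            .set_index("variant_id")
            .cluster_id
        )
        meta = pd.read_csv(pdir / "metadata.tsv", sep="\t")
        clusters = pd.read_csv(run / "clusters.tsv", sep="\t")
        met_cols = [
            f"ccf_{s}" for s, t in zip(meta.sample_id, meta.tissue_class)
            if t in ("lymph_node", "bone", "visceral") and f"ccf_{s}" in clusters.columns
        ]
        seeded = set(
            clusters.cluster_id[(clusters[met_cols] >= 0.02).any(axis=1)]
        ) if met_cols else set()
        phases = label_phases(tree, seeded)
        counts, skipped = count_cpg_transitions(variants, assign, phases)
        try:
            dur = phase_durations(counts)
            dur.insert(0, "patient", pdir.name)
            timing_rows.append(dur)
            top = dur.set_index("phase").proportion
            print(f"{pdir.name}: time split trunk/branch/metastatic = "
                  + "/".join(f"{top.get(p, 0):.2f}" for p in
                             ("trunk_to_branch", "branch_to_seeding", "seeding_to_sampling")))
        except ValueError:
            print(f"{pdir.name}: no clock mutations on phased lineage")

        panel = design_panel(variants, assign, quota=50, seed=1)
        panel_rows.append(
            {"patient": pdir.name, "n_targets": len(panel.targets),
             "n_regions": len(panel.regions),
             "panel_bp": int((panel.regions.end - panel.regions.start).sum())}
        )
    if timing_rows:
        pd.concat(timing_rows).to_csv(Path("results") / "timing.tsv", sep="\t", index=False)
    pd.DataFrame(panel_rows).to_csv(Path("results") / "panel_summary.tsv",
                                    sep="\t", index=False)
    print("\npanel summary:")
    print(pd.DataFrame(panel_rows).to_string(index=False))


if __name__ == "__main__":
    main()
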