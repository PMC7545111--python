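#!/usr/bin/env python
"""Body-fluid representation of tissue subclones.

For each patient's fluid samples: apply the detection rule (a subclone is
detected when at least half of its SNVs show supporting reads), build the
clusters x fluids detection matrix, and rank tissue samples by similarity of
subclonal composition to each fluid.  Writes results/fluid_detection.tsv and
results/fluid_matching.tsv.
"""

import json
from pathlib import Path

import pandas as pd

from clonetracer.dissemination import detect_subclones_in_fluid, match_fluid_to_tissue

COHORT = Path("results/cohort")
RUNS = Path("results/runs")


def main() -> None:
    det_rows, match_rows = [], []
    for pdir in sorted(COHORT.iterdir()):
        run = RUNS / pdir.name
        if not (run / "ccf.tsv").exists():
            continue
        ccf = pd.read_csv(run / "ccf.tsv", sep="\t")
        assign = pd.read_csv(run / "assignments.tsv", sep="\t")
        variants = pd.read_csv(pdir / "variants.tsv", sep="\t")
        ccf = ccf.merge(
            variants[["variant_id", "sample_id", "is_indel"]],
            on=["variant_id", "sample_id"],
            how="left",
        ).merge(
            variants[["variant_id", "sample_id", "alt_count"]],
            on=["variant_id", "sample_id"], how="left", suffixes=("", "_v"),
        )
        meta = pd.read_csv(pdir / "metadata.tsv", sep="\t")
        members = {
            cid: list(g.variant_id) for cid, g in assign.groupby("cluster_id")
        }
        clusters = pd.read_csv(run / "clusters.tsv", sep="\t")
        fluid_ids = set(meta.sample_id[meta.tissue_class == "fluid"])
        tissue_ccfs = {
            col[4:]: dict(zip(clusters.cluster_id, clusters[col]))
            for col in clusters.columns
            if col.startswith("ccf_") and col[4:] not in fluid_ids
        }
        for fid in meta.sample_id[meta.tissue_class == "fluid"]:
            fl = ccf[ccf.sample_id == fid]
            if fl.empty:
                continue
            det = detect_subclones_in_fluid(fl, members)
            det.insert(0, "fluid", fid)
            det.insert(0, "patient", pdir.name)
            det_rows.append(det)
            try:
                ranked = match_fluid_to_tissue(det, tissue_ccfs)
                best = ranked.iloc[0]
                match_rows.append(
                    {"patient": pdir.name, "fluid": fid,
                     "best_tissue": best.sample_id,
                     "similarity": round(float(best.similarity), 3),
                     "n_detected": int(det.detected.sum())}
                )
                print(f"{pdir.name} {fid}: {int(det.detected.sum())} subclones detected;"
                      f" closest tissue {best.sample_id} (similarity {best.similarity:.2f})")
            except ValueError:
                print(f"{pdir.name} {fid}: no subclone detected (noise-level fluid)")
    if det_rows:
        pd.concat(det_rows).to_csv(Path("results") / "fluid_detection.tsv",
                                   sep="\t", index=False)
    if match_rows:
        pd.DataFrame(match_rows).to_csv(Path("results") / "fluid_matching.tsv",
                                        sep="\t", index=False)


if __name__ == "__main__":
    main()
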