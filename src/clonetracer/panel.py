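"""Targeted-capture panel design from clustered whole-genome variants.

Targets are chosen per mutation cluster so every branch of the clone tree is
represented on the panel: repeat-masked variants are excluded, a seeded
random subset of fixed size is sampled from each cluster, and all
protein-altering variants are added back regardless of quota or repeat
status.  Capture regions are the targets padded with 60 nt flanks for
substitutions and 110 nt for indels (wider to absorb indel misalignment),
then merged where they overlap or abut.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FLANK_SUB = 60
FLANK_INDEL = 110


@dataclass
class TargetPanel:
    targets: pd.DataFrame
    regions: pd.DataFrame
    flank_sub: int = FLANK_SUB
    flank_indel: int = FLANK_INDEL
    warnings: list[str] = field(default_factory=list)


def select_targets(
    variants: pd.DataFrame,
    assignment: pd.Series,
    repeat_mask: pd.DataFrame | None,
    protein_altering: set,
    quota: int,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-cluster seeded sampling of capture targets.

    ``variants`` has one row per variant (variant_id, chrom, pos, is_indel);
    ``repeat_mask`` is BED-like (chrom, start, end; 0-based half-open).
    Repeat-masked variants are excluded before sampling; protein-altering
    variants are unioned in afterwards, even if repeat-masked (the coding set
    is added after sampling).  Deterministic for a fixed seed.
    """
    uniq = variants.drop_duplicates("variant_id").set_index("variant_id")
    in_repeat = pd.Series(False, index=uniq.index)
    if repeat_mask is not None and not repeat_mask.empty:
        for _, r in repeat_mask.iterrows():
            hit = (uniq.chrom == r.chrom) & (r.start < uniq.pos) & (uniq.pos <= r.end)
            in_repeat |= hit

    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    warnings: list[str] = []
    for cid in sorted(assignment.unique()):
        members = assignment.index[assignment == cid]
        eligible = [m for m in members if m in uniq.index and not in_repeat.get(m, False)]
        if not eligible:
            warnings.append(f"cluster {cid} has no non-repeat variant; unrepresented")
            continue
        take = min(quota, len(eligible))
        picked = rng.choice(np.array(sorted(eligible)), size=take, replace=False)
        chosen.extend(picked.tolist())

    final = sorted(set(chosen) | {v for v in protein_altering if v in uniq.index})
    out = uniq.loc[final].reset_index()
    out["protein_altering"] = out.variant_id.isin(protein_altering)
    return out, warnings


def build_regions(targets: pd.DataFrame) -> pd.DataFrame:
    """Flanked, merged capture regions (BED: 0-based half-open, sorted).

    A substitution at 1-based position p spans [p - 61, p + 60) after
    conversion; an indel of reference length L spans [p - 111, p + 110 + L).
    Overlapping or bookended intervals are merged.
    """
    if targets.empty:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    rows = []
    for _, t in targets.iterrows():
        is_indel = bool(t.get("is_indel", False))
        flank = FLANK_INDEL if is_indel else FLANK_SUB
        ref_len = len(str(t["ref"])) if "ref" in t and isinstance(t.get("ref"), str) else 1
        start0 = int(t.pos) - 1 - flank
        end0 = int(t.pos) - 1 + flank + (ref_len if is_indel else 1)
        rows.append((t.chrom, max(0, start0), end0))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    merged = []
    for chrom, g in df.groupby("chrom", sort=True):
        cur_s, cur_e = None, None
        for _, r in g.iterrows():
            if cur_s is None:
                cur_s, cur_e = r.start, r.end
            elif r.start <= cur_e:  # overlap or bookend
                cur_e = max(cur_e, r.end)
            else:
                merged.append((chrom, cur_s, cur_e))
                cur_s, cur_e = r.start, r.end
        merged.append((chrom, cur_s, cur_e))
    return pd.DataFrame(merged, columns=["chrom", "start", "end"])


def design_panel(
    variants: pd.DataFrame,
    assignment: pd.Series,
    repeat_mask: pd.DataFrame | None = None,
    protein_altering: set | None = None,
    quota: int = 50,
    seed: int = 0,
) -> TargetPanel:
    targets, warns = select_targets(
        variants, assignment, repeat_mask, protein_altering or set(), quota, seed
    )
    regions = build_regions(targets)
    return TargetPanel(targets=targets, regions=regions, warnings=warns)
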