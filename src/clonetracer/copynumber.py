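"""Clonal copy number from log-ratios, ploidy grid search, profile agreement.

Off-target read log-ratios are converted to clonal integer copy numbers with
the standard purity/ploidy back-transform: an observed ratio mixes tumor and
normal cells, so

    cn = ( (rho * psi + 2 (1 - rho)) * 2**logR - 2 (1 - rho) ) / rho

rounded to the nearest integer and floored at zero.  The per-sample ploidy
psi is unknown for samples without a high-quality reference and is fitted by
grid search over 2.0-5.0 in steps of 0.1, choosing the (ploidy, reference)
pair that maximizes the percentage of autosomal basepairs whose converted
copy number matches a reference profile -- where mismatching segments count
as correct when the converted value is 2, since copy-neutral state at an
earlier time point is expected for most of the genome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SEX_CHROMS = {"chrX", "chrY", "X", "Y"}


@dataclass
class PloidyFit:
    ploidy: float
    agreement: float  # percent of autosomal bp matching the best reference
    reference_id: str


def logratio_to_copynumber(logR, rho: float, ploidy: float) -> np.ndarray:
    """Clonal integer copy number from a log2 ratio (vectorized)."""
    if rho <= 0 or rho > 1:
        raise ValueError("purity must lie in (0, 1]")
    if ploidy < 1:
        raise ValueError("ploidy must be >= 1")
    logR = np.asarray(logR, dtype=float)
    cn = ((rho * ploidy + 2 * (1 - rho)) * np.exp2(logR) - 2 * (1 - rho)) / rho
    out = np.maximum(np.rint(cn), 0).astype(int)
    return out if out.ndim else int(out)


def _intersect(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Pairwise intersection of two segmentations (autosomes only)."""
    rows = []
    a = a[~a.chrom.isin(SEX_CHROMS)]
    b = b[~b.chrom.isin(SEX_CHROMS)]
    for chrom, ga in a.groupby("chrom"):
        gb = b[b.chrom == chrom]
        for _, ra in ga.iterrows():
            ov = gb[(gb.start < ra.end) & (gb.end > ra.start)]
            for _, rb in ov.iterrows():
                rows.append(
                    {
                        "chrom": chrom,
                        "start": max(ra.start, rb.start),
                        "end": min(ra.end, rb.end),
                        "cn_a": ra.cn_total,
                        "cn_b": rb.cn_total,
                    }
                )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "cn_a", "cn_b"])


def profile_agreement(cn_a: pd.DataFrame, cn_b: pd.DataFrame) -> float:
    """Percent of intersected autosomal basepairs with equal total copy number."""
    inter = _intersect(cn_a, cn_b)
    if inter.empty:
        raise ValueError("profiles share no autosomal territory")
    bp = inter.end - inter.start
    return float(100.0 * bp[inter.cn_a == inter.cn_b].sum() / bp.sum())


def fit_ploidy(
    sample_segments: pd.DataFrame,
    rho: float,
    references: dict[str, pd.DataFrame],
    grid: np.ndarray | None = None,
) -> PloidyFit:
    """Grid-search the sample ploidy against clonal reference profiles.

    ``sample_segments`` carries chrom/start/end/logR; each reference carries
    chrom/start/end/cn_total (clonal integer states).  The segment
    intersection is computed once per reference; each grid ploidy then only
    re-converts the log-ratios.  Mismatching segments count as correct when
    the converted value is 2 (copy-neutral exemption).  Ties in agreement are
    broken toward the ploidy nearest 2, then toward the lower ploidy.
    """
    if grid is None:
        grid = np.round(np.arange(2.0, 5.0 + 1e-9, 0.1), 1)
    if len(grid) == 0 or not references:
        raise ValueError("ploidy grid and reference profiles must be non-empty")
    sample = sample_segments.rename(columns={"logR": "cn_total"})  # placeholder column
    best: PloidyFit | None = None
    for ref_id, ref in references.items():
        inter = _intersect(sample, ref)
        if inter.empty:
            continue
        logr = inter.cn_a.values.astype(float)  # the placeholder carries logR
        ref_cn = inter.cn_b.values.astype(int)
        bp = (inter.end - inter.start).values.astype(float)
        total = bp.sum()
        for psi in grid:
            conv = logratio_to_copynumber(logr, rho, float(psi))
            ok = (conv == ref_cn) | (conv == 2)
            agree = float(100.0 * bp[ok].sum() / total)
            key = (agree, -abs(psi - 2.0), -psi)
            if best is None or key > (best.agreement, -abs(best.ploidy - 2.0), -best.ploidy):
                best = PloidyFit(ploidy=float(psi), agreement=agree, reference_id=ref_id)
    if best is None:
        raise ValueError("no reference overlaps the sample segmentation")
    return best
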