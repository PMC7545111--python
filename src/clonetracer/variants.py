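"""Variant filters, tumor purity estimation, multiplicity and CCF computation.

The cancer cell fraction (CCF) of a variant in a sample follows from its
variant allele fraction ``f_s`` (alt reads / depth), the sample purity ``rho``
and the locus copy number in tumor (``n_t``) and normal (``n_n``) cells::

    n_mut = f_s * (1 / rho) * (rho * n_t + n_n * (1 - rho))
    ccf   = n_mut / n_chr

where ``n_chr`` is the number of chromosomal copies carrying the mutation,
assigned by binomial maximum likelihood over 1..C (C = major allele copy
number).  Purity is estimated as the mode of a Gaussian kernel density over
truncal-variant VAFs, then fine-tuned so the truncal mutation cluster sits at
CCF 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class PurityEstimationError(ValueError):
    pass


@dataclass
class PurityEstimate:
    rho: float
    ploidy: float
    method: str  # kde_mode | fine_tuned | external
    kde_bandwidth: float = float("nan")

    def __post_init__(self):
        if not (0 < self.rho <= 1):
            raise ValueError(f"purity must lie in (0, 1], got {self.rho}")


@dataclass(frozen=True)
class CopyNumberState:
    """Locus copy number: total in tumor cells, in normal cells, and major allele."""

    n_locus_t: int
    n_locus_n: int = 2
    major: int | None = None

    def __post_init__(self):
        object.__setattr__(
            self, "major", self.major if self.major is not None else max(1, (self.n_locus_t + 1) // 2)
        )
        if self.major > self.n_locus_t:
            raise ValueError("major allele copy number cannot exceed total")


@dataclass
class CCFRecord:
    n_mut: float
    n_chr: int
    ccf: float


# ---------------------------------------------------------------------------
# filters


def filter_recurrent_calls(calls: pd.DataFrame) -> set:
    """Retain variants called in >= 2 samples of the same patient.

    ``calls`` must have columns ``variant_id``, ``sample_id`` and boolean
    ``called``.  With a single sample the filter cannot detect recurrence and
    is disabled (all called variants pass) with a warning.
    """
    n_samples = calls.sample_id.nunique()
    called = calls[calls.called.astype(bool)]
    if n_samples < 2:
        warnings.warn("single-sample patient: recurrence filter disabled")
        return set(called.variant_id.unique())
    counts = called.groupby("variant_id").sample_id.nunique()
    return set(counts.index[counts >= 2])


def filter_fixed_sample_snvs(
    snvs: pd.DataFrame,
    fixed_segments: pd.DataFrame,
    hmw_profiles: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """CN-agreement filter for fixed (paraffin-embedded) samples.

    An SNV is retained iff its locus lies in a fixed-sample segment whose
    total copy number equals that of at least one high-molecular-weight (HMW)
    reference profile at the same locus.  Segment tables use 0-based
    half-open coordinates with columns chrom, start, end, cn_total; SNV
    positions are 1-based.
    """
    if not hmw_profiles:
        warnings.warn("no HMW reference profile: CN-agreement filter inapplicable")
        return snvs

    def cn_at(segs: pd.DataFrame, chrom: str, pos1: int):
        sel = segs[(segs.chrom == chrom) & (segs.start < pos1) & (pos1 <= segs.end)]
        return None if sel.empty else int(sel.cn_total.iloc[0])

    keep = []
    for _, row in snvs.iterrows():
        cn_fixed = cn_at(fixed_segments, row.chrom, row.pos)
        if cn_fixed is None:
            keep.append(False)
            continue
        ok = any(
            cn_at(prof, row.chrom, row.pos) == cn_fixed for prof in hmw_profiles.values()
        )
        keep.append(ok)
    return snvs[np.array(keep, dtype=bool)]


# ---------------------------------------------------------------------------
# purity


def _expected_vaf(ccf: float, m: int, rho: float, n_t: int, n_n: int = 2) -> float:
    return m * rho * ccf / (rho * n_t + n_n * (1 - rho))


def estimate_purity(
    truncal_vafs: np.ndarray,
    ploidy_class: str = "diploid",
    min_vaf: float = 0.01,
    mode_selection: str = "global",
) -> PurityEstimate:
    """Purity from the KDE mode of truncal VAFs.

    VAFs below 1% are excluded as likely false-positive calls.  The mode v is
    inverted through v = rho * m / (rho * psi + 2 (1 - rho)) with m = 1 and
    psi = 2 (diploid) or 4 (tetraploid), giving rho = 2 v / (1 + 2 v - v psi).
    Bandwidth is Silverman's rule.

    ``mode_selection``: "global" takes the density maximum (appropriate when
    the input really is truncal-only); "rightmost" takes the rightmost local
    maximum reaching at least a quarter of the global peak -- robust when the
    input is a truncal proxy that may still contain a dense high-CCF subclone,
    since no cluster can sit above the clonal peak.
    """
    vafs = np.asarray(truncal_vafs, dtype=float)
    vafs = vafs[(vafs >= min_vaf) & (vafs <= 1.0)]
    if vafs.size == 0:
        raise PurityEstimationError("no truncal VAFs above the 1% exclusion threshold")
    psi = 2.0 if ploidy_class == "diploid" else 4.0
    if vafs.size == 1 or np.ptp(vafs) < 1e-12:
        mode = float(vafs[0])
        bw = float("nan")
    else:
        kde = stats.gaussian_kde(vafs, bw_method="silverman")
        grid = np.linspace(max(min_vaf, vafs.min()), vafs.max(), 512)
        dens = kde(grid)
        if mode_selection == "rightmost":
            pad = np.concatenate([[-np.inf], dens, [-np.inf]])
            is_peak = (pad[1:-1] > pad[:-2]) & (pad[1:-1] >= pad[2:])
            peaks = np.where(is_peak & (dens >= 0.25 * dens.max()))[0]
            mode = float(grid[peaks.max()]) if peaks.size else float(grid[np.argmax(dens)])
        else:
            mode = float(grid[np.argmax(dens)])
        bw = float(kde.factor * vafs.std(ddof=1))
    denom = 1.0 + 2.0 * mode - mode * psi
    if denom <= 0:
        rho = 1.0
        warnings.warn("VAF mode at boundary: purity clipped to 1")
    else:
        rho = 2.0 * mode / denom
    rho = float(np.clip(rho, 1e-6, 1.0))
    if rho >= 1.0 or mode >= 0.5 * (psi / 2):
        warnings.warn("purity estimate at boundary")
    return PurityEstimate(rho=rho, ploidy=psi, method="kde_mode", kde_bandwidth=bw)


def fine_tune_purity(
    estimate: PurityEstimate,
    truncal_ccf: float,
    window: tuple[float, float] = (0.75, 1.25),
) -> PurityEstimate:
    """Rescale purity so the truncal cluster's mean CCF becomes exactly 1.

    At fixed read counts the diploid CCF scales approximately as 1/rho, so the
    multiplicative update is rho' = rho * truncal_ccf.  The adjustment is
    rejected (original estimate returned, flagged) if it would push purity out
    of (0, 1] while leaving the acceptance window [0.75, 1.25] unreachable.
    """
    if truncal_ccf <= 0:
        raise PurityEstimationError("truncal CCF must be positive")
    new_rho = estimate.rho * truncal_ccf
    if new_rho > 1.0:
        # cap at 1; achievable CCF becomes truncal_ccf * rho / 1
        capped_ccf = truncal_ccf * estimate.rho
        if not (window[0] <= capped_ccf <= window[1]):
            warnings.warn(
                f"fine-tuning capped at purity 1 leaves truncal CCF {capped_ccf:.3f} "
                f"outside [{window[0]}, {window[1]}]"
            )
        new_rho = 1.0
    return PurityEstimate(
        rho=float(new_rho),
        ploidy=estimate.ploidy,
        method="fine_tuned",
        kde_bandwidth=estimate.kde_bandwidth,
    )


# ---------------------------------------------------------------------------
# multiplicity and CCF


def assign_multiplicity(
    alt_count: int, depth: int, rho: float, cn_state: CopyNumberState
) -> int:
    """Copies carrying the mutation, by binomial maximum likelihood over 1..C.

    Ties break toward the smaller multiplicity (the conservative choice: it
    yields the larger mutation copy number interpretation of CCF <= the
    alternative).  Raises on homozygous deletions (C = 0).
    """
    C = cn_state.major
    if C == 0 or cn_state.n_locus_t == 0:
        raise ValueError("variant in homozygous deletion is unassignable")
    if depth <= 0:
        raise ValueError("depth must be positive")
    denom = rho * cn_state.n_locus_t + cn_state.n_locus_n * (1 - rho)
    best_m, best_ll = 1, -np.inf
    for m in range(1, C + 1):
        f = np.clip(m * rho / denom, 1e-12, 1 - 1e-12)
        ll = stats.binom.logpmf(alt_count, depth, f)
        if ll > best_ll + 1e-9:  # strict improvement required: ties keep smaller m
            best_m, best_ll = m, ll
    return best_m


def compute_ccf(
    f_s: float, rho: float, cn_state: CopyNumberState, n_chr: int
) -> CCFRecord:
    """Mutation copy number and CCF from the VAF.

    CCF is deliberately not clipped at 1; values above 1 are handled by the
    clustering model downstream.
    """
    if not (0 < rho <= 1):
        raise ValueError("purity must lie in (0, 1]")
    if n_chr < 1:
        raise ValueError("n_chr must be >= 1")
    n_mut = f_s * (1.0 / rho) * (rho * cn_state.n_locus_t + cn_state.n_locus_n * (1 - rho))
    return CCFRecord(n_mut=float(n_mut), n_chr=int(n_chr), ccf=float(n_mut / n_chr))


def ccf_table(
    variants: pd.DataFrame,
    purity: dict[str, float],
    segments: pd.DataFrame,
    ploidy_class: str = "diploid",
) -> pd.DataFrame:
    """Vectorized per-variant-per-sample multiplicity and CCF.

    ``variants`` is the long table (variant_id, sample_id, chrom, pos,
    alt_count, depth, ...); ``segments`` maps loci to copy-number states per
    sample (columns sample_id, chrom, start, end, cn_total, major).  Returns
    the input with n_chr, n_mut and ccf columns appended.
    """
    out = variants.copy()
    out["vaf"] = np.where(out.depth > 0, out.alt_count / out.depth.clip(lower=1), 0.0)
    n_t = np.full(len(out), 2, dtype=int)
    major = np.full(len(out), 1, dtype=int)

    seg_by_sample = {s: g for s, g in segments.groupby("sample_id")}
    for sid, g in out.groupby("sample_id"):
        segs = seg_by_sample.get(sid)
        if segs is None:  # fluid etc. without own CN profile: assume diploid
            continue
        for _, seg in segs.iterrows():
            sel = g.index[
                (g.chrom == seg.chrom) & (seg.start < g.pos) & (g.pos <= seg.end)
            ]
            n_t[out.index.get_indexer(sel)] = int(seg.cn_total)
            major[out.index.get_indexer(sel)] = int(seg.major)

    rho = out.sample_id.map(purity).astype(float).values
    denom = rho * n_t + 2.0 * (1 - rho)

    # multiplicity by exhaustive binomial ML over 1..C (vectorized per m)
    max_c = int(major.max()) if len(major) else 1
    n_chr = np.ones(len(out), dtype=int)
    best = np.full(len(out), -np.inf)
    alt = out.alt_count.values
    dep = out.depth.values.clip(min=1)
    for m in range(1, max_c + 1):
        valid = major >= m
        f = np.clip(m * rho / denom, 1e-12, 1 - 1e-12)
        ll = stats.binom.logpmf(alt, dep, f)
        upd = valid & (ll > best + 1e-9)
        n_chr[upd] = m
        best[upd] = ll[upd]

    n_mut = out.vaf.values / rho * denom
    out["n_locus_t"] = n_t
    out["major"] = major
    out["n_chr"] = n_chr
    out["n_mut"] = n_mut
    out["ccf"] = n_mut / n_chr
    return out
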