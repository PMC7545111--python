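"""Filters, purity estimation, multiplicity assignment and CCF algebra."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from clonetracer.variants import (
    CopyNumberState,
    PurityEstimationError,
    PurityEstimate,
    assign_multiplicity,
    compute_ccf,
    estimate_purity,
    filter_fixed_sample_snvs,
    filter_recurrent_calls,
    fine_tune_purity,
)


def _calls(pattern: dict[str, int], n_samples: int = 10) -> pd.DataFrame:
    rows = []
    for vid, k in pattern.items():
        for s in range(n_samples):
            rows.append({"variant_id": vid, "sample_id": f"s{s}", "called": s < k})
    return pd.DataFrame(rows)


class TestRecurrenceFilter:
    def test_called_in_three_of_ten_retained(self):
        assert filter_recurrent_calls(_calls({"v": 3})) == {"v"}

    def test_called_in_one_sample_dropped(self):
        assert filter_recurrent_calls(_calls({"v": 1})) == set()

    def test_toy_counts(self):
        pattern = {"a": 1, "b": 2, "c": 2, "d": 3, "e": 1}
        assert filter_recurrent_calls(_calls(pattern)) == {"b", "c", "d"}

    def test_single_sample_patient_disables_filter_with_warning(self):
        calls = _calls({"v": 1, "w": 0}, n_samples=1)
        with pytest.warns(UserWarning, match="single-sample"):
            assert filter_recurrent_calls(calls) == {"v"}


class TestFixedSampleCnFilter:
    def _snvs(self, cns):
        return pd.DataFrame(
            {
                "variant_id": [f"v{i}" for i in range(len(cns))],
                "chrom": "chr1",
                "pos": [100 + 1000 * i for i in range(len(cns))],
            }
        ), pd.DataFrame(
            {
                "chrom": "chr1",
                "start": [1000 * i for i in range(len(cns))],
                "end": [1000 * (i + 1) for i in range(len(cns))],
                "cn_total": cns,
            }
        )

    def test_agreeing_cn_retained_disagreeing_dropped(self):
        snvs, fixed = self._snvs([2, 3, 4, 2])
        hmw = {"h": pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [4000], "cn_total": [2]})}
        kept = filter_fixed_sample_snvs(snvs, fixed, hmw)
        assert list(kept.variant_id) == ["v0", "v3"]

    def test_cn3_matching_one_hmw_profile_retained(self):
        snvs, fixed = self._snvs([3])
        hmw = {
            "h1": pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [4000], "cn_total": [2]}),
            "h2": pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [4000], "cn_total": [3]}),
        }
        assert len(filter_fixed_sample_snvs(snvs, fixed, hmw)) == 1

    def test_no_reference_passes_through_with_warning(self):
        snvs, fixed = self._snvs([3])
        with pytest.warns(UserWarning, match="inapplicable"):
            kept = filter_fixed_sample_snvs(snvs, fixed, {})
        assert len(kept) == len(snvs)


class TestPurity:
    def test_vaf_mode_030_inverts_to_purity_060(self):
        rng = np.random.default_rng(0)
        depth = 800
        alt = rng.binomial(depth, 0.30, size=500)
        est = estimate_purity(alt / depth, "diploid")
        assert est.rho == pytest.approx(0.60, abs=0.02)

    def test_vaf_half_means_pure_tumor(self):
        rng = np.random.default_rng(1)
        alt = rng.binomial(800, 0.5, size=300)
        est = estimate_purity(alt / 800, "diploid")
        assert est.rho == pytest.approx(1.0, abs=0.03)

    def test_mode_past_half_clips_to_one_with_warning(self):
        with pytest.warns(UserWarning, match="boundary"):
            est = estimate_purity(np.full(50, 0.55), "diploid")
        assert est.rho == pytest.approx(1.0)

    def test_all_vafs_below_one_percent_is_an_error(self):
        with pytest.raises(PurityEstimationError):
            estimate_purity(np.full(100, 0.005), "diploid")

    def test_tetraploid_mode_inversion(self):
        # v = rho/(4 rho + 2(1-rho)) -> rho = 2v/(1-2v); v=0.2 -> rho = 2/3
        est = estimate_purity(np.full(50, 0.2), "tetraploid")
        assert est.rho == pytest.approx(2 / 3, abs=1e-6)

    def test_recovers_true_purity_across_seeds(self):
        """KDE-mode purity within +-0.05 of truth for rho >= 0.3 at depth 800."""
        failures = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            rho = rng.uniform(0.3, 1.0)
            alt = rng.binomial(800, rho / 2, size=300)
            est = estimate_purity(alt / 800, "diploid")
            if abs(est.rho - rho) > 0.05:
                failures += 1
        assert failures == 0


class TestFineTune:
    def test_truncal_ccf_08_rescales_rho_down(self):
        est = PurityEstimate(rho=0.5, ploidy=2, method="kde_mode")
        new = fine_tune_purity(est, truncal_ccf=0.8)
        assert new.rho == pytest.approx(0.4)
        assert new.method == "fine_tuned"

    def test_truncal_ccf_one_is_fixed_point(self):
        est = PurityEstimate(rho=0.7, ploidy=2, method="kde_mode")
        assert fine_tune_purity(est, 1.0).rho == pytest.approx(0.7)

    def test_capped_adjustment_outside_window_flagged(self):
        # rescaling up past purity 1 is capped; the achievable truncal CCF
        # (3.0 * 0.5 = 1.5) then falls outside [0.75, 1.25] and is flagged
        est = PurityEstimate(rho=0.5, ploidy=2, method="kde_mode")
        with pytest.warns(UserWarning, match="outside"):
            new = fine_tune_purity(est, truncal_ccf=3.0)
        assert new.rho == pytest.approx(1.0)

    def test_capped_adjustment_inside_window_not_flagged(self):
        est = PurityEstimate(rho=0.6, ploidy=2, method="kde_mode")
        new = fine_tune_purity(est, truncal_ccf=2.0)  # achievable CCF 1.2
        assert new.rho == pytest.approx(1.0)

    def test_nonpositive_truncal_ccf_is_error(self):
        est = PurityEstimate(rho=0.5, ploidy=2, method="kde_mode")
        with pytest.raises(PurityEstimationError):
            fine_tune_purity(est, 0.0)


def brute_force_multiplicity(alt, depth, rho, n_t, n_n, C):
    """Independent oracle: exhaustive binomial likelihood over 1..C."""
    lls = []
    for m in range(1, C + 1):
        f = m * rho / (rho * n_t + n_n * (1 - rho))
        f = min(max(f, 1e-12), 1 - 1e-12)
        lls.append(stats.binom.logpmf(alt, depth, f))
    best = max(lls)
    return 1 + min(i for i, ll in enumerate(lls) if ll >= best - 1e-9)


class TestMultiplicity:
    def test_single_candidate(self):
        st_ = CopyNumberState(n_locus_t=2, major=1)
        assert assign_multiplicity(10, 100, 0.5, st_) == 1

    def test_two_thirds_vaf_prefers_two_copies(self):
        st_ = CopyNumberState(n_locus_t=3, major=2)
        assert assign_multiplicity(60, 100, 1.0, st_) == 2

    def test_tie_breaks_toward_smaller_multiplicity(self):
        # f1 = 1/3 and f2 = 2/3 are equidistant in likelihood at alt/depth = 0.5
        st_ = CopyNumberState(n_locus_t=3, major=2)
        assert assign_multiplicity(50, 100, 1.0, st_) == 1

    def test_homozygous_deletion_unassignable(self):
        with pytest.raises(ValueError):
            assign_multiplicity(5, 100, 0.5, CopyNumberState(n_locus_t=0, major=0))

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(2000):
            C = int(rng.integers(1, 7))
            n_t = int(rng.integers(C, 9))
            rho = float(rng.uniform(0.1, 1.0))
            depth = int(rng.integers(50, 1500))
            alt = int(rng.integers(0, depth + 1))
            st_ = CopyNumberState(n_locus_t=n_t, n_locus_n=2, major=C)
            assert assign_multiplicity(alt, depth, rho, st_) == brute_force_multiplicity(
                alt, depth, rho, n_t, 2, C
            )


class TestCCF:
    @pytest.mark.parametrize(
        "f_s,rho,n_t,n_chr,expected",
        [
            (0.5, 1.0, 2, 1, 1.0),
            (0.25, 0.5, 2, 1, 1.0),
            (0.3, 0.8, 3, 1, 1.05),
        ],
    )
    def test_worked_examples(self, f_s, rho, n_t, n_chr, expected):
        rec = compute_ccf(f_s, rho, CopyNumberState(n_locus_t=n_t), n_chr)
        assert rec.ccf == pytest.approx(expected)
        assert rec.n_mut == pytest.approx(expected * n_chr)

    def test_ccf_not_clipped_above_one(self):
        rec = compute_ccf(0.9, 0.5, CopyNumberState(n_locus_t=2), 1)
        assert rec.ccf > 1.0

    @given(
        ccf=st.floats(0.01, 1.5),
        rho=st.floats(0.05, 1.0),
        n_t=st.integers(1, 8),
        m=st.integers(1, 4),
    )
    @settings(max_examples=300, deadline=None)
    def test_inverts_generator_vaf_formula_exactly(self, ccf, rho, n_t, m):
        """compute_ccf is the algebraic inverse of the generative VAF model."""
        if m > n_t:
            m = n_t
        f = m * rho * ccf / (rho * n_t + 2 * (1 - rho))
        rec = compute_ccf(f, rho, CopyNumberState(n_locus_t=n_t, major=max(m, 1)), m)
        assert rec.ccf == pytest.approx(ccf, rel=1e-9)

    def test_ccf_strictly_increasing_in_vaf(self):
        st_ = CopyNumberState(n_locus_t=3)
        ccfs = [compute_ccf(f, 0.6, st_, 1).ccf for f in np.linspace(0.01, 0.9, 20)]
        assert all(b > a for a, b in zip(ccfs, ccfs[1:]))
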