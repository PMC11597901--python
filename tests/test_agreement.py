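"""Agreement statistics: RMSE, CCC, Pearson, Bland–Altman, ICC, SEM/MDC, offset."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from gaitmmc import agreement as ag
from gaitmmc.types import StatsConfig, ValidationError


class TestRmseWaveforms:
    def test_identical_waveforms(self):
        w = np.random.default_rng(0).normal(size=(5, 101))
        assert ag.rmse_waveforms(w, w) == (0.0, 0.0)

    def test_constant_offset(self):
        w = np.random.default_rng(1).normal(size=(6, 101))
        mean, sd = ag.rmse_waveforms(w, w + 3.0)
        assert mean == pytest.approx(3.0)
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_three_points(self):
        mean, _ = ag.rmse_waveforms(np.array([[0.0, 0.0, 0.0]]), np.array([[1.0, 2.0, 2.0]]))
        assert mean == pytest.approx(np.sqrt(3.0))

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="mismatch"):
            ag.rmse_waveforms(np.zeros((2, 101)), np.zeros((2, 100)))


class TestLinCcc:
    def test_perfect_concordance(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert ag.lin_ccc(x, x)[0] == pytest.approx(1.0)

    def test_perfect_negative_concordance(self):
        x = np.array([-1.0, 0.0, 1.0])
        assert ag.lin_ccc(x, -x)[0] == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # s_xy=2, s_x²=1, s_y²=4, means 2 and 4 → 2·2/(1+4+4) = 4/9
        lcc, _, _ = ag.lin_ccc([1.0, 2.0, 3.0], [2.0, 4.0, 6.0])
        assert lcc == pytest.approx(4.0 / 9.0)

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        y = x + rng.normal(scale=0.5, size=30)
        lcc, lo, hi = ag.lin_ccc(x, y)
        assert lo < lcc < hi
        assert -1 <= lo and hi <= 1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            ag.lin_ccc(np.ones(5), np.ones(5))

    @given(st.integers(0, 10_000))
    def test_ccc_never_exceeds_pearson_in_magnitude(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        lcc, _, _ = ag.lin_ccc(x, y)
        r = ag.pearson(x, y)
        assert abs(lcc) <= abs(r) + 1e-12

    def test_equals_pearson_when_scales_and_means_match(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=200)
        y = rng.normal(size=200)
        # standardize both to identical mean and sd
        x = (x - x.mean()) / x.std(ddof=1)
        y = (y - y.mean()) / y.std(ddof=1)
        assert ag.lin_ccc(x, y)[0] == pytest.approx(ag.pearson(x, y), abs=1e-12)


class TestPearson:
    def test_exact_linear_relation(self):
        x = np.array([0.0, 1.0, 2.0, 5.0])
        assert ag.pearson(x, 2 * x + 1) == pytest.approx(1.0)

    def test_hand_computed_example(self):
        assert ag.pearson([1.0, 2.0, 3.0], [1.0, 3.0, 2.0]) == pytest.approx(0.5)

    def test_interpretation_bands(self):
        assert ag.interpret(0.95, ag.PEARSON_BANDS) == "very high"
        assert ag.interpret(0.80, ag.PEARSON_BANDS) == "high"
        assert ag.interpret(0.10, ag.PEARSON_BANDS) == "negligent"
        assert ag.interpret(0.96, ag.LCC_BANDS) == "substantial"
        assert ag.interpret(0.85, ag.ICC_BANDS) == "good"

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            ag.pearson(np.ones(4), np.arange(4.0))


class TestBlandAltman:
    def test_identical_systems(self):
        p = ag.PairedParams(np.arange(5.0), np.arange(5.0))
        assert ag.bland_altman(p) == (0.0, 0.0, 0.0)

    def test_two_point_closed_form(self):
        p = ag.PairedParams(np.array([1.0, 3.0]), np.zeros(2))
        bias, lo, hi = ag.bland_altman(p)
        assert bias == pytest.approx(2.0)
        assert lo == pytest.approx(2.0 - 1.96 * np.sqrt(2.0))
        assert hi == pytest.approx(2.0 + 1.96 * np.sqrt(2.0))

    @given(st.integers(0, 10_000))
    def test_bias_is_loa_midpoint_and_width_identity(self, seed):
        rng = np.random.default_rng(seed)
        p = ag.PairedParams(rng.normal(size=10), rng.normal(size=10))
        bias, lo, hi = ag.bland_altman(p)
        assert (lo + hi) / 2 == pytest.approx(bias, abs=1e-10)
        d_sd = (p.a - p.b).std(ddof=1)
        assert hi - lo == pytest.approx(2 * 1.96 * d_sd, rel=1e-10)


def _anova_icc_oracle(data):
    """Explicit two-way ANOVA decomposition, accumulated cell by cell."""
    n, k = data.shape
    grand = sum(sum(row) for row in data) / (n * k)
    ss_rows = 0.0
    for i in range(n):
        ss_rows += k * (sum(data[i]) / k - grand) ** 2
    ss_cols = 0.0
    for j in range(k):
        ss_cols += n * (sum(data[:, j]) / n - grand) ** 2
    ss_tot = 0.0
    for i in range(n):
        for j in range(k):
            ss_tot += (data[i, j] - grand) ** 2
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestIcc:
    def test_duplicated_sessions_give_unity(self):
        col = np.array([1.0, 5.0, 9.0, 13.0])
        icc, lo, hi = ag.icc_2_1(np.column_stack([col, col]))
        assert icc == pytest.approx(1.0)

    def test_no_between_subject_variance_gives_near_zero(self):
        rng = np.random.default_rng(4)
        data = rng.normal(0.0, 1.0, size=(200, 2))  # all subjects identical in truth
        icc, _, _ = ag.icc_2_1(data)
        assert icc <= 0.1

    def test_hand_dataset_matches_explicit_anova(self):
        data = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0], [7.0, 8.0]])
        icc, _, _ = ag.icc_2_1(data)
        assert icc == pytest.approx(_anova_icc_oracle(data), abs=1e-10)

    def test_matches_anova_oracle_on_random_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            n = rng.integers(3, 7)
            data = rng.normal(size=(n, 2)) + rng.normal(size=(n, 1))
            assert ag.icc_2_1(data)[0] == pytest.approx(_anova_icc_oracle(data), abs=1e-10)

    def test_matches_pingouin_point_estimate_and_ci(self):
        """Independent cross-check: two-way random, absolute agreement, single."""
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(6)
        for _ in range(5):
            n = 12
            data = rng.normal(size=(n, 2)) + 2 * rng.normal(size=(n, 1))
            icc, lo, hi = ag.icc_2_1(data)
            df = pd.DataFrame(
                {
                    "targets": np.repeat(np.arange(n), 2),
                    "raters": np.tile([0, 1], n),
                    "ratings": data.ravel(),
                }
            )
            ref = pg.intraclass_corr(df, targets="targets", raters="raters", ratings="ratings")
            row = ref[ref["Type"].isin(["ICC2", "ICC(A,1)"])].iloc[0]
            assert icc == pytest.approx(row["ICC"], abs=1e-9)
            ci_col = "CI95%" if "CI95%" in ref.columns else "CI95"
            ci_lo, ci_hi = row[ci_col]  # pingouin rounds the CI to 2 decimals
            assert lo == pytest.approx(ci_lo, abs=0.011)
            assert hi == pytest.approx(ci_hi, abs=0.011)

    def test_zero_total_variance_rejected(self):
        with pytest.raises(ValidationError):
            ag.icc_2_1(np.ones((4, 2)))


class TestSemMdc:
    @pytest.mark.parametrize(
        "sd,icc,expected", [(2.0, 0.75, 1.0), (3.0, 1.0, 0.0), (3.0, 0.0, 3.0)]
    )
    def test_sem_examples(self, sd, icc, expected):
        assert ag.sem_from_icc(sd, icc) == pytest.approx(expected)

    def test_icc_above_one_rejected(self):
        with pytest.raises(ValidationError):
            ag.sem_from_icc(1.0, 1.5)

    def test_mdc_conventions(self):
        assert ag.mdc_from_sem(1.0, "z_over_sqrt2") == pytest.approx(1.96 / np.sqrt(2))
        assert ag.mdc_from_sem(1.0, "z_times_sqrt2") == pytest.approx(1.96 * np.sqrt(2))
        assert ag.mdc_from_sem(0.0, "z_over_sqrt2") == 0.0
        with pytest.raises(ValidationError):
            ag.mdc_from_sem(1.0, "bogus")


class TestOffsetCorrect:
    def test_constant_offset_removed(self):
        ref = np.sin(np.linspace(0, 2 * np.pi, 101))
        corrected, offset = ag.offset_correct(ref + 6.0, ref)
        assert offset == pytest.approx(6.0)
        np.testing.assert_allclose(corrected, ref, atol=1e-12)

    def test_zero_mean_residual_by_construction(self):
        rng = np.random.default_rng(7)
        mmc, ref = rng.normal(size=(2, 101))
        corrected, _ = ag.offset_correct(mmc, ref)
        assert np.mean(corrected - ref) == pytest.approx(0.0, abs=1e-12)

    def test_rom_invariant_under_correction(self):
        rng = np.random.default_rng(8)
        mmc, ref = rng.normal(size=(2, 101))
        corrected, _ = ag.offset_correct(mmc, ref)
        assert np.ptp(corrected) == pytest.approx(np.ptp(mmc), abs=1e-12)


def _fake_summaries(n=6, sessions=(1, 2), speeds=(0.7, 1.0, 1.3), seed=0, wobble=0.0):
    """Synthetic per-trial summaries with participant-level structure."""
    rng = np.random.default_rng(seed)
    out = []
    grid = np.linspace(0, 2 * np.pi, 101)
    for p in range(n):
        base = {"hip": rng.normal(30, 3), "knee": rng.normal(60, 3)}
        for joint in ("hip", "knee"):
            shape = base[joint] * 0.5 * (1 + np.sin(grid)) + rng.normal(0.0, 2.0)
            for session in sessions:
                for speed in speeds:
                    w = shape + wobble * rng.normal(size=101)
                    out.append(
                        ag.TrialSummary(
                            participant_id=f"P{p:02d}",
                            session=session,
                            speed=speed,
                            joint=joint,
                            max=float(w.max()),
                            min=float(w.min()),
                            rom=float(np.ptp(w)),
                            mean_cycle=w,
                        )
                    )
    return out


class TestReports:
    def test_duplicated_sessions_are_perfectly_reliable(self):
        summaries = _fake_summaries(wobble=0.0)
        rep = ag.reliability_report(summaries)
        assert len(rep) == 6  # 2 joints × 3 speeds
        assert np.allclose(rep["icc_max"], 1.0)
        assert np.allclose(rep["rmse_mean"], 0.0)
        assert np.allclose(rep["lcc"], 1.0)

    def test_reference_against_itself(self):
        s = _fake_summaries(sessions=(1,), wobble=0.0)
        rep = ag.accuracy_report(s, s)
        assert np.allclose(rep["bias_max"], 0.0)
        assert np.allclose(rep["rmse_mean"], 0.0)
        assert np.allclose(rep["lcc"], 1.0)
        assert np.allclose(rep["r_max"], 1.0)

    def test_rom_columns_identical_corrected_vs_uncorrected(self):
        rng_sum = _fake_summaries(sessions=(1,), wobble=1.0, seed=3)
        ref_sum = _fake_summaries(sessions=(1,), wobble=1.0, seed=4)
        raw = ag.accuracy_report(rng_sum, ref_sum, corrected=False)
        cor = ag.accuracy_report(rng_sum, ref_sum, corrected=True)
        for col in ("bias_rom", "loa_low_rom", "loa_high_rom", "r_rom"):
            np.testing.assert_allclose(raw[col], cor[col], atol=1e-12)

    def test_missing_pairing_rejected(self):
        mmc = _fake_summaries(sessions=(1,))
        ref = [s for s in _fake_summaries(sessions=(1,)) if s.participant_id != "P00"]
        with pytest.raises(ValidationError, match="paired|fewer"):
            ag.accuracy_report(mmc, ref)
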