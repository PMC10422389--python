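"""Filtering, resampling, peak descriptors, group curves, ICC."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import footkinetics as fk
from footkinetics.curve_stats import (
    butterworth_lowpass,
    build_parameter_table,
    extract_params,
    icc,
    mean_ci_curves,
    resample_stance,
)
from footkinetics.errors import ValidationError


def _sine_gain(fs, fc, f, n=2000):
    t = np.arange(n) / fs
    x = np.sin(2 * np.pi * f * t)
    y = butterworth_lowpass(x, fs, fc)
    core = slice(n // 4, 3 * n // 4)  # avoid edge transients
    return np.abs(y[core]).max() / np.abs(x[core]).max()


class TestButterworth:
    def test_dc_gain_unity(self):
        x = np.full(200, 3.7)
        np.testing.assert_allclose(butterworth_lowpass(x, 100.0, 10.0), x, atol=1e-9)

    def test_stopband_attenuation(self):
        # double-pass 4th-order magnitude at f/fc = 4: 1/(1 + 4^8) ~ 1.5e-5
        assert _sine_gain(100.0, 10.0, 40.0) <= 1e-4

    def test_half_gain_at_cutoff(self):
        assert _sine_gain(1000.0, 50.0, 50.0) == pytest.approx(0.5, abs=0.02)

    def test_short_series_rejected(self):
        with pytest.raises(ValidationError):
            butterworth_lowpass(np.zeros(10), 100.0, 10.0)

    def test_nyquist_cutoff_clipped_with_warning(self, caplog):
        import logging

        from footkinetics import curve_stats

        curve_stats._clip_warned.clear()  # the warning is once-per-cutoff
        x = np.sin(np.arange(100) * 0.3)
        with caplog.at_level(logging.WARNING, logger="footkinetics.curve_stats"):
            y = butterworth_lowpass(x, 100.0, 50.0)
        assert "clipping" in caplog.text
        assert y.shape == x.shape


class TestResample:
    def test_linear_ramp_exact(self):
        x = np.arange(50.0)
        y = resample_stance(x, 10, 40)
        np.testing.assert_allclose(y, np.linspace(10, 40, 101), rtol=1e-14)
        assert y[0] == 10.0 and y[-1] == 40.0

    def test_constant(self):
        np.testing.assert_array_equal(resample_stance(np.full(30, 2.5), 0, 29),
                                      np.full(101, 2.5))

    def test_sine_within_interpolation_error(self):
        fs = 100.0
        t = np.arange(80) / fs
        x = np.sin(2 * np.pi * 3.0 * t)
        y = resample_stance(x, 0, 79)
        stations = np.linspace(0, 79, 101) / fs
        exact = np.sin(2 * np.pi * 3.0 * stations)
        # linear interpolation error bound: (w*dt)^2 / 8
        bound = (2 * np.pi * 3.0 / fs) ** 2 / 8
        assert np.abs(y - exact).max() <= bound

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            resample_stance(np.arange(10.0), 0, 9, n=1)
        with pytest.raises(ValidationError):
            resample_stance(np.arange(10.0), 5, 5)


class TestExtractParams:
    def test_bell_curve(self):
        g = np.exp(-0.5 * ((np.arange(101) - 75) / 10.0) ** 2) * 1.2
        p = extract_params(g)
        assert p.max_val == pytest.approx(1.2)
        assert p.t_max == 75.0

    def test_monotone_curve_peaks_at_end(self):
        p = extract_params(np.linspace(0, 1, 101))
        assert p.t_max == 100.0 and p.t_min == 0.0

    def test_plateau_takes_first_occurrence(self):
        c = np.zeros(101)
        c[40:51] = 1.0
        assert extract_params(c).t_max == 40.0

    @settings(derandomize=True, max_examples=50)
    @given(shift=st.floats(-5, 5))
    def test_constant_shift_moves_values_not_times(self, shift):
        rng = np.random.default_rng(7)
        c = rng.normal(size=101)
        p0, p1 = extract_params(c), extract_params(c + shift)
        assert p1.max_val == pytest.approx(p0.max_val + shift)
        assert p1.min_val == pytest.approx(p0.min_val + shift)
        assert (p1.t_max, p1.t_min) == (p0.t_max, p0.t_min)


class TestMeanCI:
    def test_identical_curves_zero_width(self):
        c = np.tile(np.linspace(0, 1, 101), (5, 1))
        mean, lo, hi = mean_ci_curves(c)
        np.testing.assert_allclose(hi - lo, 0.0, atol=1e-12)
        np.testing.assert_allclose(mean, c[0])

    def test_symmetric_pair(self):
        c = np.stack([np.full(101, 2.0), np.full(101, -2.0)])
        mean, lo, hi = mean_ci_curves(c)
        np.testing.assert_allclose(mean, 0.0, atol=1e-12)
        np.testing.assert_allclose(hi, -lo, atol=1e-12)

    def test_matches_direct_t_formula(self, rng):
        c = rng.normal(size=(10, 101))
        mean, lo, hi = mean_ci_curves(c, 0.95)
        half = stats.t.ppf(0.975, 9) * c.std(axis=0, ddof=1) / np.sqrt(10)
        np.testing.assert_allclose(hi, c.mean(axis=0) + half, rtol=1e-12)

    def test_width_shrinks_as_sqrt_n(self, rng):
        base = rng.normal(size=(40, 101))
        w10 = np.mean(mean_ci_curves(base[:10])[2] - mean_ci_curves(base[:10])[1])
        w40 = np.mean(mean_ci_curves(base)[2] - mean_ci_curves(base)[1])
        assert w40 < w10  # 1/sqrt(n) scaling dominates the t quantile

    def test_single_subject_rejected(self):
        with pytest.raises(ValidationError):
            mean_ci_curves(np.zeros((1, 101)))


class TestParameterTable:
    def _records(self, n_subj, n_shoe, n_dev, n_trial):
        rows = []
        for s in range(n_subj):
            for sh in ("A", "B")[:n_shoe]:
                for d in ("platform", "insole")[:n_dev]:
                    for t in range(1, n_trial + 1):
                        rows.append(dict(subject=f"S{s:02d}", shoe=sh, device=d,
                                         trial=t, joint="ankle", motion="dfpf",
                                         parameter="max_val", value=1.0))
        return rows

    def test_full_design_row_count(self):
        df = build_parameter_table(self._records(10, 2, 2, 5))
        assert len(df) == 200

    def test_minimal_design(self):
        assert len(build_parameter_table(self._records(1, 1, 1, 1))) == 1

    def test_rejected_trial_reduces_rows(self):
        rows = self._records(10, 2, 2, 5)[:-1]
        assert len(build_parameter_table(rows)) == 199

    def test_duplicate_cell_rejected(self):
        rows = self._records(1, 1, 1, 1) * 2
        with pytest.raises(ValidationError, match="duplicate"):
            build_parameter_table(rows)


class TestICC:
    def _brute_force(self, x):
        """Sums-of-squares two-way ANOVA, written out longhand."""
        import math

        n, k = x.shape
        grand = sum(map(math.fsum, x)) / (n * k)
        ss_rows = k * math.fsum((row.mean() - grand) ** 2 for row in x)
        ss_cols = n * math.fsum((x[:, j].mean() - grand) ** 2 for j in range(k))
        ss_tot = math.fsum((v - grand) ** 2 for v in x.ravel())
        ms_r = ss_rows / (n - 1)
        ms_c = ss_cols / (k - 1)
        ms_e = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
        return ((ms_r - ms_e) / ms_r,
                (ms_r - ms_e) / (ms_r + (ms_c - ms_e) / n))

    def test_perfect_agreement(self):
        x = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        r = icc(x)
        assert r.consistency == pytest.approx(1.0)
        assert r.agreement == pytest.approx(1.0)

    def test_constant_offset_hurts_agreement_only(self):
        base = np.arange(10.0)
        x = np.stack([base, base + 2.0], axis=1)
        r = icc(x)
        assert r.consistency == pytest.approx(1.0)
        assert r.agreement < 1.0

    def test_matches_brute_force_anova(self, rng):
        for _ in range(20):
            x = rng.normal(size=(10, 2))
            r = icc(x)
            c, a = self._brute_force(x)
            assert r.consistency == pytest.approx(c, abs=1e-10)
            assert r.agreement == pytest.approx(a, abs=1e-10)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        x = rng.normal(size=(12, 5))
        df = pd.DataFrame(
            [(i, j, x[i, j]) for i in range(12) for j in range(5)],
            columns=["subj", "rater", "y"],
        )
        table = pg.intraclass_corr(df, targets="subj", raters="rater",
                                   ratings="y").set_index("Type")
        r = icc(x)
        assert r.consistency == pytest.approx(table.loc["ICC(C,k)", "ICC"], abs=1e-9)
        assert r.agreement == pytest.approx(table.loc["ICC(A,k)", "ICC"], abs=1e-9)
        assert r.p_consistency == pytest.approx(table.loc["ICC(C,k)", "pval"], abs=1e-9)

    def test_zero_between_subject_variance_warns(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="footkinetics.curve_stats"):
            r = icc(np.zeros((4, 3)))
        assert r.consistency == 0.0 and r.agreement == 0.0
        assert "variance" in caplog.text

    def test_affine_invariances(self, rng):
        x = rng.normal(size=(8, 4))
        r0 = icc(x)
        r_scaled = icc(3.0 * x + 5.0)  # affine on all measurements
        assert r_scaled.consistency == pytest.approx(r0.consistency, abs=1e-10)
        assert r_scaled.agreement == pytest.approx(r0.agreement, abs=1e-10)
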