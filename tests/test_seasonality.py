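"""Cosine fitting, acceptance rules and birth-season estimation."""

import dataclasses
import math

import numpy as np
import pytest

import paleoherd as ph
from paleoherd import ValidationError
from conftest import random_birth_params


def brute_force_cosine_grid(x, y, period_range=(16.0, 60.0), n_periods=177, n_phases=200):
    """Independent oracle: dense grid over (X, x0) with exact linear
    least squares for (A, M) at each grid point."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    best = (np.inf, None, None)
    for X in np.linspace(*period_range, n_periods):
        x0s = np.linspace(0.0, X, n_phases, endpoint=False)
        c = np.cos(2 * np.pi * (x[None, :] - x0s[:, None]) / X)  # (phases, n)
        c_mean = c.mean(axis=1)
        var = (c**2).mean(axis=1) - c_mean**2
        cov = (c * y).mean(axis=1) - c_mean * y.mean()
        with np.errstate(divide="ignore", invalid="ignore"):
            A = np.where(var > 1e-12, cov / var, 0.0)
        M = y.mean() - A * c_mean
        rss = ((A[:, None] * c + M[:, None] - y) ** 2).sum(axis=1)
        i = int(np.argmin(rss))
        if rss[i] < best[0]:
            x0 = x0s[i] if A[i] >= 0 else (x0s[i] + X / 2) % X
            best = (float(rss[i]), float(X), float(x0))
    return {"X": best[1], "ratio": best[2] / best[1]}


def _circular_delta(a, b):
    d = abs(a - b) % 1.0
    return min(d, 1.0 - d)


class TestFitCosine:
    def test_noiseless_exact_recovery(self, noiseless_sequence, config):
        seq, truth = noiseless_sequence
        fit = ph.fit_cosine(seq, config)
        assert fit.A == pytest.approx(1.0, rel=1e-6)
        assert fit.X == pytest.approx(20.0, rel=1e-6)
        assert fit.x0 == pytest.approx(truth.x0, rel=1e-6)
        assert fit.M == pytest.approx(0.0, abs=1e-6)
        assert fit.r == pytest.approx(1.0, abs=1e-9)

    def test_too_few_samples_is_an_error_not_a_rejection(self, config):
        seq = ph.ToothSequence(
            "S", "sheep", "M2", "lower",
            (ph.IsotopeSample(0, -5), ph.IsotopeSample(1, -4), ph.IsotopeSample(2, -6)),
        )
        with pytest.raises(ValidationError):
            ph.fit_cosine(seq, config)

    def test_constant_sequence_rejected_as_no_sinusoid(self, config):
        seq = ph.ToothSequence(
            "S", "sheep", "M2", "lower",
            tuple(ph.IsotopeSample(float(i), -5.0) for i in range(8)),
        )
        fit = ph.accept_fit(ph.fit_cosine(seq, config), config)
        assert not fit.accepted
        assert fit.rejection_reason == "no_sinusoid"

    def test_agrees_with_grid_search_oracle(self, config):
        rng = np.random.default_rng(2024)
        for _ in range(40):
            params = random_birth_params(rng, A_true=3.0, X_true=30.0, n_samples=12)
            seq, _ = ph.simulate_tooth_sequence(params)
            fit = ph.fit_cosine(seq, config)
            oracle = brute_force_cosine_grid(seq.x, seq.d18O)
            assert _circular_delta((fit.x0 / fit.X) % 1.0, oracle["ratio"]) <= 0.02
            assert abs(fit.X - oracle["X"]) <= 0.5

    def test_shift_invariance(self, noiseless_sequence, config):
        seq, _ = noiseless_sequence
        shifted = ph.ToothSequence(
            seq.specimen_id, seq.taxon, seq.tooth, seq.jaw,
            tuple(dataclasses.replace(s, d18O=s.d18O + 3.0) for s in seq.samples),
        )
        base = ph.fit_cosine(seq, config)
        moved = ph.fit_cosine(shifted, config)
        assert moved.M == pytest.approx(base.M + 3.0, abs=1e-6)
        assert moved.A == pytest.approx(base.A, rel=1e-6)
        assert moved.x0 == pytest.approx(base.x0, rel=1e-6)

    def test_scale_invariance_of_ratio(self, noiseless_sequence, config):
        seq, _ = noiseless_sequence
        scaled = ph.ToothSequence(
            seq.specimen_id, seq.taxon, seq.tooth, seq.jaw,
            tuple(dataclasses.replace(s, x=s.x * 1.6) for s in seq.samples),
        )
        base = ph.fit_cosine(seq, config)
        moved = ph.fit_cosine(scaled, config)
        assert (moved.x0 / moved.X) % 1 == pytest.approx((base.x0 / base.X) % 1, abs=1e-6)

    def test_ratio_estimates_unbiased_over_random_phases(self, config):
        rng = np.random.default_rng(99)
        errs = []
        for _ in range(300):
            params = random_birth_params(rng)
            seq, truth = ph.simulate_tooth_sequence(params)
            fit = ph.fit_cosine(seq, config)
            d = ((fit.x0 / fit.X) - truth.ratio + 0.5) % 1.0 - 0.5
            errs.append(d)
        # circular mean error
        assert abs(np.angle(np.mean(np.exp(2j * np.pi * np.asarray(errs)))) / (2 * np.pi)) < 0.02


class TestAcceptFit:
    def _fit(self, **kwargs):
        defaults = dict(
            A=3.0, x0=5.0, X=30.0, M=-5.0, r=0.95, n=10,
            resid_sd=0.3, interior_near_max=True,
        )
        defaults.update(kwargs)
        return ph.CosineFit(**defaults)

    def test_low_r_rejected(self, config):
        fit = ph.accept_fit(self._fit(r=0.90, X=25.0), config)
        assert (fit.accepted, fit.rejection_reason) == (False, "low_r")

    def test_short_period_rejected(self, config):
        fit = ph.accept_fit(self._fit(r=0.95, X=15.5), config)
        assert (fit.accepted, fit.rejection_reason) == (False, "short_period")

    def test_thresholds_inclusive(self, config):
        fit = ph.accept_fit(self._fit(r=0.92, X=16.0), config)
        assert fit.accepted and fit.rejection_reason is None

    def test_missing_erj_rejected_first(self, config):
        fit = ph.accept_fit(self._fit(missing_erj=True, r=0.5), config)
        assert fit.rejection_reason == "missing_ERJ"

    def test_no_clear_maximum(self, config):
        fit = ph.accept_fit(self._fit(interior_near_max=False), config)
        assert fit.rejection_reason == "no_clear_maximum"

    def test_pure_predicate(self, config):
        fit = self._fit()
        assert ph.accept_fit(fit, config) == ph.accept_fit(fit, config)

    def test_truncated_monotone_sequence_rejected(self, config):
        # one third of a cycle with the maximum outside the sampled window
        params = ph.SequenceSimParams(
            A_true=2.5, X_true=60.0, birth_phase=0.6, n_samples=8,
            spacing=2.5, noise_sd=0.2, seed=5,
        )
        seq, _ = ph.simulate_tooth_sequence(params)
        fit = ph.accept_fit(ph.fit_cosine(seq, config), config)
        assert not fit.accepted


class TestBirthSeason:
    def _accepted_fit(self, x0, X):
        return ph.CosineFit(
            A=3.0, x0=x0, X=X, M=-5.0, r=0.95, n=10, accepted=True,
            resid_sd=0.3, interior_near_max=True,
        )

    def test_zero_delay_gives_zero_ratio(self):
        est = ph.normalized_birth_position(self._accepted_fit(0.0, 30.0), "goat", "M2", "lower")
        assert est.ratio == 0.0 and not est.corrected

    def test_half_period_gives_half(self):
        est = ph.normalized_birth_position(self._accepted_fit(15.0, 30.0), "goat", "M2", "lower")
        assert est.ratio == pytest.approx(0.5)

    def test_upper_sheep_m3_correction_wraps(self):
        est = ph.normalized_birth_position(self._accepted_fit(28.5, 30.0), "sheep", "M3", "upper")
        assert est.corrected
        assert est.ratio == pytest.approx(0.023, abs=1e-9)

    def test_correction_not_applied_to_goats_or_lower_jaws(self):
        for species, tooth, jaw in (("goat", "M3", "upper"), ("sheep", "M3", "lower"), ("sheep", "M2", "upper")):
            est = ph.normalized_birth_position(self._accepted_fit(6.0, 30.0), species, tooth, jaw)
            assert not est.corrected and est.ratio == pytest.approx(0.2)

    def test_rejected_fit_errors(self):
        fit = ph.CosineFit(A=3.0, x0=5.0, X=30.0, M=-5.0, r=0.5, n=10,
                           accepted=False, rejection_reason="low_r")
        with pytest.raises(ValidationError):
            ph.normalized_birth_position(fit, "sheep", "M2", "lower")


class TestReferenceBins:
    def _bins(self):
        return ph.ReferenceBirthBins(
            bins=(
                ph.ReferenceBin("goat", "M2", "lower", 0.78, 0.95, "summer-autumn"),
                ph.ReferenceBin("sheep", "M3", "upper", 0.9, 0.1, "winter"),  # wraps
            ),
            name="test-refs",
        )

    def _est(self, ratio, species="goat", tooth="M2", jaw="lower"):
        return ph.BirthSeasonEstimate(ratio=ratio, species=species, tooth=tooth, jaw=jaw)

    def test_ratio_inside_envelope(self):
        est = ph.assign_birth_season(self._est(0.85), self._bins())
        assert est.season_labels == ("summer-autumn",)
        assert est.reference_set == "test-refs"

    def test_ratio_outside_every_bin_unassigned(self):
        est = ph.assign_birth_season(self._est(0.3), self._bins())
        assert est.season_labels == ("unassigned",)

    def test_wrapping_bin(self):
        est = ph.assign_birth_season(
            self._est(0.05, species="sheep", tooth="M3", jaw="upper"), self._bins()
        )
        assert est.season_labels == ("winter",)

    def test_no_bins_for_combination_errors(self):
        with pytest.raises(ValidationError):
            ph.assign_birth_season(self._est(0.5, species="sheep", tooth="M2"), self._bins())

    def test_csv_loading(self, tmp_path):
        path = tmp_path / "refs.csv"
        path.write_text(
            "species,tooth,jaw,lo,hi,label\ngoat,M2,lower,0.78,0.95,summer-autumn\n"
        )
        bins = ph.ReferenceBirthBins.from_csv(path)
        assert bins.bins[0].contains(0.8)

    def test_recovery_selects_true_bin(self, config):
        # simulated goats born in the 0.78-0.95 envelope are assigned to it
        # whenever the fit is accepted and recovery is within +-0.05
        bins = self._bins()
        rng = np.random.default_rng(17)
        assigned = total = 0
        for _ in range(60):
            params = random_birth_params(
                rng, birth_phase=float(rng.uniform(0.80, 0.93)),
                taxon="goat", tooth="M2",
            )
            seq, truth = ph.simulate_tooth_sequence(params)
            fit = ph.accept_fit(ph.fit_cosine(seq, config), config)
            if not fit.accepted:
                continue
            est = ph.normalized_birth_position(fit, "goat", "M2", "lower", config)
            est = ph.assign_birth_season(est, bins)
            total += 1
            assigned += est.season_labels == ("summer-autumn",)
        assert total >= 20
        assert assigned >= 0.85 * total


class TestSequenceSummary:
    def test_arithmetic(self):
        seq = ph.ToothSequence(
            "S", "sheep", "M2", "lower",
            (ph.IsotopeSample(0, -8.0), ph.IsotopeSample(1, -3.9), ph.IsotopeSample(2, -5.0)),
        )
        s = ph.sequence_summary(seq)
        assert (s.d18O_min, s.d18O_max) == (-8.0, -3.9)
        assert s.amplitude == pytest.approx(4.1)
        assert (s.x_min, s.x_max) == (0.0, 1.0)
        assert s.optima_labels == ("cold season", "warm season")

    def test_constant_sequence_has_no_optima(self):
        seq = ph.ToothSequence(
            "S", "sheep", "M2", "lower",
            tuple(ph.IsotopeSample(float(i), -5.0) for i in range(4)),
        )
        s = ph.sequence_summary(seq)
        assert s.amplitude == 0.0 and s.optima_labels == ()

    def test_simulated_m3_amplitudes_span_reported_envelope(self):
        # full-cycle M3 fixtures built for half-amplitudes 1.75-3.65 permil
        # reproduce intra-tooth amplitudes within the reported 3.5-7.3
        for a_true in (1.75, 2.6, 3.65):
            params = ph.SequenceSimParams(
                A_true=a_true, n_samples=21, spacing=1.5, noise_sd=0.0, tooth="M3"
            )
            seq, _ = ph.simulate_tooth_sequence(params)
            amp = ph.sequence_summary(seq).amplitude
            assert 3.4 <= amp <= 7.3 + 1e-9
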