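"""The stability decision cascade: component classification, LRT, power
gating, per-locus and per-sample calls."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy import stats

from conftest import draw_histogram
from msicall.calls import (
    MSI,
    MSS,
    NON_CONTRIBUTORY,
    STABLE,
    UNSTABLE,
    ClassificationConfig,
    MicrosatelliteCall,
    SampleCall,
    call_microsatellite,
    call_sample,
    classify_components,
    decide_status,
    estimate_power,
    lrt,
    min_reads_for_power,
)
from msicall.em import EMConfig, MixtureFit, em_fit, log_likelihood
from msicall.extraction import LengthHistogram
from msicall.profiles import shift_profile
from msicall.simulate import SimulatedLocusSpec, simulate_sample
from msicall.extraction import extract_histograms


CFG = ClassificationConfig()


def fit_of(means, props):
    return MixtureFit(
        means=tuple(means), proportions=tuple(props), log_likelihood=0.0,
        n_iterations=0, converged=True,
    )


def make_call(locus, status, n=2000):
    return MicrosatelliteCall(
        locus=locus, status=status,
        unstable_components=((-6.0, 0.3),) if status == UNSTABLE else (),
        n_reads=n,
    )


class TestClassifyComponents:
    def test_boundaries_around_mean_26(self, toy_profile):
        assert toy_profile.mean == pytest.approx(26.0)
        flags = classify_components(
            fit_of([26.0, 23.3, 28.6], [0.4, 0.3, 0.3]), toy_profile, CFG
        )
        # 26.0 exact -> stable; 23.3 is 2.7 beyond vs band 2.6 -> unstable;
        # 28.6 sits exactly on the +10% boundary -> stable (inclusive)
        assert flags == (True, False, True)


class TestLRT:
    def test_no_unstable_components_gives_null_result(self, profile):
        h = LengthHistogram.from_counts(profile.locus, {int(round(profile.mean)): 100})
        stat, p = lrt(h, fit_of([profile.mean], [1.0]), profile, CFG)
        assert stat == 0.0 and p == 1.0

    def test_statistic_nonnegative(self, profile):
        rng = np.random.default_rng(3)
        h = draw_histogram(profile, shift_profile(profile, profile.mean), 400, rng)
        full = em_fit(h, profile, k=3)
        stat, p = lrt(h, full, profile, CFG)
        assert stat >= 0.0 and 0.0 <= p <= 1.0

    def test_strong_instability_is_overwhelming(self, profile):
        """30% unstable at -6 nt, 2000 observations: direct computation of
        both log-likelihoods puts the chi-square tail below 1e-6."""
        rng = np.random.default_rng(8)
        truth = {l: 0.7 * p for l, p in shift_profile(profile, profile.mean).items()}
        for l, p in shift_profile(profile, profile.mean - 6).items():
            truth[l] = truth.get(l, 0.0) + 0.3 * p
        h = draw_histogram(profile, truth, 2000, rng)
        full = em_fit(h, profile, k=3)
        stat, p = lrt(h, full, profile, CFG)
        assert p < 1e-6
        # oracle: recompute the two log-likelihoods explicitly
        band = CFG.stable_mean_tolerance * profile.mean
        reduced = em_fit(
            h, profile, k=1,
            mean_bounds=(profile.mean - band, profile.mean + band),
        )
        direct_stat = 2 * (full.log_likelihood - reduced.log_likelihood)
        n_unstable = sum(
            abs(m - profile.mean) > band for m in full.means
        )
        assert stat == pytest.approx(direct_stat, abs=1e-6)
        assert p == pytest.approx(
            float(stats.chi2.sf(direct_stat, 2 * n_unstable)), rel=1e-9
        )


class TestPower:
    def test_zero_reads_zero_power(self, profile):
        assert estimate_power(0, profile, CFG) == 0.0

    def test_monotone_in_depth(self, profile):
        cfg = ClassificationConfig(seed=17, power_mc_replicates=60)
        powers = [estimate_power(n, profile, cfg) for n in (60, 300, 1500)]
        # allow small Monte Carlo wiggle
        assert powers[1] >= powers[0] - 0.1
        assert powers[2] >= powers[1] - 0.1

    def test_asymptotic_consistency(self, profile):
        cfg = ClassificationConfig(seed=23, power_mc_replicates=30)
        assert estimate_power(1_000_000, profile, cfg) >= 0.97

    def test_minimal_depth_matches_fresh_seed_simulation(self, profile):
        """The bisection-found minimal depth should reproduce roughly the
        target power under an independent Monte Carlo seed."""
        cfg = ClassificationConfig(seed=31, power_mc_replicates=50)
        n_star = min_reads_for_power(profile, cfg, lo=25, hi=20_000)
        fresh = ClassificationConfig(seed=1031, power_mc_replicates=120)
        p_star = estimate_power(n_star, profile, fresh)
        assert p_star >= cfg.power_threshold * 0.85
        # and just below the crossing the power should not be far above it
        p_below = estimate_power(max(10, n_star // 3), profile, fresh)
        assert p_below <= p_star + 0.05


class TestCallMicrosatellite:
    def test_pure_stable_sample(self, panel, profiles):
        loci, stable = panel
        l = loci[2]
        spec = SimulatedLocusSpec.with_unstable(l, stable[l.name], 0.0, depth=2000, seed=51)
        mates, _ = simulate_sample([spec])
        h = extract_histograms(mates, [l])[l.name]
        call = call_microsatellite(h, profiles[l.name], CFG)
        assert call.status == STABLE

    def test_strong_instability_quantified(self, panel, profiles):
        loci, stable = panel
        l = loci[3]
        spec = SimulatedLocusSpec.with_unstable(
            l, stable[l.name], 0.30, unstable_shift=-6, depth=2000, seed=52
        )
        mates, _ = simulate_sample([spec])
        h = extract_histograms(mates, [l])[l.name]
        call = call_microsatellite(h, profiles[l.name], CFG)
        assert call.status == UNSTABLE
        total = sum(p for _s, p in call.unstable_components)
        assert total == pytest.approx(0.30, abs=0.05)
        shift = sum(s * p for s, p in call.unstable_components) / total
        assert shift == pytest.approx(-6.0, abs=0.5)

    def test_no_coverage_is_non_contributory(self, profile):
        empty = LengthHistogram.from_counts(profile.locus, {})
        call = call_microsatellite(empty, profile, CFG)
        assert call.status == NON_CONTRIBUTORY
        assert call.n_reads == 0

    def test_subminimal_histogram_is_non_contributory(self, profile):
        h = LengthHistogram.from_counts(profile.locus, {int(round(profile.mean)): 10})
        assert call_microsatellite(h, profile, CFG).status == NON_CONTRIBUTORY

    def test_subthreshold_instability_called_stable(self, profile):
        """1.5% unstable alleles sit below the 2% proportion gate."""
        rng = np.random.default_rng(61)
        truth = {l: 0.985 * p for l, p in shift_profile(profile, profile.mean).items()}
        for l, p in shift_profile(profile, profile.mean - 6).items():
            truth[l] = truth.get(l, 0.0) + 0.015 * p
        h = draw_histogram(profile, truth, 4000, rng)
        call = call_microsatellite(h, profile, CFG)
        assert call.status == STABLE

    def test_heterozygous_shift_flags_polymorphism(self, profile):
        """A single unstable component near 50% raises a germline
        polymorphism suspicion rather than silently passing."""
        rng = np.random.default_rng(62)
        truth = {l: 0.5 * p for l, p in shift_profile(profile, profile.mean).items()}
        for l, p in shift_profile(profile, profile.mean - 4).items():
            truth[l] = truth.get(l, 0.0) + 0.5 * p
        h = draw_histogram(profile, truth, 4000, rng)
        call = call_microsatellite(h, profile, CFG)
        assert call.status == UNSTABLE
        assert call.polymorphism_suspected

    def test_monotone_in_unstable_fraction(self, panel, profiles):
        """Raising the unstable fraction (same read-noise seed) never flips
        an unstable call back to stable."""
        loci, stable = panel
        l = loci[0]
        statuses = []
        for fraction in (0.03, 0.06, 0.12, 0.25, 0.50):
            spec = SimulatedLocusSpec.with_unstable(
                l, stable[l.name], fraction, depth=1000, seed=77
            )
            mates, _ = simulate_sample([spec])
            h = extract_histograms(mates, [l])[l.name]
            statuses.append(call_microsatellite(h, profiles[l.name], CFG).status)
        seen_unstable = False
        for status in statuses:
            if status == UNSTABLE:
                seen_unstable = True
            assert not (seen_unstable and status == STABLE)


class TestDecisionTable:
    def test_exhaustive_cascade(self):
        """Every combination of cascade inputs maps to exactly one status
        and matches the published rules."""
        cfg = CFG
        for all_stable, total, sig, power in itertools.product(
            (True, False),
            (0.0, 0.015, 0.02, 0.5),
            (None, True, False),
            (None, 0.5, 0.80, 0.81),
        ):
            status = decide_status(all_stable, total, sig, power, cfg)
            if all_stable or total < 0.02:
                assert status == STABLE
            elif sig:
                assert status == UNSTABLE
            elif power is not None and power > 0.80:
                assert status == STABLE
            else:
                assert status == NON_CONTRIBUTORY


class TestCallSample:
    @pytest.mark.parametrize(
        "statuses,expected",
        [
            ((UNSTABLE, UNSTABLE, STABLE, STABLE, STABLE), MSI),
            ((UNSTABLE, STABLE, STABLE, STABLE, STABLE), MSS),
            ((UNSTABLE,) * 4 + (NON_CONTRIBUTORY,), MSI),
            ((STABLE, STABLE) + (NON_CONTRIBUTORY,) * 3, NON_CONTRIBUTORY),
            ((STABLE,) * 5, MSS),
            ((UNSTABLE, UNSTABLE) + (NON_CONTRIBUTORY,) * 3, MSI),
        ],
    )
    def test_decision_rule(self, statuses, expected):
        calls = [make_call(f"L{i}", s) for i, s in enumerate(statuses)]
        verdict = call_sample(calls, CFG)
        assert verdict.status == expected

    def test_duplicate_locus_rejected(self):
        calls = [make_call("L0", STABLE)] * 2
        with pytest.raises(ValueError, match="duplicate"):
            call_sample(calls, CFG)

    def test_panel_mismatch_rejected(self):
        calls = [make_call(f"L{i}", STABLE) for i in range(4)]
        with pytest.raises(ValueError, match="missing"):
            call_sample(calls, CFG, expected_loci=[f"L{i}" for i in range(5)])
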