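"""Per-microsatellite stability decisions and the sample-level MSI verdict.

Decision cascade for one locus, given the fitted mixture:

1. A component is *stable* when its mean lies within ±10% of the reference
   mean, *potentially unstable* otherwise.
2. If every component is stable, or the unstable components jointly carry
   less than 2% of the mixture, the locus is **stable**.
3. Otherwise a likelihood-ratio test compares the full mixture to a model
   refitted with the stable components only.  A significant test makes the
   locus **unstable**, and the unstable components' mean shifts and
   proportions quantify the instability.
4. A non-significant test falls back on statistical power: if, at the
   observed read depth, the test would detect a minimal instability (2%
   unstable alleles shifted by -6 nt) with more than 80% probability, the
   locus is **stable**; otherwise the data simply cannot tell and the
   locus is **non-contributory**.

A sample is MSI when at least two of the five panel microsatellites are
unstable; MSS when at most one is, provided enough loci were contributory.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .em import EMConfig, MixtureFit, em_fit, log_likelihood
from .extraction import LengthHistogram
from .profiles import ReferenceProfile, shift_profile

STABLE = "stable"
UNSTABLE = "unstable"
NON_CONTRIBUTORY = "non_contributory"
MSI = "MSI"
MSS = "MSS"


@dataclass(frozen=True)
class ClassificationConfig:
    """Thresholds of the decision cascade.

    Defaults implement the published rule set: ±10% stable band, 2% minimum
    unstable proportion, 80% power gate, >=2/5 unstable loci for MSI.
    ``min_reads`` guards against interpreting near-empty histograms;
    ``min_contributory_loci`` prevents an MSS claim from too few
    interpretable loci.
    """

    stable_mean_tolerance: float = 0.10
    min_unstable_proportion: float = 0.02
    power_threshold: float = 0.80
    lrt_alpha: float = 0.01
    power_mc_replicates: int = 100
    power_effect_shift: float = -6.0
    min_reads: int = 50
    min_unstable_loci_for_msi: int = 2
    min_contributory_loci: int = 4
    polymorphism_band: tuple[float, float] = (0.40, 0.60)
    seed: int = 0
    em: EMConfig = field(default_factory=EMConfig)

    def __post_init__(self) -> None:
        for name in ("stable_mean_tolerance", "min_unstable_proportion", "power_threshold"):
            value = getattr(self, name)
            if not 0 < value < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if not 0 < self.lrt_alpha < 1:
            raise ValueError("lrt_alpha must be in (0, 1)")


@dataclass(frozen=True)
class MicrosatelliteCall:
    """Decision for one locus, with the quantities that produced it."""

    locus: str
    status: str
    unstable_components: tuple[tuple[float, float], ...]  # (mean shift nt, proportion)
    n_reads: int
    lrt_statistic: Optional[float] = None
    lrt_p: Optional[float] = None
    power: Optional[float] = None
    polymorphism_suspected: bool = False
    fit: Optional[MixtureFit] = None


@dataclass(frozen=True)
class SampleCall:
    """Sample-level verdict over the five-microsatellite panel."""

    sample: str
    per_locus: tuple[MicrosatelliteCall, ...]
    status: str

    @property
    def n_unstable(self) -> int:
        return sum(c.status == UNSTABLE for c in self.per_locus)


def classify_components(
    fit: MixtureFit, profile: ReferenceProfile, config: ClassificationConfig
) -> tuple[bool, ...]:
    """Stable flag per component: True iff its mean sits within the
    ±``stable_mean_tolerance`` band around the reference mean (inclusive)."""
    band = config.stable_mean_tolerance * profile.mean
    return tuple(abs(m - profile.mean) <= band for m in fit.means)


def _stable_bounds(
    profile: ReferenceProfile, config: ClassificationConfig
) -> tuple[float, float]:
    band = config.stable_mean_tolerance * profile.mean
    lo = max(float(profile.lengths[0]), profile.mean - band)
    hi = min(float(profile.lengths[-1]), profile.mean + band)
    return lo, hi


def lrt(
    histogram: LengthHistogram,
    full_fit: MixtureFit,
    profile: ReferenceProfile,
    config: ClassificationConfig,
) -> tuple[float, float]:
    """Likelihood-ratio test of the full mixture against the stable-only model.

    The reduced model is refitted by EM with its component means confined to
    the stable band (so it cannot wander off and explain the unstable
    mode), seeded from the stable components of the full fit.  The
    chi-square reference uses 2 degrees of freedom per removed component
    (one mean, one proportion) — conservative at the boundary.
    """
    flags = classify_components(full_fit, profile, config)
    n_unstable = sum(not f for f in flags)
    if n_unstable == 0:
        return 0.0, 1.0
    stable_means = [m for m, f in zip(full_fit.means, flags) if f]
    stable_props = [p for p, f in zip(full_fit.proportions, flags) if f]
    if stable_means:
        init_means = stable_means
        total = sum(stable_props)
        init_props = (
            [p / total for p in stable_props] if total > 0 else None
        )
    else:
        init_means = [profile.mean]
        init_props = [1.0]
    reduced = em_fit(
        histogram,
        profile,
        k=len(init_means),
        config=config.em,
        mean_bounds=_stable_bounds(profile, config),
        init_means=init_means,
        init_proportions=init_props,
    )
    statistic = 2.0 * (full_fit.log_likelihood - reduced.log_likelihood)
    statistic = max(statistic, 0.0)
    df = 2 * n_unstable
    p_value = float(stats.chi2.sf(statistic, df))
    return statistic, p_value


def _sample_alternative_histogram(
    n_reads: int,
    profile: ReferenceProfile,
    config: ClassificationConfig,
    rng: np.random.Generator,
) -> LengthHistogram:
    """Draw a histogram from the minimal-instability alternative: stable
    component at the reference mean plus ``min_unstable_proportion`` of
    reads shifted by ``power_effect_shift``."""
    q = config.min_unstable_proportion
    alt: dict[int, float] = {}
    for length, p in zip(profile.lengths.tolist(), profile.probs.tolist()):
        alt[length] = alt.get(length, 0.0) + (1.0 - q) * p
    for length, p in shift_profile(
        profile, profile.mean + config.power_effect_shift
    ).items():
        alt[length] = alt.get(length, 0.0) + q * p
    lengths = np.array(sorted(alt))
    probs = np.array([alt[int(l)] for l in lengths])
    probs = probs / probs.sum()
    counts = rng.multinomial(n_reads, probs)
    return LengthHistogram.from_counts(
        profile.locus, {int(l): int(c) for l, c in zip(lengths, counts) if c > 0}
    )


def _rejects(
    histogram: LengthHistogram, profile: ReferenceProfile, config: ClassificationConfig
) -> bool:
    # Power replicates only need the cascade's verdict, not a polished fit:
    # a single deterministic start and a coarser tolerance suffice.
    config = replace(
        config,
        em=replace(config.em, n_restarts=1, loglik_tolerance=1e-4, max_iterations=200),
    )
    fit = em_fit(histogram, profile, k=3, config=config.em)
    # Power of the likelihood-ratio test itself: the proportion gate is a
    # separate guard of the cascade, not part of the test whose power the
    # coverage question is about.
    _stat, p = lrt(histogram, fit, profile, config)
    return p < config.lrt_alpha


def estimate_power(
    n_reads: int,
    profile: ReferenceProfile,
    config: ClassificationConfig,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Monte Carlo power of the instability test at the observed depth.

    Simulates ``power_mc_replicates`` datasets of ``n_reads`` observations
    from the minimal-instability alternative and measures how often the
    cascade rejects stability.  Seeded from ``config.seed`` and ``n_reads``
    for reproducibility; monotone non-decreasing in ``n_reads`` up to Monte
    Carlo error.
    """
    if n_reads <= 0:
        return 0.0
    if rng is None:
        rng = np.random.default_rng((config.seed, n_reads))
    hits = 0
    for _ in range(config.power_mc_replicates):
        histogram = _sample_alternative_histogram(n_reads, profile, config, rng)
        if _rejects(histogram, profile, config):
            hits += 1
    return hits / config.power_mc_replicates


def min_reads_for_power(
    profile: ReferenceProfile,
    config: ClassificationConfig,
    lo: int = 50,
    hi: int = 200_000,
) -> int:
    """Smallest read count whose estimated power clears the gate, by
    doubling search then bisection.  This is the machinery that yields the
    per-locus minimum coverage required for a locus to be interpretable."""
    n = lo
    while n < hi and estimate_power(n, profile, config) < config.power_threshold:
        n *= 2
    upper, lower = min(n, hi), max(lo, n // 2)
    while upper - lower > max(1, lower // 20):
        mid = (upper + lower) // 2
        if estimate_power(mid, profile, config) >= config.power_threshold:
            upper = mid
        else:
            lower = mid
    return upper


def decide_status(
    all_stable: bool,
    total_unstable_proportion: float,
    lrt_significant: Optional[bool],
    power: Optional[float],
    config: ClassificationConfig,
) -> str:
    """Pure decision table of the cascade (exhaustively testable).

    ``lrt_significant`` / ``power`` are None on branches where they are
    not evaluated.
    """
    if all_stable or total_unstable_proportion < config.min_unstable_proportion:
        return STABLE
    if lrt_significant:
        return UNSTABLE
    if power is not None and power > config.power_threshold:
        return STABLE
    return NON_CONTRIBUTORY


def call_microsatellite(
    histogram: LengthHistogram,
    profile: ReferenceProfile,
    config: ClassificationConfig = ClassificationConfig(),
    power_cache: Optional[dict] = None,
) -> MicrosatelliteCall:
    """Run the full decision cascade for one locus.

    An empty or sub-minimal histogram (``n_reads < config.min_reads``,
    e.g. constitutive lack of coverage) is non-contributory outright.
    ``power_cache`` optionally memoises power estimates across samples
    keyed by (locus, n_reads).
    """
    n = histogram.n_reads
    if n < config.min_reads:
        return MicrosatelliteCall(
            locus=histogram.locus,
            status=NON_CONTRIBUTORY,
            unstable_components=(),
            n_reads=n,
        )
    fit = em_fit(histogram, profile, k=3, config=config.em)
    flags = classify_components(fit, profile, config)
    unstable = [
        (m - profile.mean, p)
        for m, p, f in zip(fit.means, fit.proportions, flags)
        if not f
    ]
    total_unstable = sum(p for _s, p in unstable)
    if all(flags) or total_unstable < config.min_unstable_proportion:
        return MicrosatelliteCall(
            locus=histogram.locus,
            status=STABLE,
            unstable_components=(),
            n_reads=n,
            fit=fit,
        )
    statistic, p_value = lrt(histogram, fit, profile, config)
    if p_value < config.lrt_alpha:
        reported = tuple(
            (shift, prop)
            for shift, prop in unstable
            if prop >= config.min_unstable_proportion
        )
        if not reported:  # jointly above threshold but individually below
            reported = tuple(unstable)
        lo, hi = config.polymorphism_band
        polymorphism = len(reported) == 1 and lo <= reported[0][1] <= hi
        return MicrosatelliteCall(
            locus=histogram.locus,
            status=UNSTABLE,
            unstable_components=reported,
            n_reads=n,
            lrt_statistic=statistic,
            lrt_p=p_value,
            polymorphism_suspected=polymorphism,
            fit=fit,
        )
    # power varies slowly with depth: cache per ~10% depth bucket
    bucket_width = max(25, n // 10)
    cache_key = (histogram.locus, bucket_width * round(n / bucket_width))
    if power_cache is not None and cache_key in power_cache:
        power = power_cache[cache_key]
    else:
        power = estimate_power(n, profile, config)
        if power_cache is not None:
            power_cache[cache_key] = power
    status = STABLE if power > config.power_threshold else NON_CONTRIBUTORY
    return MicrosatelliteCall(
        locus=histogram.locus,
        status=status,
        unstable_components=(),
        n_reads=n,
        lrt_statistic=statistic,
        lrt_p=p_value,
        power=power,
        fit=fit,
    )


def call_sample(
    calls: Sequence[MicrosatelliteCall],
    config: ClassificationConfig = ClassificationConfig(),
    sample: str = "sample",
    expected_loci: Optional[Sequence[str]] = None,
) -> SampleCall:
    """Aggregate per-locus calls into the sample MSI / MSS verdict.

    MSI requires at least ``min_unstable_loci_for_msi`` unstable loci; MSS
    additionally requires at least ``min_contributory_loci`` interpretable
    loci — otherwise the sample itself is non-contributory.
    """
    names = [c.locus for c in calls]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate locus calls: {sorted(names)}")
    if expected_loci is not None:
        missing = set(expected_loci) - set(names)
        extra = set(names) - set(expected_loci)
        if missing or extra:
            raise ValueError(
                f"panel mismatch: missing {sorted(missing)}, unexpected {sorted(extra)}"
            )
    n_unstable = sum(c.status == UNSTABLE for c in calls)
    n_contributory = sum(c.status != NON_CONTRIBUTORY for c in calls)
    if n_unstable >= config.min_unstable_loci_for_msi:
        status = MSI
    elif n_contributory >= config.min_contributory_loci:
        status = MSS
    else:
        status = NON_CONTRIBUTORY
    return SampleCall(sample=sample, per_locus=tuple(calls), status=status)


def call_sample_from_histograms(
    histograms: Mapping[str, LengthHistogram],
    profiles: Mapping[str, ReferenceProfile],
    config: ClassificationConfig = ClassificationConfig(),
    sample: str = "sample",
    power_cache: Optional[dict] = None,
) -> SampleCall:
    """Convenience pipeline tail: per-locus cascade then the sample verdict."""
    missing = set(profiles) - set(histograms)
    if missing:
        raise ValueError(
            f"no histograms for profiled loci: {sorted(missing)} "
            "(panel and reference-profile files disagree?)"
        )
    calls = [
        call_microsatellite(histograms[locus], profiles[locus], config, power_cache)
        for locus in profiles
    ]
    return call_sample(calls, config, sample=sample, expected_loci=list(profiles))
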