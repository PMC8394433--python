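"""In-silico study designs: detection-limit ladders and dilution linearity.

These routines wire the simulator to the full pipeline (extraction -> EM ->
decision cascade) the same way a wet-lab dilution experiment would feed the
sequencer: a synthetic MSI-positive control is mixed into an MSS background
at decreasing fractions and every mixture is processed blind.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .calls import (
    MSI,
    UNSTABLE,
    ClassificationConfig,
    SampleCall,
    call_sample_from_histograms,
    classify_components,
)
from .extraction import extract_histograms
from .loci import MicrosatelliteLocus
from .profiles import ReferenceProfile, build_reference
from .simulate import (
    DEFAULT_DILUTIONS,
    DEFAULT_POSITIVE_FRACTIONS,
    SimulatedLocusSpec,
    simulate_dilution_series,
    simulate_sample,
)


def build_reference_profiles(
    loci: Sequence[MicrosatelliteLocus],
    stable_lengths: Mapping[str, int],
    depth: int = 5000,
    n_controls: int = 4,
    stutter_sd: float = 1.0,
    seed: int = 0,
) -> dict[str, ReferenceProfile]:
    """Emulate a pool of MSS control samples and build reference profiles
    through the real extraction path."""
    per_locus: dict[str, list] = {l.name: [] for l in loci}
    for control in range(n_controls):
        specs = [
            SimulatedLocusSpec.with_unstable(
                l,
                stable_lengths[l.name],
                0.0,
                depth=depth,
                stutter_sd=stutter_sd,
                seed=seed + 131 * control + i,
            )
            for i, l in enumerate(loci)
        ]
        mates, _ = simulate_sample(specs)
        for name, histogram in extract_histograms(mates, loci).items():
            per_locus[name].append(histogram)
    return {name: build_reference(hists) for name, hists in per_locus.items()}


def simulate_and_call(
    loci: Sequence[MicrosatelliteLocus],
    stable_lengths: Mapping[str, int],
    profiles: Mapping[str, ReferenceProfile],
    unstable_fractions: Mapping[str, float],
    depth: int = 2000,
    stutter_sd: float = 1.0,
    unstable_shift: int = -6,
    seed: int = 0,
    config: ClassificationConfig = ClassificationConfig(),
    power_cache: Optional[dict] = None,
    sample: str = "sim",
) -> SampleCall:
    """One simulated sample through the whole pipeline."""
    specs = [
        SimulatedLocusSpec.with_unstable(
            l,
            stable_lengths[l.name],
            unstable_fractions.get(l.name, 0.0),
            unstable_shift=unstable_shift,
            depth=depth,
            stutter_sd=stutter_sd,
            seed=seed + i,
        )
        for i, l in enumerate(loci)
    ]
    mates, _ = simulate_sample(specs)
    histograms = extract_histograms(mates, loci)
    return call_sample_from_histograms(
        histograms, dict(profiles), config, sample=sample, power_cache=power_cache
    )


def msi_call_rate(
    loci: Sequence[MicrosatelliteLocus],
    stable_lengths: Mapping[str, int],
    profiles: Mapping[str, ReferenceProfile],
    unstable_fraction: float,
    n_seeds: int = 20,
    depth: int = 2000,
    stutter_sd: float = 1.0,
    unstable_shift: int = -6,
    seed: int = 0,
    config: ClassificationConfig = ClassificationConfig(),
    power_cache: Optional[dict] = None,
) -> float:
    """Fraction of seeded replicates called MSI at one unstable fraction."""
    fractions = {l.name: unstable_fraction for l in loci}
    hits = 0
    for replicate in range(n_seeds):
        verdict = simulate_and_call(
            loci,
            stable_lengths,
            profiles,
            fractions,
            depth=depth,
            stutter_sd=stutter_sd,
            unstable_shift=unstable_shift,
            seed=seed + 7919 * replicate,
            config=config,
            power_cache=power_cache,
        )
        hits += verdict.status == MSI
    return hits / n_seeds


@dataclass(frozen=True)
class DetectionLimitResult:
    fractions: tuple[float, ...]
    msi_rates: tuple[float, ...]
    limit: Optional[float]  # smallest tested fraction with rate >= threshold


def detection_limit(
    loci: Sequence[MicrosatelliteLocus],
    stable_lengths: Mapping[str, int],
    profiles: Mapping[str, ReferenceProfile],
    fractions: Sequence[float] = (0.185, 0.093, 0.062, 0.05, 0.037),
    n_seeds: int = 20,
    depth: int = 2000,
    stutter_sd: float = 1.0,
    unstable_shift: int = -6,
    rate_threshold: float = 0.9,
    seed: int = 0,
    config: ClassificationConfig = ClassificationConfig(),
) -> DetectionLimitResult:
    """Sweep a ladder of unstable fractions (a dilution-series analogue)
    and report the smallest tested fraction still called MSI in at least
    ``rate_threshold`` of replicates."""
    cache: dict = {}
    rates = []
    for index, fraction in enumerate(fractions):
        rates.append(
            msi_call_rate(
                loci,
                stable_lengths,
                profiles,
                fraction,
                n_seeds=n_seeds,
                depth=depth,
                stutter_sd=stutter_sd,
                unstable_shift=unstable_shift,
                seed=seed + 104729 * index,
                config=config,
                power_cache=cache,
            )
        )
    detected = [f for f, r in zip(fractions, rates) if r >= rate_threshold]
    return DetectionLimitResult(
        fractions=tuple(fractions),
        msi_rates=tuple(rates),
        limit=min(detected) if detected else None,
    )


@dataclass(frozen=True)
class LinearityResult:
    expected: dict[str, list[float]]
    estimated: dict[str, list[float]]
    r_squared: dict[str, float]

    @property
    def min_r_squared(self) -> float:
        return min(self.r_squared.values())


def dilution_linearity(
    loci: Sequence[MicrosatelliteLocus],
    stable_lengths: Mapping[str, int],
    profiles: Mapping[str, ReferenceProfile],
    positive_fractions: Mapping[str, float] = DEFAULT_POSITIVE_FRACTIONS,
    dilutions: Sequence[float] = (1.0,) + tuple(DEFAULT_DILUTIONS),
    n_seeds: int = 3,
    depth: int = 2000,
    stutter_sd: float = 1.0,
    unstable_shift: int = -6,
    seed: int = 0,
    config: ClassificationConfig = ClassificationConfig(),
) -> LinearityResult:
    """Regress the EM-quantified unstable proportion on the expected one
    across a dilution series; R^2 per locus.

    The estimated proportion is the summed proportion of components
    classified unstable in the per-locus fit (whatever the final status),
    i.e. exactly the quantification the caller reports.
    """
    expected: dict[str, list[float]] = {l.name: [] for l in loci}
    estimated: dict[str, list[float]] = {l.name: [] for l in loci}
    cache: dict = {}
    for replicate in range(n_seeds):
        series = simulate_dilution_series(
            loci,
            stable_lengths,
            positive_fractions=positive_fractions,
            dilutions=dilutions,
            depth=depth,
            stutter_sd=stutter_sd,
            unstable_shift=unstable_shift,
            seed=seed + 15485863 * replicate,
        )
        for sample in series:
            mates, _ = simulate_sample(list(sample.specs))
            histograms = extract_histograms(mates, loci)
            verdict = call_sample_from_histograms(
                histograms, dict(profiles), config, power_cache=cache
            )
            for call in verdict.per_locus:
                fit = call.fit
                if fit is None:
                    continue
                profile = profiles[call.locus]
                flags = classify_components(fit, profile, config)
                total = sum(
                    p for p, f in zip(fit.proportions, flags) if not f
                )
                expected[call.locus].append(sample.expected_fractions[call.locus])
                estimated[call.locus].append(total)
    r_squared = {}
    for name in expected:
        regression = stats.linregress(expected[name], estimated[name])
        r_squared[name] = float(regression.rvalue**2)
    return LinearityResult(expected=expected, estimated=estimated, r_squared=r_squared)
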