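"""Shared fixtures: a synthetic five-locus panel and reference profiles
built by running the simulator output through the extraction module."""

from __future__ import annotations

import numpy as np
import pytest

from msicall.extraction import LengthHistogram, extract_histograms
from msicall.profiles import ReferenceProfile, build_reference
from msicall.simulate import SimulatedLocusSpec, simulate_sample, synthetic_panel

PANEL_SEED = 20210820


@pytest.fixture(scope="session")
def panel():
    loci, stable_lengths = synthetic_panel(seed=PANEL_SEED)
    return loci, stable_lengths


@pytest.fixture(scope="session")
def locus(panel):
    """A single convenient locus (BAT-26-like, 26 nt stable run)."""
    loci, _ = panel
    return next(l for l in loci if l.name == "BAT-26")


@pytest.fixture(scope="session")
def profiles(panel) -> dict[str, ReferenceProfile]:
    """Reference profiles from a pooled MSS control simulation, through the
    real extraction path (stutter SD 1 nt, 4000 read pairs per locus)."""
    loci, stable_lengths = panel
    specs = [
        SimulatedLocusSpec.with_unstable(
            l, stable_lengths[l.name], 0.0, depth=4000, stutter_sd=1.0, seed=900 + i
        )
        for i, l in enumerate(loci)
    ]
    mates, _ = simulate_sample(specs)
    histograms = extract_histograms(mates, loci)
    return {name: build_reference([h]) for name, h in histograms.items()}


@pytest.fixture(scope="session")
def profile(profiles, locus) -> ReferenceProfile:
    return profiles[locus.name]


@pytest.fixture()
def toy_profile() -> ReferenceProfile:
    """Small exact profile (mean 26.0, no pseudocount) for arithmetic tests."""
    h = LengthHistogram.from_counts("TOY", {25: 50, 26: 900, 27: 50})
    return build_reference([h], min_total_reads=100, pseudocount=0.0)


def draw_histogram(
    profile: ReferenceProfile,
    pmf: dict[int, float],
    n: int,
    rng: np.random.Generator,
) -> LengthHistogram:
    """Multinomial sample of ``n`` observations from an arbitrary pmf."""
    lengths = np.array(sorted(pmf))
    probs = np.array([pmf[int(l)] for l in lengths], dtype=float)
    probs = probs / probs.sum()
    counts = rng.multinomial(n, probs)
    return LengthHistogram.from_counts(
        profile.locus, {int(l): int(c) for l, c in zip(lengths, counts) if c > 0}
    )
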