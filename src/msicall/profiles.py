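"""Empirical reference length distributions for each microsatellite.

A reference profile is the normalized length distribution of a locus in a
pool of microsatellite-stable (MSS) control samples.  It captures the PCR
stutter shape of the locus empirically — no parametric (e.g. normal) form
is assumed, because observed stutter distributions are asymmetric and
locus-specific.  The profile acts as a fixed "shape" that can be translated
along the length axis: every component of the mixture model is this shape
relocated to a candidate allele mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .extraction import LengthHistogram

SCHEMA_VERSION = 1
DEFAULT_PSEUDOCOUNT = 1e-6
DEFAULT_MIN_TOTAL_READS = 500
SUPPORT_PAD = 3


class ReferenceBuildError(ValueError):
    """Raised when control data are insufficient to build a profile."""


class ProfileFormatError(ValueError):
    """Raised for unreadable or inconsistent profile files."""


@dataclass(frozen=True)
class ReferenceProfile:
    """Empirical normalized length distribution of one locus in MSS controls.

    ``lengths`` is a contiguous integer support (padded beyond the observed
    range); ``probs`` the corresponding probabilities after pseudocount
    flooring, summing to 1.
    """

    locus: str
    lengths: np.ndarray  # contiguous ints, ascending
    probs: np.ndarray
    mean: float
    n_source_reads: int
    pseudocount: float

    def __post_init__(self) -> None:
        lengths = np.asarray(self.lengths, dtype=int)
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "lengths", lengths)
        object.__setattr__(self, "probs", probs)
        if lengths.shape != probs.shape or lengths.ndim != 1 or lengths.size == 0:
            raise ProfileFormatError("lengths and probs must be 1-D and matched")
        if np.any(np.diff(lengths) != 1):
            raise ProfileFormatError("support must be contiguous")
        if abs(probs.sum() - 1.0) > 1e-6:
            raise ProfileFormatError(
                f"probabilities sum to {probs.sum():.6f}, expected 1"
            )
        recomputed = float(np.dot(lengths, probs))
        if abs(recomputed - self.mean) > 1e-6:
            raise ProfileFormatError(
                f"stored mean {self.mean} disagrees with pmf mean {recomputed}"
            )

    @property
    def pmf(self) -> dict[int, float]:
        return dict(zip(self.lengths.tolist(), self.probs.tolist()))

    @property
    def support(self) -> tuple[int, int]:
        """Closed support bounds (min, max)."""
        return int(self.lengths[0]), int(self.lengths[-1])

    def component_pmf(self, at_lengths: np.ndarray, component_mean: float) -> np.ndarray:
        """Profile shape relocated so its expected value is ``component_mean``,
        evaluated at integer ``at_lengths`` and floored at ``pseudocount``.

        Fractional relocation interpolates linearly between the two adjacent
        integer translations, which keeps the empirical shape and makes the
        component mean exact.  The floor keeps log-likelihoods finite for
        observed lengths outside the translated support.
        """
        shift = component_mean - self.mean
        lo = int(np.floor(shift))
        frac = shift - lo
        at = np.asarray(at_lengths)
        val = (1.0 - frac) * self._translated(at, lo) + frac * self._translated(at, lo + 1)
        if self.pseudocount > 0:
            return np.maximum(val, self.pseudocount)
        return val

    def _translated(self, at: np.ndarray, shift: int) -> np.ndarray:
        idx = at - shift - int(self.lengths[0])
        ok = (idx >= 0) & (idx < self.lengths.size)
        out = np.zeros(at.shape, dtype=float)
        out[ok] = self.probs[idx[ok]]
        return out


def build_reference(
    histograms: Sequence[LengthHistogram],
    min_total_reads: int = DEFAULT_MIN_TOTAL_READS,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> ReferenceProfile:
    """Merge control histograms of one locus into a reference profile.

    Counts are summed (order-invariant), normalized over the observed
    range padded by ±3 bins, floored at ``pseudocount`` per bin and
    renormalized; the mean is recomputed from the final pmf.
    """
    if not histograms:
        raise ReferenceBuildError("at least one histogram is required")
    names = {h.locus for h in histograms}
    if len(names) != 1:
        raise ReferenceBuildError(f"histograms from multiple loci: {sorted(names)}")
    locus = histograms[0].locus
    merged: dict[int, int] = {}
    for h in histograms:
        for length, count in h.counts.items():
            merged[length] = merged.get(length, 0) + count
    total = sum(merged.values())
    if total < min_total_reads:
        raise ReferenceBuildError(
            f"{locus}: {total} control reads, need {min_total_reads} "
            f"(deficit {min_total_reads - total})"
        )
    lo = max(0, min(merged) - SUPPORT_PAD)
    hi = max(merged) + SUPPORT_PAD
    lengths = np.arange(lo, hi + 1)
    counts = np.array([merged.get(int(l), 0) for l in lengths], dtype=float)
    frac = counts / counts.sum()
    frac = np.maximum(frac, pseudocount)
    probs = frac / frac.sum()
    mean = float(np.dot(lengths, probs))
    return ReferenceProfile(
        locus=locus,
        lengths=lengths,
        probs=probs,
        mean=mean,
        n_source_reads=total,
        pseudocount=pseudocount,
    )


def shift_profile(profile: ReferenceProfile, target_mean: float) -> dict[int, float]:
    """The profile's shape translated so its expected value is ``target_mean``.

    Integer shifts translate mass bin-for-bin; fractional shifts linearly
    interpolate the two adjacent integer translations so the expectation is
    exact.  Mass that would land below length 0 is truncated and the
    distribution renormalized.
    """
    if target_mean < 0:
        raise ValueError("target_mean must be non-negative")
    shift = target_mean - profile.mean
    lo = int(np.floor(shift))
    frac = shift - lo
    out: dict[int, float] = {}
    for offset, weight in ((lo, 1.0 - frac), (lo + 1, frac)):
        if weight == 0.0:
            continue
        for length, p in zip(profile.lengths.tolist(), profile.probs.tolist()):
            out[length + offset] = out.get(length + offset, 0.0) + weight * p
    truncated = {k: v for k, v in out.items() if k >= 0}
    total = sum(truncated.values())
    if total < 1.0 - 1e-12:  # mass fell below zero: renormalize
        truncated = {k: v / total for k, v in truncated.items()}
    return dict(sorted(truncated.items()))


def _profile_to_dict(profile: ReferenceProfile) -> dict:
    return {
        "locus": profile.locus,
        "n_source_reads": int(profile.n_source_reads),
        "pseudocount": float(profile.pseudocount),
        "mean": round(float(profile.mean), 9),
        "pmf": {int(l): float(p) for l, p in zip(profile.lengths, profile.probs)},
    }


def _profile_from_dict(data: Mapping) -> ReferenceProfile:
    try:
        pmf = {int(k): float(v) for k, v in data["pmf"].items()}
        lengths = np.array(sorted(pmf), dtype=int)
        probs = np.array([pmf[int(l)] for l in lengths], dtype=float)
        return ReferenceProfile(
            locus=str(data["locus"]),
            lengths=lengths,
            probs=probs,
            mean=float(data["mean"]),
            n_source_reads=int(data["n_source_reads"]),
            pseudocount=float(data["pseudocount"]),
        )
    except ProfileFormatError:
        raise
    except (KeyError, TypeError, ValueError) as exc:
        raise ProfileFormatError(f"invalid profile record: {exc}") from exc


def save_profiles(profiles: Mapping[str, ReferenceProfile] | Sequence[ReferenceProfile], path: str | Path) -> None:
    """Write reference profiles to a human-readable, versioned YAML file."""
    if isinstance(profiles, Mapping):
        items = list(profiles.values())
    else:
        items = list(profiles)
    doc = {
        "schema_version": SCHEMA_VERSION,
        "profiles": [_profile_to_dict(p) for p in items],
    }
    with open(path, "w") as handle:
        handle.write("# msicall reference profiles\n")
        yaml.safe_dump(doc, handle, sort_keys=False)


def load_profiles(path: str | Path) -> dict[str, ReferenceProfile]:
    with open(path) as handle:
        doc = yaml.safe_load(handle)
    if not isinstance(doc, Mapping) or "schema_version" not in doc:
        raise ProfileFormatError(f"{path}: not a profile file")
    if doc["schema_version"] != SCHEMA_VERSION:
        raise ProfileFormatError(
            f"{path}: schema version {doc['schema_version']} not supported "
            f"(expected {SCHEMA_VERSION})"
        )
    profiles = [_profile_from_dict(rec) for rec in doc.get("profiles", [])]
    return {p.locus: p for p in profiles}


def save_profile(profile: ReferenceProfile, path: str | Path) -> None:
    save_profiles([profile], path)


def load_profile(path: str | Path, locus: str | None = None) -> ReferenceProfile:
    profiles = load_profiles(path)
    if locus is None:
        if len(profiles) != 1:
            raise ProfileFormatError(
                f"{path} holds {len(profiles)} profiles; specify a locus"
            )
        return next(iter(profiles.values()))
    try:
        return profiles[locus]
    except KeyError:
        raise ProfileFormatError(f"{path}: no profile for locus {locus}") from None
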