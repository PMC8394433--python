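"""Amplicon-like paired-end read simulation for microsatellite loci.

Reads carry a flank5 + homopolymer + flank3 insert embedded in random
sequence context, with replication-slippage length noise around each
allele.  The stutter model is a deletion-skewed two-sided geometric: with
probability ``a`` the observed run length is offset by a geometrically
distributed magnitude, deletions three times as likely as insertions.  The
closed-form pmf and moments make the simulator auditable, and mixtures of
a stable and one or two shifted unstable alleles at configurable fractions
emulate tumour dilution experiments in silico.
"""

from __future__ import annotations

import gzip
import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .loci import MicrosatelliteLocus
from .extraction import reverse_complement

READ_LENGTH = 150
DELETION_ODDS = 3.0  # deletions : insertions

# Fractions of unstable alleles measured in a typical MSI-positive control,
# per locus, used as dilution-series defaults.
DEFAULT_POSITIVE_FRACTIONS: dict[str, float] = {
    "BAT-25": 0.73,
    "BAT-26": 0.77,
    "NR-21": 0.74,
    "NR-24": 0.70,
    "NR-27": 0.77,
}
DEFAULT_DILUTIONS = (1 / 4, 1 / 8, 1 / 12, 1 / 16, 1 / 20)

_BETHESDA_STABLE_LENGTHS = {
    "BAT-25": 25,
    "BAT-26": 26,
    "NR-21": 21,
    "NR-24": 24,
    "NR-27": 27,
}


@dataclass(frozen=True)
class StutterModel:
    """Two-sided geometric slippage-offset distribution.

    offset = 0 with probability 1-a; otherwise magnitude ~ Geometric(p)
    (support >= 1), deletion with probability 3/4, insertion 1/4.
    """

    a: float
    p: float
    offsets: np.ndarray
    probs: np.ndarray

    @property
    def mean(self) -> float:
        w_del = DELETION_ODDS / (DELETION_ODDS + 1.0)
        return -self.a * (2.0 * w_del - 1.0) / self.p

    @property
    def variance(self) -> float:
        eg2 = (2.0 - self.p) / self.p**2
        return self.a * eg2 - self.mean**2

    @property
    def sd(self) -> float:
        return math.sqrt(self.variance)


def stutter_model(stutter_sd: float, tail_tol: float = 1e-12) -> StutterModel:
    """Calibrate (a, p) so the offset standard deviation equals ``stutter_sd``.

    The geometric step-size parameter p starts at 0.7 (stutter is mostly
    ±1 nt) and is relaxed only when the requested spread is too large to
    reach with a mixing weight a <= 0.95.
    """
    if stutter_sd < 0:
        raise ValueError("stutter_sd must be non-negative")
    if stutter_sd == 0:
        return StutterModel(0.0, 1.0, np.array([0]), np.array([1.0]))
    w_del = DELETION_ODDS / (DELETION_ODDS + 1.0)
    skew = 2.0 * w_del - 1.0  # E[J] = -a * skew / p
    p = 0.7
    a = None
    for _ in range(200):
        eg = 1.0 / p
        eg2 = (2.0 - p) / p**2
        # Var = a*EG2 - (a*skew*EG)^2  ->  (skew*EG)^2 a^2 - EG2 a + sd^2 = 0
        qa = (skew * eg) ** 2
        disc = eg2**2 - 4.0 * qa * stutter_sd**2
        if disc >= 0:
            a_candidate = (eg2 - math.sqrt(disc)) / (2.0 * qa)
            if 0 < a_candidate <= 0.95:
                a = a_candidate
                break
        p *= 0.9
    if a is None:
        raise ValueError(f"cannot calibrate stutter model for sd={stutter_sd}")
    j_max = 1
    while a * (1 - p) ** (j_max - 1) * p > tail_tol:
        j_max += 1
    offsets = np.arange(-j_max, j_max + 1)
    probs = np.zeros(offsets.size)
    for idx, j in enumerate(offsets.tolist()):
        if j == 0:
            probs[idx] = 1.0 - a
        else:
            geom = (1 - p) ** (abs(j) - 1) * p
            probs[idx] = a * (w_del if j < 0 else 1.0 - w_del) * geom
    probs = probs / probs.sum()
    return StutterModel(a, p, offsets, probs)


def sample_read_length(
    allele_length: int, stutter_sd: float, rng: np.random.Generator, size: int = 1
) -> np.ndarray:
    """Observed run length(s) for reads of one allele: allele length plus a
    slippage offset, clipped at zero."""
    model = stutter_model(stutter_sd)
    offsets = rng.choice(model.offsets, size=size, p=model.probs)
    return np.maximum(allele_length + offsets, 0)


@dataclass(frozen=True)
class SimulatedLocusSpec:
    """Simulation recipe for one locus in one sample."""

    locus: MicrosatelliteLocus
    stable_length: int
    alleles: tuple[tuple[int, float], ...]  # (length nt, fraction)
    depth: int
    stutter_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("depth must be non-negative")
        if self.stutter_sd < 0:
            raise ValueError("stutter_sd must be non-negative")
        total = sum(f for _l, f in self.alleles)
        if self.alleles and abs(total - 1.0) > 1e-9:
            raise ValueError(f"allele fractions sum to {total}, expected 1")

    @classmethod
    def with_unstable(
        cls,
        locus: MicrosatelliteLocus,
        stable_length: int,
        unstable_fraction: float = 0.0,
        unstable_shift: int = -6,
        depth: int = 2000,
        stutter_sd: float = 1.0,
        seed: int = 0,
    ) -> "SimulatedLocusSpec":
        """Stable allele plus (optionally) one shifted unstable allele."""
        if not 0 <= unstable_fraction <= 1:
            raise ValueError("unstable_fraction must be in [0, 1]")
        alleles: tuple[tuple[int, float], ...]
        if unstable_fraction == 0:
            alleles = ((stable_length, 1.0),)
        elif unstable_fraction == 1:
            alleles = ((stable_length + unstable_shift, 1.0),)
        else:
            alleles = (
                (stable_length, 1.0 - unstable_fraction),
                (stable_length + unstable_shift, unstable_fraction),
            )
        return cls(
            locus=locus,
            stable_length=stable_length,
            alleles=alleles,
            depth=depth,
            stutter_sd=stutter_sd,
            seed=seed,
        )


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_context(rng: np.random.Generator, length: int) -> str:
    if length <= 0:
        return ""
    return rng.choice(_BASES, size=length).tobytes().decode()


def _random_flank(rng: np.random.Generator, repeat_base: str, length: int = 20) -> str:
    """Random flank free of 4+ runs of the repeat base; its inner edge
    (first/last base handled by the caller) avoids extending the repeat."""
    forbidden = repeat_base * 4
    while True:
        flank = _random_context(rng, length)
        if forbidden not in flank:
            return flank


def synthetic_panel(
    seed: int = 0, repeat_base: str = "A", flank_length: int = 20
) -> tuple[list[MicrosatelliteLocus], dict[str, int]]:
    """A five-locus poly-A panel shaped like the Bethesda panel (BAT-25,
    BAT-26, NR-21, NR-24, NR-27 run lengths) with synthetic random flanks.

    Flank bases adjacent to the repeat are forced to differ from the repeat
    base so the inter-flank span is unambiguous, mimicking primer design.
    Flanks are fixed by ``seed``.
    """
    rng = np.random.default_rng(seed)
    others = [b for b in "ACGT" if b != repeat_base]
    loci = []
    for name, stable in _BETHESDA_STABLE_LENGTHS.items():
        flank5 = _random_flank(rng, repeat_base, flank_length)
        flank3 = _random_flank(rng, repeat_base, flank_length)
        if flank5[-1] == repeat_base:
            flank5 = flank5[:-1] + str(rng.choice(others))
        if flank3[0] == repeat_base:
            flank3 = str(rng.choice(others)) + flank3[1:]
        loci.append(
            MicrosatelliteLocus(
                name=name, repeat_base=repeat_base, flank5=flank5, flank3=flank3
            )
        )
    return loci, dict(_BETHESDA_STABLE_LENGTHS)


def simulate_read_pairs(
    spec: SimulatedLocusSpec, rng: Optional[np.random.Generator] = None
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Generate ``depth`` read pairs and the per-read truth table.

    Both mates of a pair read the same simulated fragment, so they carry
    the same sampled repeat length (and are later counted as two
    observations, as in real amplicon data).  Fully reproducible from
    ``spec.seed`` when ``rng`` is not supplied.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    locus = spec.locus
    pairs: list[tuple[str, str]] = []
    records = []
    if spec.depth == 0 or not spec.alleles:
        return pairs, pd.DataFrame(
            columns=["read_id", "locus", "allele_index", "allele_length", "sampled_length"]
        )
    allele_lengths = np.array([l for l, _f in spec.alleles])
    fractions = np.array([f for _l, f in spec.alleles])
    choices = rng.choice(allele_lengths.size, size=spec.depth, p=fractions)
    model = stutter_model(spec.stutter_sd)
    offsets = rng.choice(model.offsets, size=spec.depth, p=model.probs)
    sampled = np.maximum(allele_lengths[choices] + offsets, 0)
    for i in range(spec.depth):
        run_length = int(sampled[i])
        insert = locus.flank5 + locus.repeat_base * run_length + locus.flank3
        pad_total = max(READ_LENGTH - len(insert), 0)
        pad_left = int(rng.integers(0, pad_total + 1)) if pad_total else 0
        fragment = (
            _random_context(rng, pad_left)
            + insert
            + _random_context(rng, pad_total - pad_left)
        )
        pairs.append((fragment, reverse_complement(fragment)))
        records.append(
            {
                "read_id": f"{locus.name}:{i}",
                "locus": locus.name,
                "allele_index": int(choices[i]),
                "allele_length": int(allele_lengths[choices[i]]),
                "sampled_length": run_length,
            }
        )
    return pairs, pd.DataFrame.from_records(records)


def write_fastq_pairs(
    pairs: Sequence[tuple[str, str]],
    r1_path: str | Path,
    r2_path: str | Path,
    name_prefix: str = "sim",
) -> None:
    """Write read pairs as two FASTQ files (gzip if the path ends in .gz),
    with constant qualities (the caller ignores base qualities anyway).
    Gzip members carry a zeroed mtime so identical simulations produce
    byte-identical files."""

    def _open(path: str | Path):
        if str(path).endswith(".gz"):
            raw = open(path, "wb")
            # empty filename + zero mtime keep the gzip header reproducible
            return io.TextIOWrapper(
                gzip.GzipFile(filename="", mode="wb", fileobj=raw, mtime=0),
                encoding="ascii",
            )
        return open(path, "wt")

    for path, mate in ((r1_path, 0), (r2_path, 1)):
        with _open(path) as handle:
            for i, pair in enumerate(pairs):
                seq = pair[mate]
                handle.write(f"@{name_prefix}:{i}/{mate + 1}\n{seq}\n+\n{'I' * len(seq)}\n")


def simulate_fastq(
    spec: SimulatedLocusSpec,
    r1_path: str | Path,
    r2_path: str | Path,
    truth_path: Optional[str | Path] = None,
) -> pd.DataFrame:
    """Simulate one locus to paired FASTQ files; returns the truth table."""
    pairs, truth = simulate_read_pairs(spec)
    write_fastq_pairs(pairs, r1_path, r2_path, name_prefix=spec.locus.name)
    if truth_path is not None:
        truth.to_csv(truth_path, sep="\t", index=False)
    return truth


def simulate_sample(
    specs: Sequence[SimulatedLocusSpec],
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[str], pd.DataFrame]:
    """Simulate several loci into one pooled mate stream (R1+R2 merged),
    as fed to extraction; returns (mates, concatenated truth)."""
    mates: list[str] = []
    truths = []
    for spec in specs:
        pairs, truth = simulate_read_pairs(spec, rng=rng)
        for r1, r2 in pairs:
            mates.append(r1)
            mates.append(r2)
        truths.append(truth)
    truth = (
        pd.concat(truths, ignore_index=True)
        if truths
        else pd.DataFrame(
            columns=["read_id", "locus", "allele_index", "allele_length", "sampled_length"]
        )
    )
    return mates, truth


@dataclass(frozen=True)
class DilutionSample:
    """One point of an in-silico dilution series."""

    dilution: float
    specs: tuple[SimulatedLocusSpec, ...]
    expected_fractions: Mapping[str, float] = field(default_factory=dict)


def simulate_dilution_series(
    loci: Sequence[MicrosatelliteLocus],
    stable_lengths: Mapping[str, int],
    positive_fractions: Mapping[str, float] = DEFAULT_POSITIVE_FRACTIONS,
    dilutions: Sequence[float] = DEFAULT_DILUTIONS,
    depth: int = 2000,
    stutter_sd: float = 1.0,
    unstable_shift: int = -6,
    seed: int = 0,
) -> list[DilutionSample]:
    """Dilute an MSI-positive control into an MSS background in silico.

    Sample at dilution d carries an unstable fraction of
    ``positive_fraction * d`` at every locus, mirroring DNA mixing
    experiments used to establish limits of detection.
    """
    samples = []
    for d_index, dilution in enumerate(dilutions):
        specs = []
        expected = {}
        for l_index, locus in enumerate(loci):
            fraction = positive_fractions[locus.name] * dilution
            expected[locus.name] = fraction
            specs.append(
                SimulatedLocusSpec.with_unstable(
                    locus=locus,
                    stable_length=stable_lengths[locus.name],
                    unstable_fraction=fraction,
                    unstable_shift=unstable_shift,
                    depth=depth,
                    stutter_sd=stutter_sd,
                    seed=seed + 1000 * d_index + l_index,
                )
            )
        samples.append(
            DilutionSample(
                dilution=dilution, specs=tuple(specs), expected_fractions=expected
            )
        )
    return samples
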