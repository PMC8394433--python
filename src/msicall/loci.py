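"""Panel definitions: microsatellite loci and their flanking-sequence anchors.

A locus is identified in a read purely by its two flanking sequences; the
repeat itself is never matched against a reference, which is what makes the
approach robust to heavily contracted or expanded alleles.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

_VALID_BASES = set("ACGTN")
_REPEAT_BASES = set("ACGT")


class PanelError(ValueError):
    """Raised for malformed locus definitions."""


@dataclass(frozen=True)
class AlignmentScoring:
    """Smith-Waterman scoring for flank anchoring.

    Penalties are stored as non-negative magnitudes.  A flank anchor is
    accepted when its local-alignment score reaches
    ``min_score_fraction * match * len(flank)`` (the perfect-match score).
    """

    match: int = 1
    mismatch: int = 1
    gap_open: int = 2
    gap_extend: int = 1
    min_score_fraction: float = 0.8

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise PanelError("match reward must be positive")
        if self.mismatch < 0 or self.gap_open < 0 or self.gap_extend < 0:
            raise PanelError("penalties must be non-negative")
        if not 0 < self.min_score_fraction <= 1:
            raise PanelError("min_score_fraction must be in (0, 1]")

    def perfect_score(self, flank: str) -> float:
        return self.match * len(flank)


@dataclass(frozen=True)
class HomopolymerRule:
    """Filter deciding whether a trimmed inter-flank sequence is a genuine
    homopolymer run rather than a chimeric or mispriming artefact.

    ``min_run`` is the shortest uninterrupted run of the repeat base that
    must be present; ``min_content`` is the minimum fraction of the trimmed
    sequence made up of the repeat base (tolerating isolated sequencing
    errors inside the repeat).
    """

    min_run: int = 8
    min_content: float = 0.8

    def passes(self, trimmed: str, repeat_base: str) -> bool:
        if not trimmed:
            return False
        n_base = trimmed.count(repeat_base)
        if n_base < self.min_content * len(trimmed):
            return False
        if n_base == len(trimmed):
            return len(trimmed) >= self.min_run
        longest = max(len(m) for m in re.findall(f"{repeat_base}+", trimmed) or [""])
        return longest >= self.min_run


@dataclass(frozen=True)
class MicrosatelliteLocus:
    """One mononucleotide microsatellite and the anchors used to find it.

    ``flank5`` and ``flank3`` are given on the same strand, in the order
    flank5 -> repeat -> flank3.  ``min_flank_identity``, when set, overrides
    the acceptance threshold in ``sw_scoring``.
    """

    name: str
    repeat_base: str
    flank5: str
    flank3: str
    sw_scoring: AlignmentScoring = field(default_factory=AlignmentScoring)
    min_flank_identity: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.name:
            raise PanelError("locus name must be non-empty")
        if self.repeat_base not in _REPEAT_BASES:
            raise PanelError(f"repeat_base must be one of ACGT, got {self.repeat_base!r}")
        for label, flank in (("flank5", self.flank5), ("flank3", self.flank3)):
            if len(flank) < 10:
                raise PanelError(f"{label} of {self.name} must be at least 10 nt")
            if not set(flank) <= _VALID_BASES:
                raise PanelError(f"{label} of {self.name} contains non-ACGTN characters")
            if set(flank) == {self.repeat_base}:
                raise PanelError(
                    f"{label} of {self.name} is a pure run of the repeat base"
                )
        if self.min_flank_identity is not None and not 0 < self.min_flank_identity <= 1:
            raise PanelError("min_flank_identity must be in (0, 1]")

    @property
    def accept_fraction(self) -> float:
        """Effective fraction of the perfect score required to accept an anchor."""
        if self.min_flank_identity is not None:
            return self.min_flank_identity
        return self.sw_scoring.min_score_fraction


def read_panel(path: str | Path) -> list[MicrosatelliteLocus]:
    """Read a locus-definition table (TSV).

    Required columns: ``name``, ``repeat_base``, ``flank5``, ``flank3``.
    Optional scoring overrides: ``match``, ``mismatch``, ``gap_open``,
    ``gap_extend``, ``min_score_fraction``.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"name", "repeat_base", "flank5", "flank3"}
    missing = required - set(df.columns)
    if missing:
        raise PanelError(f"panel file {path} lacks columns: {sorted(missing)}")
    loci = []
    for _, row in df.iterrows():
        kwargs = {}
        for key in ("match", "mismatch", "gap_open", "gap_extend"):
            if key in df.columns and pd.notna(row.get(key)):
                kwargs[key] = int(row[key])
        if "min_score_fraction" in df.columns and pd.notna(row.get("min_score_fraction")):
            kwargs["min_score_fraction"] = float(row["min_score_fraction"])
        scoring = AlignmentScoring(**kwargs) if kwargs else AlignmentScoring()
        loci.append(
            MicrosatelliteLocus(
                name=str(row["name"]),
                repeat_base=str(row["repeat_base"]).upper(),
                flank5=str(row["flank5"]).upper(),
                flank3=str(row["flank3"]).upper(),
                sw_scoring=scoring,
            )
        )
    names = [l.name for l in loci]
    if len(set(names)) != len(names):
        raise PanelError("duplicate locus names in panel")
    return loci


def write_panel(loci: list[MicrosatelliteLocus], path: str | Path) -> None:
    rows = [
        {
            "name": l.name,
            "repeat_base": l.repeat_base,
            "flank5": l.flank5,
            "flank3": l.flank3,
            "match": l.sw_scoring.match,
            "mismatch": l.sw_scoring.mismatch,
            "gap_open": l.sw_scoring.gap_open,
            "gap_extend": l.sw_scoring.gap_extend,
            "min_score_fraction": l.sw_scoring.min_score_fraction,
        }
        for l in loci
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
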