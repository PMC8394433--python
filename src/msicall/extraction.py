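"""Recover microsatellite length distributions from unaligned reads.

Each read (and its reverse complement) is searched for the 5' and 3'
flanking sequences of every locus in the panel.  When both flanks anchor
with a sufficient local-alignment score, the inter-flank sequence is
trimmed out; if it looks like a homopolymer run of the locus' repeat base,
its full length is recorded.  No mapping, no base-quality filtering: the
length distribution is built straight from FASTQ, mirroring how fragment
sizing works in capillary electrophoresis.

Anchoring uses exact substring search first and falls back to
Smith-Waterman local alignment (Biopython's ``PairwiseAligner``) guarded by
a short seed-match prefilter, so the common error-free case costs a string
search rather than a dynamic-programming fill.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from types import MappingProxyType
from typing import Iterable, Iterator, Mapping, NamedTuple, Optional, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .loci import AlignmentScoring, HomopolymerRule, MicrosatelliteLocus

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DEFAULT_HOMOPOLYMER_RULE = HomopolymerRule()


class FastqFormatError(ValueError):
    """A FASTQ record could not be parsed; the message names the record index."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@lru_cache(maxsize=32)
def _aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    # N scores as a mismatch against everything, including N itself.
    matrix = substitution_matrices.Array(alphabet="ACGTN", dims=2)
    for x in "ACGTN":
        for y in "ACGTN":
            matrix[x, y] = scoring.match if (x == y and x != "N") else -scoring.mismatch
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -scoring.gap_open
    aligner.extend_gap_score = -scoring.gap_extend
    return aligner


@lru_cache(maxsize=256)
def _seeds(flank: str) -> tuple[str, ...]:
    """Three non-overlapping substrings of the flank.

    With the default acceptance threshold an accepted anchor carries at most
    two edits, so at least one of three seeds survives intact (pigeonhole)
    and the prefilter loses nothing; for much looser thresholds it is a
    heuristic.
    """
    n = len(flank)
    third = n // 3
    if third < 4:
        return (flank[: n // 2], flank[n // 2 :])
    return (flank[:third], flank[third : 2 * third], flank[2 * third :])


class FlankHit(NamedTuple):
    """Accepted anchoring of both flanks on one orientation of a read.

    ``start``/``end`` delimit the inter-flank region (0-based, half-open)
    in the coordinates of the orientation given by ``strand`` ('+' for the
    read as sequenced, '-' for its reverse complement).
    """

    start: int
    end: int
    strand: str
    score: float


def _locate(
    seq: str, flank: str, scoring: AlignmentScoring, min_fraction: float, offset: int = 0
) -> Optional[tuple[int, int, float]]:
    """Find an accepted occurrence of ``flank`` in ``seq[offset:]``.

    Returns (start, end, score) in ``seq`` coordinates, or None.
    """
    perfect = scoring.perfect_score(flank)
    pos = seq.find(flank, offset)
    if pos >= 0:
        return pos, pos + len(flank), perfect
    region = seq[offset:]
    if len(region) < len(flank) * min_fraction:
        return None
    if not any(s in region for s in _seeds(flank)):
        return None
    alignments = _aligner(scoring).align(region, flank)
    try:
        best = alignments[0]
    except IndexError:
        return None
    if best.score < min_fraction * perfect:
        return None
    blocks = best.aligned[0]
    return offset + int(blocks[0][0]), offset + int(blocks[-1][1]), float(best.score)


def _anchor_one_strand(
    seq: str, locus: MicrosatelliteLocus
) -> Optional[tuple[int, int, float]]:
    hit5 = _locate(seq, locus.flank5, locus.sw_scoring, locus.accept_fraction)
    if hit5 is None:
        return None
    # flank3 must begin strictly after the accepted flank5 alignment ends
    hit3 = _locate(seq, locus.flank3, locus.sw_scoring, locus.accept_fraction, offset=hit5[1])
    if hit3 is None:
        return None
    return hit5[1], hit3[0], hit5[2] + hit3[2]


def find_flanks(read_sequence: str, locus: MicrosatelliteLocus) -> Optional[FlankHit]:
    """Anchor both flanks of ``locus`` on a read or its reverse complement.

    Returns the inter-flank span on the orientation where both flanks were
    accepted (the higher combined score wins when both orientations
    anchor), or None when either flank fails on both orientations.
    Absence of anchors is a normal outcome, not an error.
    """
    if not read_sequence:
        raise ValueError("read_sequence must be non-empty")
    seq = read_sequence.upper()
    fwd = _anchor_one_strand(seq, locus)
    rev = _anchor_one_strand(reverse_complement(seq), locus)
    if fwd is None and rev is None:
        return None
    if rev is None or (fwd is not None and fwd[2] >= rev[2]):
        return FlankHit(fwd[0], fwd[1], "+", fwd[2])
    return FlankHit(rev[0], rev[1], "-", rev[2])


def extract_length(
    read_sequence: str,
    locus: MicrosatelliteLocus,
    homopolymer_rule: HomopolymerRule = DEFAULT_HOMOPOLYMER_RULE,
) -> Optional[int]:
    """Microsatellite length carried by one read, or None.

    The length is the full inter-flank span (sequencing errors inside the
    repeat do not shorten it, just as internal sequence does not change an
    amplicon's electrophoretic size).  The trimmed sequence must pass the
    homopolymer rule; a read whose inter-flank region is not a repeat run
    is excluded.
    """
    if not read_sequence:
        return None
    hit = find_flanks(read_sequence, locus)
    if hit is None:
        return None
    seq = read_sequence.upper()
    oriented = seq if hit.strand == "+" else reverse_complement(seq)
    trimmed = oriented[hit.start : hit.end]
    if not homopolymer_rule.passes(trimmed, locus.repeat_base):
        return None
    return hit.end - hit.start


@dataclass(frozen=True)
class LengthHistogram:
    """Observed counts of trimmed microsatellite lengths for one locus."""

    locus: str
    counts: Mapping[int, int]
    n_reads: int

    @classmethod
    def from_counts(cls, locus: str, counts: Mapping[int, int]) -> "LengthHistogram":
        clean = {int(k): int(v) for k, v in counts.items() if v > 0}
        if any(k < 0 for k in clean):
            raise ValueError("lengths must be non-negative")
        if any(v < 0 for v in clean.values()):
            raise ValueError("counts must be non-negative")
        return cls(locus=locus, counts=MappingProxyType(dict(sorted(clean.items()))), n_reads=sum(clean.values()))

    def to_series(self) -> pd.Series:
        return pd.Series(dict(self.counts), name=self.locus).sort_index()


def iter_fastq(*paths: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (title, sequence) from one or more FASTQ / FASTQ.gz files.

    Raises FastqFormatError naming the (0-based) record index of a
    malformed record.
    """
    for path in paths:
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "rt") as handle:
            records = FastqGeneralIterator(handle)
            index = 0
            while True:
                try:
                    title, seq, _qual = next(records)
                except StopIteration:
                    break
                except ValueError as exc:
                    raise FastqFormatError(
                        f"malformed FASTQ record {index} in {path}: {exc}"
                    ) from exc
                yield title, seq
                index += 1


def extract_histograms(
    reads: Iterable[str],
    loci: Sequence[MicrosatelliteLocus],
    homopolymer_rule: HomopolymerRule = DEFAULT_HOMOPOLYMER_RULE,
) -> dict[str, LengthHistogram]:
    """Scan every read against every locus; one histogram per locus.

    Each mate is treated as an independent observation.  The result does
    not depend on read order.
    """
    counters: dict[str, Counter] = {locus.name: Counter() for locus in loci}
    simple = [
        (
            locus,
            locus.flank5,
            locus.flank3,
            reverse_complement(locus.flank3),
            reverse_complement(locus.flank5),
            (_seeds(locus.flank5), _seeds(locus.flank3)),
            (
                _seeds(reverse_complement(locus.flank3)),
                _seeds(reverse_complement(locus.flank5)),
            ),
        )
        for locus in loci
    ]
    for read in reads:
        seq = read.upper()
        for locus, f5, f3, rc_f3, rc_f5, fwd_seeds, rev_seeds in simple:
            # fast path: both flanks exact on the forward strand
            p5 = seq.find(f5)
            if p5 >= 0:
                p3 = seq.find(f3, p5 + len(f5))
                if p3 >= 0:
                    trimmed = seq[p5 + len(f5) : p3]
                    if homopolymer_rule.passes(trimmed, locus.repeat_base):
                        counters[locus.name][len(trimmed)] += 1
                    continue
            else:
                # fast path on the reverse strand without materialising it:
                # rc(read) contains f5..f3 iff read contains rc(f3)..rc(f5)
                q3 = seq.find(rc_f3)
                if q3 >= 0:
                    q5 = seq.find(rc_f5, q3 + len(rc_f3))
                    if q5 >= 0:
                        trimmed = reverse_complement(seq[q3 + len(rc_f3) : q5])
                        if homopolymer_rule.passes(trimmed, locus.repeat_base):
                            counters[locus.name][len(trimmed)] += 1
                        continue
            # gate the alignment fallback on seed hits from both flanks in
            # the same orientation (same pigeonhole argument as in _locate)
            if (
                any(s in seq for s in fwd_seeds[0])
                and any(s in seq for s in fwd_seeds[1])
            ) or (
                any(s in seq for s in rev_seeds[0])
                and any(s in seq for s in rev_seeds[1])
            ):
                length = extract_length(seq, locus, homopolymer_rule)
                if length is not None:
                    counters[locus.name][length] += 1
    return {
        name: LengthHistogram.from_counts(name, counter)
        for name, counter in counters.items()
    }


def build_histogram(
    reads: Iterable[str],
    locus: MicrosatelliteLocus,
    homopolymer_rule: HomopolymerRule = DEFAULT_HOMOPOLYMER_RULE,
) -> LengthHistogram:
    """Histogram of microsatellite lengths for a single locus."""
    return extract_histograms(reads, [locus], homopolymer_rule)[locus.name]


def histograms_from_fastq(
    fastq_paths: Sequence[str | Path],
    loci: Sequence[MicrosatelliteLocus],
    homopolymer_rule: HomopolymerRule = DEFAULT_HOMOPOLYMER_RULE,
) -> dict[str, LengthHistogram]:
    """Build per-locus histograms from FASTQ files (paired or interleaved).

    Mates are counted independently, so R1/R2 files are simply
    concatenated streams.
    """
    reads = (seq for _title, seq in iter_fastq(*fastq_paths))
    return extract_histograms(reads, loci, homopolymer_rule)


def histograms_to_tsv(histograms: Mapping[str, LengthHistogram], path: str | Path) -> None:
    rows = [
        {"locus": h.locus, "length": length, "count": count}
        for h in histograms.values()
        for length, count in h.counts.items()
    ]
    pd.DataFrame(rows, columns=["locus", "length", "count"]).to_csv(
        path, sep="\t", index=False
    )


def histograms_from_tsv(path: str | Path) -> dict[str, LengthHistogram]:
    df = pd.read_csv(path, sep="\t")
    out = {}
    for locus, group in df.groupby("locus"):
        out[str(locus)] = LengthHistogram.from_counts(
            str(locus), dict(zip(group["length"].astype(int), group["count"].astype(int)))
        )
    return out
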