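"""Ping-pong amplification signatures from 5'-5' overlaps of piRNA pairs.

The ping-pong cycle leaves sense/antisense piRNA pairs whose 5' ends overlap
by exactly 10 nt.  For each TE family we histogram the 5'-5' overlap of every
physically overlapping sense x antisense read pair on the consensus, compute
a z-score of the count at overlap 10 against the other offsets, and report
the pairs-per-piRNA metric used for heatmaps.

Geometry: a plus-strand read's 5' end is its lowest consensus coordinate s;
a minus-strand read's 5' end is its highest coordinate m; the overlap is
k = m - s + 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .smallrna import ConsensusAlignment

__all__ = [
    "OverlapSignature",
    "overlap_distribution",
    "zscore_signature",
    "pairs_per_pirna",
    "family_signature",
]

DEFAULT_K = 20
Z_THRESHOLD = 1.96


@dataclass(frozen=True)
class OverlapSignature:
    """Per-family overlap histogram and the z-score signature at overlap 10."""

    family_id: str
    overlap_counts: tuple[int, ...]  # index 0 == overlap 1
    z10: float  # nan when undefined
    significant: bool
    ppr: float  # pairs at overlap 10 per assigned piRNA; nan when undefined
    n_pirnas: int


def overlap_distribution(
    alignments: list[ConsensusAlignment],
    k_max: int = DEFAULT_K,
    collapse: bool = False,
) -> np.ndarray:
    """Histogram of 5'-5' overlaps over all sense x antisense pairs.

    Counts, for each overlap length k in 1..k_max, the number of (plus-strand
    read, minus-strand read) pairs whose 5' ends overlap by exactly k nt and
    that physically overlap on the consensus.  Pairs are all combinations,
    not capped per read; with ``collapse`` reads are first reduced to unique
    (5' position, length, strand) species counted once.
    """
    fams = {a.family_id for a in alignments}
    if len(fams) > 1:
        raise ValueError(f"alignments span multiple families: {sorted(fams)}")
    plus = [(a.five_prime, a.length) for a in alignments if a.strand == "+"]
    minus = [(a.five_prime, a.length) for a in alignments if a.strand == "-"]
    if collapse:
        plus = sorted(set(plus))
        minus = sorted(set(minus))
    counts = np.zeros(k_max, dtype=np.int64)
    if not plus or not minus:
        return counts
    s = np.array([p for p, _ in plus])
    lp = np.array([l for _, l in plus])
    for m, lm in minus:
        k = m - s + 1
        ok = (k >= 1) & (k <= k_max) & (k <= lp + lm - 1) & (m - lm + 1 <= s + lp - 1)
        if ok.any():
            counts += np.bincount(k[ok] - 1, minlength=k_max)
    return counts


def zscore_signature(overlap_counts: np.ndarray) -> tuple[float, bool]:
    """z-score of the overlap-10 count against the other offsets.

    Background is the counts at offsets 1..K excluding 10; the z-score uses
    the population standard deviation.  When the background SD is zero the
    signature is +inf (significant) if the count at 10 exceeds the background
    mean, and undefined (nan, not significant) otherwise.  Significance is
    z > 1.96 (one-sided P < 0.025).
    """
    counts = np.asarray(overlap_counts, dtype=float)
    if counts.size < 11:
        raise ValueError("overlap_counts must cover offsets at least up to 10")
    c10 = counts[9]
    background = np.delete(counts, 9)
    mean = background.mean()
    sd = background.std()  # population SD
    if sd == 0.0:
        if c10 > mean:
            return math.inf, True
        return math.nan, False
    z = (c10 - mean) / sd
    return float(z), bool(z > Z_THRESHOLD)


def pairs_per_pirna(pairs_at_10: int, n_family_pirnas: int) -> float:
    """Overlap-10 pair count normalized by the family's piRNA count (nan when n = 0)."""
    if n_family_pirnas < 0:
        raise ValueError("n_family_pirnas must be >= 0")
    if n_family_pirnas == 0:
        return math.nan
    return pairs_at_10 / n_family_pirnas


def family_signature(
    family_id: str,
    alignments: list[ConsensusAlignment],
    k_max: int = DEFAULT_K,
    collapse: bool = False,
) -> OverlapSignature:
    """Full per-family signature: histogram, z10, significance, pairs-per-piRNA."""
    counts = overlap_distribution(alignments, k_max=k_max, collapse=collapse)
    z10, significant = zscore_signature(counts)
    n = len({a.read_id for a in alignments})
    return OverlapSignature(
        family_id=family_id,
        overlap_counts=tuple(int(c) for c in counts),
        z10=z10,
        significant=significant,
        ppr=pairs_per_pirna(int(counts[9]), n),
        n_pirnas=n,
    )
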