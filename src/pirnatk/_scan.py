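"""Naive end-to-end read matcher (ungapped, full read length, both strands).

Uses the pigeonhole principle: a full-length placement with at most m
mismatches must contain at least one of m+1 read segments matching exactly,
so candidate offsets come from exact substring search and are then verified
position by position.  Candidate generation uses either C-speed ``str.find``
or, for repeated scans of the same references, a prebuilt k-mer position
index.  Complete for substitution-only data, which is all the synthetic
generator emits.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import revcomp

__all__ = ["Placement", "find_placements", "scan_references", "ReferenceIndex"]


@dataclass(frozen=True)
class Placement:
    """One end-to-end placement of a read on a reference.

    ``offset`` is the 0-based position of the read's leftmost base on the
    forward reference; a minus-strand placement means the reverse complement
    of the read matches there.
    """

    ref_id: str
    offset: int
    strand: str
    mismatches: int


def _exact_occurrences(text: str, pattern: str) -> list[int]:
    out = []
    i = text.find(pattern)
    while i != -1:
        out.append(i)
        i = text.find(pattern, i + 1)
    return out


def _hamming_le(text: str, pattern: str, offset: int, max_mm: int) -> int:
    """Mismatch count of pattern vs text[offset:], or -1 if it exceeds max_mm."""
    mm = 0
    for i, c in enumerate(pattern):
        if text[offset + i] != c:
            mm += 1
            if mm > max_mm:
                return -1
    return mm


def _part_bounds(m: int, k: int) -> list[int]:
    return [round(j * m / k) for j in range(k + 1)]


class ReferenceIndex:
    """K-mer position index over one reference's forward strand.

    Maps every k-mer to its (sorted) start positions, letting repeated scans
    skip the linear text search.  Any pigeonhole segment at least k long is
    located through the positions of its k-prefix (a superset of the exact
    occurrences of the whole segment, later verified base by base).
    """

    def __init__(self, sequence: str, k: int = 11):
        self.sequence = sequence
        self.k = k
        index: dict[str, list[int]] = {}
        for i in range(len(sequence) - k + 1):
            index.setdefault(sequence[i : i + k], []).append(i)
        self._index = index

    def occurrences_of_prefix(self, part: str) -> list[int]:
        """Positions where ``part`` (length >= k) could start, via its k-prefix."""
        return self._index.get(part[: self.k], ())


def find_placements(
    text: str, pattern: str, max_mm: int, index: ReferenceIndex | None = None
) -> list[tuple[int, int]]:
    """All (offset, mismatches) of full-length placements with <= max_mm mismatches."""
    n, m = len(text), len(pattern)
    if m > n:
        return []
    if max_mm == 0 and index is None:
        return [(i, 0) for i in _exact_occurrences(text, pattern)]
    bounds = _part_bounds(m, max_mm + 1)
    candidates: set[int] = set()
    for j in range(max_mm + 1):
        part = pattern[bounds[j] : bounds[j + 1]]
        if not part:
            continue
        if index is not None and len(part) >= index.k:
            occs = index.occurrences_of_prefix(part)
        else:
            occs = _exact_occurrences(text, part)
        for occ in occs:
            start = occ - bounds[j]
            if 0 <= start <= n - m:
                candidates.add(start)
    out = []
    for start in sorted(candidates):
        mm = _hamming_le(text, pattern, start, max_mm)
        if mm >= 0:
            out.append((start, mm))
    return out


def scan_references(
    references: dict[str, str],
    read_seq: str,
    max_mm: int,
    indexes: dict[str, ReferenceIndex] | None = None,
) -> list[Placement]:
    """Scan both strands of every reference; return best-stratum placements.

    The best stratum is the set of placements achieving the minimum mismatch
    count over all references and strands; placements worse than ``max_mm``
    are never reported.  ``indexes`` (per reference id) accelerates repeated
    scans; both strands share one forward index because the minus strand is
    searched as the reverse complement of the read.
    """
    hits: list[Placement] = []
    rc = revcomp(read_seq)
    for ref_id, ref_seq in references.items():
        idx = indexes.get(ref_id) if indexes else None
        for strand, seq in (("+", read_seq), ("-", rc)):
            for offset, mm in find_placements(ref_seq, seq, max_mm, index=idx):
                hits.append(Placement(ref_id, offset, strand, mm))
    if not hits:
        return []
    best = min(h.mismatches for h in hits)
    return [h for h in hits if h.mismatches == best]


def build_indexes(references: dict[str, str], k: int = 11) -> dict[str, ReferenceIndex]:
    return {ref_id: ReferenceIndex(seq, k=k) for ref_id, seq in references.items()}
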