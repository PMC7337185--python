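"""TE annotation from similarity-search hits, and per-family genomic summaries.

The annotation pipeline is: filter hits by percent identity, merge successive
same-family hits into insertions, resolve overlaps between families in favour
of the higher-identity family, then align each family's genomic copies back
to its consensus and compute nucleotide diversity (pi), median copy length,
and the full-length copy count (copies spanning at least 98% of the
consensus).

Coordinates: insertion spans are 0-based half-open throughout; the 1-based
tabular hit coordinates are converted on entry.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io_formats import SequenceRecord, TabularHit, get_logger, revcomp

__all__ = [
    "TEInsertion",
    "FamilySummary",
    "filter_hits",
    "merge_family_hits",
    "resolve_cross_family_overlaps",
    "align_copies_to_consensus",
    "nucleotide_diversity",
    "summarize_family",
    "annotate_genome",
]

_log = get_logger(__name__)

FULL_LENGTH_THRESHOLD = 0.98


@dataclass(frozen=True)
class TEInsertion:
    """A merged genomic TE annotation of one family.

    ``identity`` is the alignment-length-weighted mean identity of the merged
    hits; ``completeness`` is the genomic span length divided by the consensus
    length, and a copy is full-length when completeness >= 0.98.
    """

    family_id: str
    contig: str
    start: int  # 0-based
    end: int  # half-open
    strand: str
    identity: float
    n_merged_hits: int
    completeness: float
    full_length: bool

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class FamilySummary:
    """Per-family genomic traits: copy number, median length, full-length count, pi."""

    family_id: str
    copy_number: int
    median_length: float
    full_length_count: int
    pi: float
    consensus_length: int


def filter_hits(hits: Iterable[TabularHit], min_identity: float = 80.0) -> list[TabularHit]:
    """Drop hits below the identity threshold (hits at exactly the threshold are kept)."""
    return [h for h in hits if h.percent_identity >= min_identity]


def _make_insertion(
    family_id: str,
    contig: str,
    strand: str,
    start: int,
    end: int,
    identity: float,
    n_hits: int,
    consensus_length: int,
    full_length_threshold: float = FULL_LENGTH_THRESHOLD,
) -> TEInsertion:
    completeness = (end - start) / consensus_length
    return TEInsertion(
        family_id=family_id,
        contig=contig,
        start=start,
        end=end,
        strand=strand,
        identity=identity,
        n_merged_hits=n_hits,
        completeness=completeness,
        full_length=completeness >= full_length_threshold,
    )


def merge_family_hits(
    hits: Sequence[TabularHit],
    consensus_length: int,
    full_length_threshold: float = FULL_LENGTH_THRESHOLD,
) -> list[TEInsertion]:
    """Merge successive hits of one family on one contig and strand.

    Two hits are merged when their genomic spans overlap, or when the sum of
    their span lengths plus the gap between them is strictly smaller than the
    consensus length.  Merging runs to a fixpoint, always joining the first
    qualifying pair in sorted genomic order, so it is transitive left to
    right along the sorted list (and, when hits nest inside one another, a
    contained hit can also bridge to an earlier neighbour).  The merged
    insertion's span is the union hull and its identity the
    alignment-length-weighted mean of its hits.
    """
    if not hits:
        return []
    families = {h.query_id for h in hits}
    contigs = {h.subject_id for h in hits}
    strands = {h.strand for h in hits}
    if len(families) > 1 or len(contigs) > 1 or len(strands) > 1:
        raise ValueError("merge_family_hits requires hits of one family, contig, and strand")
    family = hits[0].query_id
    contig = hits[0].subject_id
    strand = hits[0].strand

    # work items: [start, end, identity*alen sum, alen sum, n hits]
    items = sorted(
        [h.span0[0], h.span0[1], h.percent_identity * h.alignment_length,
         h.alignment_length, 1]
        for h in hits
    )

    def _mergeable(a: list, b: list) -> bool:
        if a[0] < b[1] and b[0] < a[1]:
            return True
        gap = max(a[0], b[0]) - min(a[1], b[1])
        return (a[1] - a[0]) + (b[1] - b[0]) + gap < consensus_length

    merged_any = True
    while merged_any:
        merged_any = False
        items.sort()
        for i in range(len(items)):
            a = items[i]
            for j in range(i + 1, len(items)):
                b = items[j]
                if not _mergeable(a, b):
                    # spans are start-sorted: once b is too far right to merge
                    # with a by gap, only nested hits (handled by iterating j)
                    # can still qualify
                    continue
                items[i] = [min(a[0], b[0]), max(a[1], b[1]),
                            a[2] + b[2], a[3] + b[3], a[4] + b[4]]
                del items[j]
                merged_any = True
                break
            if merged_any:
                break

    return [
        _make_insertion(family, contig, strand, s, e, wsum / alen, n,
                        consensus_length, full_length_threshold)
        for s, e, wsum, alen, n in items
    ]


def _conflicts(a: TEInsertion, b: TEInsertion, reciprocal: float) -> bool:
    """True when two insertions of different families overlap 'fully'.

    Full overlap means containment of one span in the other, or a reciprocal
    overlap of at least ``reciprocal`` of the shorter span.  Partial overlaps
    with substantial family-specific flanks leave both insertions standing,
    treated as two independent insertions.
    """
    if a.contig != b.contig:
        return False
    ov = min(a.end, b.end) - max(a.start, b.start)
    if ov <= 0:
        return False
    if (a.start >= b.start and a.end <= b.end) or (b.start >= a.start and b.end <= a.end):
        return True
    return ov >= reciprocal * min(a.length, b.length)


def _loser(a: TEInsertion, b: TEInsertion) -> TEInsertion:
    """The insertion to discard: lower identity; ties go to the shorter span,
    then to the lexicographically larger family id."""
    if a.identity != b.identity:
        return a if a.identity < b.identity else b
    if a.length != b.length:
        return a if a.length < b.length else b
    return a if a.family_id > b.family_id else b


def resolve_cross_family_overlaps(
    insertions: Sequence[TEInsertion], reciprocal: float = 0.5
) -> list[TEInsertion]:
    """Resolve full overlaps between insertions of different families.

    When one insertion is contained in another (or they reciprocally overlap
    by >= ``reciprocal`` of the shorter), only the insertion with the highest
    identity to its consensus is kept.  Partially overlapping insertions with
    family-specific flanks are both retained.
    """
    alive = sorted(insertions, key=lambda i: (i.contig, i.start, i.end, i.family_id))
    changed = True
    while changed:
        changed = False
        for i in range(len(alive)):
            a = alive[i]
            for j in range(i + 1, len(alive)):
                b = alive[j]
                if b.contig != a.contig or b.start >= a.end:
                    break
                if a.family_id == b.family_id:
                    continue
                if _conflicts(a, b, reciprocal):
                    alive.remove(_loser(a, b))
                    changed = True
                    break
            if changed:
                break
    return alive


def align_copies_to_consensus(copies: Sequence[str], consensus: str) -> list[str]:
    """Place each copy on consensus coordinates by ungapped sliding alignment.

    Each copy is tried at every offset and kept at its best-scoring (minimum
    Hamming distance) placement, smallest offset winning ties; positions of
    the consensus outside the copy are gap-filled with '-'.  Adequate for
    substitution-only copies, which is what the simulator emits and what a
    merged genomic hull approximates.
    """
    cons = np.frombuffer(consensus.encode(), dtype=np.uint8)
    n = len(cons)
    rows: list[str] = []
    for copy in copies:
        m = len(copy)
        if m > n:
            raise ValueError(f"copy length {m} exceeds consensus length {n}")
        arr = np.frombuffer(copy.encode(), dtype=np.uint8)
        windows = np.lib.stride_tricks.sliding_window_view(cons, m)
        mism = (windows != arr).sum(axis=1)
        offset = int(np.argmin(mism))
        rows.append("-" * offset + copy + "-" * (n - offset - m))
    return rows


def nucleotide_diversity(
    aligned: Sequence[str], frequencies: Sequence[float] | None = None
) -> float:
    """Nucleotide diversity pi of a set of aligned copies.

    pi = 2 * sum_{i} sum_{j<i} x_i x_j pi_ij, where pi_ij is the per-site
    difference between copies i and j over columns where neither copy has a
    gap or N.  Frequencies default to 1/n.  A pair with no comparable columns
    contributes 0 with a logged warning.  Returns 0 for fewer than 2 copies.
    """
    n = len(aligned)
    if n < 2:
        return 0.0
    lengths = {len(s) for s in aligned}
    if len(lengths) != 1:
        raise ValueError("aligned copies must all have the same length")
    if frequencies is None:
        frequencies = [1.0 / n] * n
    elif len(frequencies) != n:
        raise ValueError("frequencies must match number of copies")

    mat = np.array([np.frombuffer(s.encode(), dtype=np.uint8) for s in aligned])
    valid = (mat != ord("-")) & (mat != ord("N"))
    total = 0.0
    n_empty = 0
    for i in range(n):
        for j in range(i):
            comp = valid[i] & valid[j]
            n_comp = int(comp.sum())
            if n_comp == 0:
                # disjoint fragments (e.g. a 5' and a 3' truncation); pi_ij = 0
                n_empty += 1
                pij = 0.0
            else:
                pij = int(((mat[i] != mat[j]) & comp).sum()) / n_comp
            total += frequencies[i] * frequencies[j] * pij
    if n_empty:
        _log.warning("%d copy pair(s) had no comparable columns; their pi_ij set to 0", n_empty)
    return 2.0 * total


def summarize_family(
    family_id: str,
    insertions: Sequence[TEInsertion],
    aligned_copies: Sequence[str],
    consensus_length: int,
) -> FamilySummary:
    """Per-family summary: copy number, median genomic length, full-length count, pi."""
    copy_number = len(insertions)
    median_length = float(statistics.median(i.length for i in insertions)) if insertions else 0.0
    full_length_count = sum(i.full_length for i in insertions)
    pi = nucleotide_diversity(aligned_copies) if copy_number >= 2 else 0.0
    return FamilySummary(
        family_id=family_id,
        copy_number=copy_number,
        median_length=median_length,
        full_length_count=full_length_count,
        pi=pi,
        consensus_length=consensus_length,
    )


def _extract_copy(genome: dict[str, str], ins: TEInsertion) -> str:
    seq = genome[ins.contig][ins.start : ins.end]
    return revcomp(seq) if ins.strand == "-" else seq


def annotate_genome(
    hits: Sequence[TabularHit],
    consensus_records: Sequence[SequenceRecord],
    genome_records: Sequence[SequenceRecord],
    min_identity: float = 80.0,
    full_length_threshold: float = FULL_LENGTH_THRESHOLD,
) -> tuple[list[TEInsertion], list[FamilySummary]]:
    """Full annotation pipeline from raw hits to insertions and family summaries."""
    cons = {r.id: r.sequence for r in consensus_records}
    genome = {r.id: r.sequence for r in genome_records}
    kept = filter_hits(hits, min_identity)

    groups: dict[tuple[str, str, str], list[TabularHit]] = {}
    for h in kept:
        if h.query_id not in cons:
            raise KeyError(f"hit family {h.query_id} absent from consensus library")
        groups.setdefault((h.query_id, h.subject_id, h.strand), []).append(h)

    merged: list[TEInsertion] = []
    for (family, _contig, _strand), ghits in sorted(groups.items()):
        merged.extend(
            merge_family_hits(ghits, len(cons[family]), full_length_threshold)
        )
    resolved = resolve_cross_family_overlaps(merged)
    resolved.sort(key=lambda i: (i.contig, i.start, i.end, i.family_id))

    summaries: list[FamilySummary] = []
    by_family: dict[str, list[TEInsertion]] = {}
    for ins in resolved:
        by_family.setdefault(ins.family_id, []).append(ins)
    for family in sorted(cons):
        fam_ins = by_family.get(family, [])
        if not fam_ins:
            continue
        copies = [_extract_copy(genome, i) for i in fam_ins]
        # hulls can exceed the consensus when merged hits straddle flanks;
        # clip to consensus length for the sliding alignment
        clen = len(cons[family])
        copies = [c[:clen] for c in copies]
        aligned = align_copies_to_consensus(copies, cons[family])
        summaries.append(summarize_family(family, fam_ins, aligned, clen))
    return resolved, summaries
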