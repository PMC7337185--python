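"""Genome-wide piRNA cluster screening and TE-density profiling.

piRNAs (23-30 nt) are mapped to the genome end-to-end with at most one
mismatch; only uniquely mapping reads (a single best-stratum placement
genome-wide) are retained.  Non-overlapping 1-kb windows with more than five
unique piRNAs per kb are called cluster windows, classified by the tissues
whose own counts pass the same density rule, and profiled for TE content by
averaging per-position TE presence/absence across windows, stratified by the
TE families' sex-bias class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._scan import build_indexes, scan_references
from .io_formats import SequenceRecord

__all__ = [
    "GenomeAlignment",
    "ClusterWindow",
    "map_unique_genome",
    "screen_windows",
    "classify_tissue",
    "te_density_profile",
]

DEFAULT_WINDOW = 1000
DEFAULT_MIN_DENSITY = 5.0


@dataclass(frozen=True)
class GenomeAlignment:
    """A unique end-to-end genomic placement of one piRNA read."""

    read_id: str
    contig: str
    offset: int
    strand: str
    mismatches: int
    length: int

    @property
    def five_prime(self) -> int:
        return self.offset if self.strand == "+" else self.offset + self.length - 1


@dataclass(frozen=True)
class ClusterWindow:
    """A 1-kb window passing the piRNA density screen."""

    contig: str
    start: int  # multiple of the window size, 0-based
    end: int
    counts: tuple[tuple[str, int], ...]  # per-tissue unique piRNA counts
    tissue_class: str  # ovary_only | testis_only | both
    low_confidence: bool  # passed only on pooled counts

    def count(self, tissue: str) -> int:
        return dict(self.counts).get(tissue, 0)


def map_unique_genome(
    reads: Iterable[SequenceRecord],
    genome_records: Sequence[SequenceRecord],
    max_mismatch: int = 1,
) -> list[GenomeAlignment]:
    """Map reads end-to-end to both strands of all contigs; keep unique reads.

    A read is unique iff its best mismatch stratum contains exactly one
    placement genome-wide; only those placements are returned.
    """
    refs = {r.id: r.sequence for r in genome_records}
    indexes = build_indexes(refs)
    out: list[GenomeAlignment] = []
    for read in reads:
        placements = scan_references(refs, read.sequence, max_mismatch, indexes=indexes)
        if len(placements) == 1:
            p = placements[0]
            out.append(
                GenomeAlignment(
                    read_id=read.id,
                    contig=p.ref_id,
                    offset=p.offset,
                    strand=p.strand,
                    mismatches=p.mismatches,
                    length=len(read.sequence),
                )
            )
    return out


def classify_tissue(
    counts: Mapping[str, int],
    threshold: float,
) -> tuple[str, bool]:
    """Tissue class of a screened window.

    A tissue is active when its own count strictly exceeds ``threshold``
    reads per window.  Active in ovary only -> ovary_only; testis only ->
    testis_only; both -> both.  A window passing the screen only on pooled
    counts (active in neither tissue individually) is reported as 'both' with
    a low-confidence flag.
    """
    active = {t for t, c in counts.items() if c > threshold}
    if active == {"ovary"}:
        return "ovary_only", False
    if active == {"testis"}:
        return "testis_only", False
    if len(active) >= 2:
        return "both", False
    return "both", True


def screen_windows(
    alignments_by_tissue: Mapping[str, Sequence[GenomeAlignment]],
    contig_lengths: Mapping[str, int],
    window: int = DEFAULT_WINDOW,
    min_density: float = DEFAULT_MIN_DENSITY,
) -> list[ClusterWindow]:
    """Screen non-overlapping tiling windows for piRNA clusters.

    A read belongs to the window containing its 5' end.  A window is a
    cluster window when the pooled (all-tissue) unique piRNA count strictly
    exceeds ``min_density * window / 1000``; tissue classification then
    applies the same rule per tissue.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    threshold = min_density * window / 1000.0
    tissues = sorted(alignments_by_tissue)
    counts: dict[tuple[str, int], dict[str, int]] = {}
    for tissue in tissues:
        for a in alignments_by_tissue[tissue]:
            w = a.five_prime // window
            key = (a.contig, w)
            counts.setdefault(key, {t: 0 for t in tissues})[tissue] += 1

    out: list[ClusterWindow] = []
    for (contig, w), per_tissue in sorted(counts.items()):
        pooled = sum(per_tissue.values())
        if pooled <= threshold:
            continue
        tissue_class, low_conf = classify_tissue(per_tissue, threshold)
        start = w * window
        out.append(
            ClusterWindow(
                contig=contig,
                start=start,
                end=min(start + window, contig_lengths.get(contig, start + window)),
                counts=tuple(sorted(per_tissue.items())),
                tissue_class=tissue_class,
                low_confidence=low_conf,
            )
        )
    return out


def te_density_profile(
    windows: Sequence[ClusterWindow],
    insertions: Sequence,
    family_classes: Mapping[str, str],
    window_size: int = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Mean per-position TE presence along cluster windows.

    For every window tissue class (plus 'all') and TE sex-bias class (plus
    'all'), profile[p] is the mean over windows of the indicator that
    position p of the window is covered by at least one insertion of a
    family in that class.  Returns a long table (window_class,
    te_expression_class, position, density).
    """
    te_classes = sorted(set(family_classes.values())) + ["all"]
    window_classes = sorted({w.tissue_class for w in windows}) + ["all"]

    by_contig: dict[str, list] = {}
    for ins in insertions:
        by_contig.setdefault(ins.contig, []).append(ins)

    # per-window binary coverage per TE class
    cover: dict[str, dict[str, list[np.ndarray]]] = {
        wc: {tc: [] for tc in te_classes} for wc in window_classes
    }
    for w in windows:
        vecs = {tc: np.zeros(window_size, dtype=bool) for tc in te_classes}
        for ins in by_contig.get(w.contig, []):
            lo = max(ins.start, w.start)
            hi = min(ins.end, w.start + window_size)
            if lo >= hi:
                continue
            tc = family_classes.get(ins.family_id)
            sl = slice(lo - w.start, hi - w.start)
            if tc is not None:
                vecs[tc][sl] = True
            vecs["all"][sl] = True
        for wc in (w.tissue_class, "all"):
            for tc in te_classes:
                cover[wc][tc].append(vecs[tc])

    rows = []
    for wc in window_classes:
        for tc in te_classes:
            stack = cover[wc][tc]
            profile = (
                np.mean(stack, axis=0) if stack else np.zeros(window_size)
            ).astype(float)
            for pos in range(window_size):
                rows.append(
                    {
                        "window_class": wc,
                        "te_expression_class": tc,
                        "position": pos,
                        "density": profile[pos],
                    }
                )
    return pd.DataFrame(rows)
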