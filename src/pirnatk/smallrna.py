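"""Small-RNA read classification, TE-family assignment, and miRNA normalization.

Reads are partitioned by size class (19-30 nt for TE-derived small RNAs,
23-30 nt for piRNAs), aligned end-to-end against the TE consensus library
with a mismatch allowance, and assigned to a family only when every
best-stratum placement falls on a single consensus; multi-family reads are
discarded.  Per-family counts are normalized by the library's total miRNA
count (per million miRNAs) and sex bias is called from the ovary/testis
fold change.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._scan import scan_references
from .io_formats import SequenceRecord, revcomp

__all__ = [
    "ConsensusAlignment",
    "FamilyPirnaLevel",
    "partition_by_size",
    "count_mirna",
    "align_to_consensus",
    "assign_unique_family",
    "family_counts",
    "normalize_and_classify",
]

NORMALIZATION_SCALE = 1_000_000  # counts per million miRNA reads


@dataclass(frozen=True)
class ConsensusAlignment:
    """End-to-end placement of one read on one TE consensus (0-based offset)."""

    read_id: str
    family_id: str
    offset: int
    strand: str
    mismatches: int
    length: int

    @property
    def five_prime(self) -> int:
        """Consensus coordinate of the read's biological 5' end."""
        return self.offset if self.strand == "+" else self.offset + self.length - 1


@dataclass(frozen=True)
class FamilyPirnaLevel:
    """Per-family piRNA level in one tissue pair, with the sex-bias call."""

    family_id: str
    ovary_raw: int
    testis_raw: int
    ovary_normalized: float
    testis_normalized: float
    fold_change: float  # ovary/testis ratio after pseudocount
    sex_bias_class: str  # ovary_biased | testis_biased | unbiased


def partition_by_size(
    reads: Iterable[SequenceRecord], lo: int, hi: int
) -> list[SequenceRecord]:
    """Keep reads with lo <= length <= hi (both bounds inclusive)."""
    if lo > hi:
        raise ValueError(f"lo ({lo}) must be <= hi ({hi})")
    return [r for r in reads if lo <= len(r.sequence) <= hi]


def count_mirna(reads: Iterable[SequenceRecord], mirna_set: Sequence[SequenceRecord]) -> int:
    """Count reads exactly matching a miRNA reference, full length, either orientation."""
    if not mirna_set:
        raise ValueError("miRNA reference set is empty")
    lookup = {m.sequence for m in mirna_set}
    lookup |= {revcomp(m.sequence) for m in mirna_set}
    return sum(1 for r in reads if r.sequence in lookup)


def align_to_consensus(
    reads: Iterable[SequenceRecord],
    consensus_records: Sequence[SequenceRecord],
    max_mismatch: int = 3,
) -> list[ConsensusAlignment]:
    """End-to-end scan of every consensus, both strands.

    For each read, all placements in its best stratum (minimum mismatch
    count across the whole library) are reported; placements with more than
    ``max_mismatch`` mismatches never are.
    """
    refs = {r.id: r.sequence for r in consensus_records}
    out: list[ConsensusAlignment] = []
    for read in reads:
        for p in scan_references(refs, read.sequence, max_mismatch):
            out.append(
                ConsensusAlignment(
                    read_id=read.id,
                    family_id=p.ref_id,
                    offset=p.offset,
                    strand=p.strand,
                    mismatches=p.mismatches,
                    length=len(read.sequence),
                )
            )
    return out


def assign_unique_family(
    alignments: Iterable[ConsensusAlignment],
) -> tuple[dict[str, str], set[str]]:
    """Assign each read to a family, or discard it as multi-family.

    A read whose best-stratum placements all fall on one consensus is
    assigned to that family (multiple positions on the same consensus are
    allowed); a read whose best stratum spans two or more families is
    discarded.  Returns (read_id -> family_id, discarded read ids).
    """
    per_read: dict[str, set[str]] = {}
    for a in alignments:
        per_read.setdefault(a.read_id, set()).add(a.family_id)
    assigned: dict[str, str] = {}
    discarded: set[str] = set()
    for read_id, fams in per_read.items():
        if len(fams) == 1:
            assigned[read_id] = next(iter(fams))
        else:
            discarded.add(read_id)
    return assigned, discarded


def family_counts(assigned: Mapping[str, str]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for fam in assigned.values():
        counts[fam] = counts.get(fam, 0) + 1
    return dict(sorted(counts.items()))


def normalize_and_classify(
    ovary_counts: Mapping[str, int],
    testis_counts: Mapping[str, int],
    ovary_mirna_total: int,
    testis_mirna_total: int,
    fold: float = 2.0,
) -> list[FamilyPirnaLevel]:
    """Normalize per-family piRNA counts by miRNA totals and call sex bias.

    normalized = raw / miRNA_total * 1e6.  The fold-change ratio adds a
    pseudocount of one raw read in each tissue before normalization, keeping
    the classification total and monotone; a family is ovary_biased when the
    ovary/testis ratio exceeds ``fold``, testis_biased when it is below
    1/``fold``, and unbiased otherwise.
    """
    if ovary_mirna_total <= 0 or testis_mirna_total <= 0:
        raise ValueError("miRNA normalization denominator must be positive")
    out: list[FamilyPirnaLevel] = []
    for family in sorted(set(ovary_counts) | set(testis_counts)):
        o_raw = int(ovary_counts.get(family, 0))
        t_raw = int(testis_counts.get(family, 0))
        o_norm = o_raw / ovary_mirna_total * NORMALIZATION_SCALE
        t_norm = t_raw / testis_mirna_total * NORMALIZATION_SCALE
        ratio = ((o_raw + 1) / ovary_mirna_total) / ((t_raw + 1) / testis_mirna_total)
        if ratio > fold:
            klass = "ovary_biased"
        elif ratio < 1.0 / fold:
            klass = "testis_biased"
        else:
            klass = "unbiased"
        out.append(
            FamilyPirnaLevel(
                family_id=family,
                ovary_raw=o_raw,
                testis_raw=t_raw,
                ovary_normalized=o_norm,
                testis_normalized=t_norm,
                fold_change=ratio,
                sex_bias_class=klass,
            )
        )
    return out


def levels_frame(levels: Sequence[FamilyPirnaLevel]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "family_id": l.family_id,
                "ovary_raw": l.ovary_raw,
                "testis_raw": l.testis_raw,
                "ovary_normalized": l.ovary_normalized,
                "testis_normalized": l.testis_normalized,
                "fold_change": l.fold_change,
                "sex_bias_class": l.sex_bias_class,
            }
            for l in levels
        ]
    )
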