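"""Synthetic genomes, TE landscapes, and gonadal small-RNA libraries.

Generates, from a single integer seed, everything the downstream stages
consume: a multi-contig genome with planted TE copies of controllable copy
number, age (per-site divergence) and truncation, planted piRNA-cluster
windows with tissue-specific activity, per-tissue small-RNA libraries
(miRNA-like reads plus 23-30 nt TE-derived reads with a controllable
fraction of ping-pong pairs), hit tables for the annotation stage, and
per-family mRNA count tables.  Every emitted read and insertion is traceable
to a ground-truth row.

The mutation model is substitution-only (uniform over the three alternative
bases, no indels), and truncated copies retain a contiguous consensus
interval anchored at one end — mimicking 5'-truncated non-LTR elements and
degraded copies without modelling mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import SequenceRecord, TabularHit, revcomp

__all__ = [
    "FamilySpec",
    "ClusterSpec",
    "LibrarySpec",
    "PlantedInsertion",
    "PlantedCluster",
    "GroundTruth",
    "mirna_reference",
    "MIRNA_CONTIG",
    "simulate_genome",
    "hits_from_truth",
    "simulate_smallrna",
    "simulate_counts",
    "simulate_trait_table",
    "default_scenario",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
MIRNA_CONTIG = "mir_scaffold"
_MIRNA_SEED = 906215  # fixed: the miRNA reference set is part of the study design


def _codes_to_seq(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of one simulated TE family.

    ``divergence`` is the per-site substitution probability applied to every
    planted copy (a proxy for family age); ``full_length_fraction`` the
    probability that a copy spans the whole consensus; truncated copies keep
    a uniformly drawn fraction in [min_truncated_fraction, 0.98) of the
    consensus, anchored at a uniformly chosen end.
    """

    family_id: str
    consensus_length: int
    te_class: str = "LTR"
    copy_number: int = 10
    divergence: float = 0.0
    full_length_fraction: float = 0.5
    min_truncated_fraction: float = 0.3

    def __post_init__(self) -> None:
        if self.te_class not in ("LTR", "non-LTR", "DNA"):
            raise ValueError(f"unknown te_class {self.te_class!r}")
        if not 0.0 <= self.divergence <= 0.2:
            raise ValueError("divergence must be in [0, 0.2]")
        for name in ("full_length_fraction", "min_truncated_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.copy_number < 0:
            raise ValueError("copy_number must be >= 0")


@dataclass(frozen=True)
class ClusterSpec:
    """A piRNA cluster window to reserve in the genome; ``tissue`` is its
    activity pattern: 'ovary', 'testis', or 'both'."""

    tissue: str

    def __post_init__(self) -> None:
        if self.tissue not in ("ovary", "testis", "both"):
            raise ValueError(f"unknown tissue {self.tissue!r}")


@dataclass(frozen=True)
class LibrarySpec:
    """Parameters of one simulated small-RNA library.

    ``pingpong_fraction`` is the fraction of each family's TE read budget
    emitted as sense/antisense pairs whose 5' ends overlap by exactly 10 nt;
    the remaining TE reads get uniform random positions and strands on the
    planted copies.
    """

    tissue: str
    n_mirna_reads: int = 1000
    te_read_budget: int | Mapping[str, int] = 500
    pingpong_fraction: float = 0.0
    read_length_range: tuple[int, int] = (23, 30)
    cluster_read_budget: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tissue not in ("ovary", "testis"):
            raise ValueError(f"unknown tissue {self.tissue!r}")
        if not 0.0 <= self.pingpong_fraction <= 1.0:
            raise ValueError("pingpong_fraction must be in [0, 1]")
        lo, hi = self.read_length_range
        if lo > hi or lo < 5 or hi > 45:
            raise ValueError("read_length_range must be within [5, 45]")


@dataclass(frozen=True)
class PlantedInsertion:
    family_id: str
    copy_index: int
    contig: str
    start: int  # 0-based half-open genomic span
    end: int
    strand: str
    full_length: bool
    cons_start: int  # consensus interval the copy derives from
    cons_end: int
    copy_seq: str  # realized copy sequence in consensus orientation

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PlantedCluster:
    cluster_id: str
    contig: str
    start: int
    end: int
    tissue: str


@dataclass
class GroundTruth:
    """Everything needed to check downstream stages against the planted design."""

    consensus: dict[str, str]
    specs: dict[str, FamilySpec]
    insertions: list[PlantedInsertion] = field(default_factory=list)
    clusters: list[PlantedCluster] = field(default_factory=list)

    def insertions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "family_id": i.family_id,
                    "copy_index": i.copy_index,
                    "contig": i.contig,
                    "start": i.start,
                    "end": i.end,
                    "strand": i.strand,
                    "full_length": i.full_length,
                    "cons_start": i.cons_start,
                    "cons_end": i.cons_end,
                }
                for i in self.insertions
            ]
        )

    def clusters_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "cluster_id": c.cluster_id,
                    "contig": c.contig,
                    "start": c.start,
                    "end": c.end,
                    "tissue": c.tissue,
                }
                for c in self.clusters
            ]
        )

    def family_copies(self, family_id: str) -> list[PlantedInsertion]:
        return [i for i in self.insertions if i.family_id == family_id]

    def true_family_pi(self, family_id: str) -> float:
        """Empirical pi of the planted copies, on the consensus frame."""
        from .te_annotation import nucleotide_diversity

        copies = self.family_copies(family_id)
        if len(copies) < 2:
            return 0.0
        clen = len(self.consensus[family_id])
        rows = [
            "-" * c.cons_start + c.copy_seq + "-" * (clen - c.cons_end) for c in copies
        ]
        return nucleotide_diversity(rows)


def mirna_reference(n: int = 50, length: int = 22) -> list[SequenceRecord]:
    """The fixed set of synthetic miRNA (hairpin-arm) sequences."""
    rng = np.random.default_rng(_MIRNA_SEED)
    return [
        SequenceRecord(f"mir{i + 1:03d}", _codes_to_seq(rng.integers(0, 4, length).astype(np.uint8)))
        for i in range(n)
    ]


def _mutate(codes: np.ndarray, divergence: float, rng: np.random.Generator) -> np.ndarray:
    if divergence <= 0:
        return codes.copy()
    mask = rng.random(codes.size) < divergence
    out = codes.copy()
    if mask.any():
        shift = rng.integers(1, 4, int(mask.sum()))
        out[mask] = (out[mask] + shift) % 4
    return out


def _overlaps_any(start: int, end: int, intervals: list[tuple[int, int]]) -> bool:
    return any(s < end and start < e for s, e in intervals)


def simulate_genome(
    specs: Sequence[FamilySpec],
    contig_lengths: Sequence[int],
    seed: int,
    clusters: Sequence[ClusterSpec] = (),
    cluster_window: int = 1000,
) -> tuple[list[SequenceRecord], GroundTruth]:
    """Simulate a genome with planted TE copies and reserved cluster windows.

    Background is i.i.d. uniform nucleotides.  Each planted copy is the
    family consensus (or a truncated fragment), mutated at the family's
    per-site divergence, inserted at a uniformly chosen non-overlapping
    position on a uniformly chosen strand.  Copies of the same family are
    additionally kept at least one consensus length apart so that planted
    copies map one-to-one onto merged annotations.  A dedicated scaffold
    carrying the miRNA reference set is appended; cluster windows are
    reserved (left as unique background sequence) and recorded in the truth.
    """
    rng = np.random.default_rng(seed)
    specs = sorted(specs, key=lambda s: s.family_id)
    if len({s.family_id for s in specs}) != len(specs):
        raise ValueError("duplicate family_id in specs")

    total_te = sum(s.copy_number * s.consensus_length for s in specs)
    if total_te >= 0.8 * sum(contig_lengths):
        raise ValueError("planted TE length exceeds 80% of total contig length; enlarge contigs")

    contig_ids = [f"contig{i + 1}" for i in range(len(contig_lengths))]
    arrays = {
        cid: rng.integers(0, 4, n).astype(np.uint8)
        for cid, n in zip(contig_ids, contig_lengths)
    }
    lengths = dict(zip(contig_ids, contig_lengths))
    probs = np.asarray(contig_lengths, dtype=float)
    probs /= probs.sum()

    consensus = {
        s.family_id: _codes_to_seq(rng.integers(0, 4, s.consensus_length).astype(np.uint8))
        for s in specs
    }
    truth = GroundTruth(consensus=consensus, specs={s.family_id: s for s in specs})

    occupied: dict[str, list[tuple[int, int]]] = {cid: [] for cid in contig_ids}
    family_sites: dict[tuple[str, str], list[tuple[int, int]]] = {}

    # reserve cluster windows first so TE copies never fall inside them
    for k, cspec in enumerate(clusters):
        placed = False
        for _ in range(1000):
            cid = contig_ids[rng.choice(len(contig_ids), p=probs)]
            n_win = lengths[cid] // cluster_window
            if n_win == 0:
                continue
            w = int(rng.integers(0, n_win))
            start, end = w * cluster_window, (w + 1) * cluster_window
            if not _overlaps_any(start, end, occupied[cid]):
                occupied[cid].append((start, end))
                truth.clusters.append(
                    PlantedCluster(f"cluster{k + 1:03d}", cid, start, end, cspec.tissue)
                )
                placed = True
                break
        if not placed:
            raise RuntimeError("could not place a cluster window; use larger contigs")

    for spec in specs:
        cons_codes = np.frombuffer(consensus[spec.family_id].encode(), dtype=np.uint8)
        cons_codes = np.searchsorted(_BASES, cons_codes).astype(np.uint8)
        L = spec.consensus_length
        for copy_index in range(spec.copy_number):
            full = bool(rng.random() < spec.full_length_fraction)
            if full:
                cs, ce = 0, L
            else:
                frac = rng.uniform(spec.min_truncated_fraction, 0.98)
                k = max(30, int(round(frac * L)))
                if rng.random() < 0.5:
                    cs, ce = 0, k
                else:
                    cs, ce = L - k, L
            frag = _mutate(cons_codes[cs:ce], spec.divergence, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            m = ce - cs

            placed = False
            for _ in range(1000):
                cid = contig_ids[rng.choice(len(contig_ids), p=probs)]
                if lengths[cid] < m:
                    continue
                start = int(rng.integers(0, lengths[cid] - m + 1))
                end = start + m
                if _overlaps_any(start, end, occupied[cid]):
                    continue
                # same-family spacing >= consensus length keeps merged
                # annotations one-to-one with planted copies
                near = family_sites.get((spec.family_id, cid), [])
                if _overlaps_any(start - L, end + L, near):
                    continue
                placed = True
                break
            if not placed:
                raise RuntimeError(
                    f"could not place copy {copy_index} of {spec.family_id} "
                    "after 1000 attempts; use larger contigs"
                )
            copy_codes = frag if strand == "+" else (3 - frag)[::-1]
            arrays[cid][start:end] = copy_codes
            occupied[cid].append((start, end))
            family_sites.setdefault((spec.family_id, cid), []).append((start, end))
            truth.insertions.append(
                PlantedInsertion(
                    family_id=spec.family_id,
                    copy_index=copy_index,
                    contig=cid,
                    start=start,
                    end=end,
                    strand=strand,
                    full_length=full,
                    cons_start=cs,
                    cons_end=ce,
                    copy_seq=_codes_to_seq(frag),
                )
            )

    records = [SequenceRecord(cid, _codes_to_seq(arrays[cid])) for cid in contig_ids]

    # dedicated miRNA scaffold, excluded from TE annotation
    mirnas = mirna_reference()
    spacer_rng = np.random.default_rng(_MIRNA_SEED + 1)
    parts: list[str] = []
    for rec in mirnas:
        parts.append(_codes_to_seq(spacer_rng.integers(0, 4, 30).astype(np.uint8)))
        parts.append(rec.sequence)
    parts.append(_codes_to_seq(spacer_rng.integers(0, 4, 30).astype(np.uint8)))
    records.append(SequenceRecord(MIRNA_CONTIG, "".join(parts)))
    return records, truth


def _hit_identity(copy_seq: str, cons_slice: str) -> tuple[float, int]:
    a = np.frombuffer(copy_seq.encode(), dtype=np.uint8)
    b = np.frombuffer(cons_slice.encode(), dtype=np.uint8)
    mism = int((a != b).sum())
    return 100.0 * (len(a) - mism) / len(a), mism


def hits_from_truth(
    truth: GroundTruth, seed: int, split_prob: float = 0.3, min_split_len: int = 120
) -> list[TabularHit]:
    """Emit a 12-column-style hit table for the planted copies.

    Each planted copy yields one hit over its genomic span; with probability
    ``split_prob`` (and enough length) the hit is instead emitted as two
    overlapping partial hits, exercising the downstream hit merger.  Identity
    is the true percent identity of the realized copy to its consensus slice.
    """
    rng = np.random.default_rng(seed)
    hits: list[TabularHit] = []

    def _mk(ins: PlantedInsertion, g0: int, g1: int, c0: int, c1: int) -> TabularHit:
        # consensus-frame slice [c0, c1) of the copy maps to genome [g0, g1)
        sub = ins.copy_seq[c0 - ins.cons_start : c1 - ins.cons_start]
        ident, mism = _hit_identity(sub, truth.consensus[ins.family_id][c0:c1])
        alen = c1 - c0
        return TabularHit(
            query_id=ins.family_id,
            subject_id=ins.contig,
            percent_identity=round(ident, 2),
            alignment_length=alen,
            mismatches=mism,
            gap_openings=0,
            query_start=c0 + 1,
            query_end=c1,
            subject_start=g0 + 1,
            subject_end=g1,
            e_value=0.0,
            bit_score=round(2.0 * alen, 1),
            strand=ins.strand,
        )

    for ins in truth.insertions:
        m = ins.length
        if m >= min_split_len and rng.random() < split_prob:
            # two overlapping hits covering the copy (overlap 20 nt)
            mid = int(rng.integers(m // 3, 2 * m // 3))
            parts = [(0, mid + 20), (mid, m)]
        else:
            parts = [(0, m)]
        for r0, r1 in parts:
            if ins.strand == "+":
                g0, g1 = ins.start + r0, ins.start + r1
            else:
                # copy runs right-to-left on the genome
                g0, g1 = ins.end - r1, ins.end - r0
            hits.append(_mk(ins, g0, g1, ins.cons_start + r0, ins.cons_start + r1))
    hits.sort(key=lambda h: (h.subject_id, h.subject_start, h.query_id))
    return hits


def simulate_smallrna(
    genome_records: Sequence[SequenceRecord],
    truth: GroundTruth,
    spec: LibrarySpec,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Simulate one tissue's small-RNA library with full provenance.

    Emits, in order: miRNA reads (exact copies of the reference set),
    per-family TE-derived reads of uniform length in the configured range —
    a ``pingpong_fraction`` of each budget as sense/antisense pairs whose 5'
    ends overlap by exactly 10 nt on the consensus, the rest at uniform
    random positions and strands — and uniquely-mappable reads from planted
    cluster windows active in this tissue.
    """
    rng = np.random.default_rng(spec.seed)
    genome = {r.id: r.sequence for r in genome_records}
    lo, hi = spec.read_length_range
    reads: list[SequenceRecord] = []
    prov: list[dict] = []
    counter = 0

    def emit(seq: str, **meta) -> str:
        nonlocal counter
        rid = f"{spec.tissue}_r{counter:07d}"
        counter += 1
        reads.append(SequenceRecord(rid, seq))
        prov.append({"read_id": rid, "tissue": spec.tissue, **meta})
        return rid

    mirnas = mirna_reference()
    for _ in range(spec.n_mirna_reads):
        i = int(rng.integers(0, len(mirnas)))
        emit(mirnas[i].sequence, source="mirna", family_id=mirnas[i].id,
             strand="+", cons_5p=-1, length=len(mirnas[i].sequence), pair_id=-1)

    families = sorted(truth.specs)
    if isinstance(spec.te_read_budget, Mapping):
        budgets = {f: int(spec.te_read_budget.get(f, 0)) for f in families}
    else:
        budgets = {f: int(spec.te_read_budget) for f in families}

    pair_counter = 0
    for family in families:
        budget = budgets[family]
        if budget <= 0:
            continue
        copies = truth.family_copies(family)
        if not copies:
            raise ValueError(f"te_read_budget > 0 but no planted copies for {family}")
        usable = [c for c in copies if c.length >= 2 * hi]
        n_pairs = int(round(budget * spec.pingpong_fraction / 2.0))
        n_single = budget - 2 * n_pairs
        if n_pairs > 0 and not usable:
            raise ValueError(f"no planted copy of {family} is long enough for ping-pong pairs")

        for _ in range(n_pairs):
            c = usable[int(rng.integers(0, len(usable)))]
            la = int(rng.integers(lo, hi + 1))
            ls = int(rng.integers(lo, hi + 1))
            p_min = c.cons_start + la - 1
            p_max = c.cons_end + 9 - ls
            p = int(rng.integers(p_min, p_max + 1))
            sense_start = p - 9
            sense = c.copy_seq[sense_start - c.cons_start : sense_start - c.cons_start + ls]
            anti = revcomp(c.copy_seq[p - la + 1 - c.cons_start : p + 1 - c.cons_start])
            pid = pair_counter
            pair_counter += 1
            emit(sense, source="te", family_id=family, strand="+",
                 cons_5p=sense_start, length=ls, pair_id=pid)
            emit(anti, source="te", family_id=family, strand="-",
                 cons_5p=p, length=la, pair_id=pid)

        for _ in range(n_single):
            c = copies[int(rng.integers(0, len(copies)))]
            max_l = min(hi, c.length)
            length = int(rng.integers(lo, max_l + 1)) if max_l > lo else lo
            start = int(rng.integers(c.cons_start, c.cons_end - length + 1))
            seq = c.copy_seq[start - c.cons_start : start - c.cons_start + length]
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                seq = revcomp(seq)
                c5 = start + length - 1
            else:
                c5 = start
            emit(seq, source="te", family_id=family, strand=strand,
                 cons_5p=c5, length=length, pair_id=-1)

    if spec.cluster_read_budget > 0:
        active = [c for c in truth.clusters if c.tissue in (spec.tissue, "both")]
        if not active:
            raise ValueError("cluster_read_budget > 0 but no active planted clusters")
        for cl in active:
            for _ in range(spec.cluster_read_budget):
                length = int(rng.integers(lo, hi + 1))
                start = int(rng.integers(cl.start, cl.end - length + 1))
                seq = genome[cl.contig][start : start + length]
                strand = "+" if rng.random() < 0.5 else "-"
                g5 = start if strand == "+" else start + length - 1
                if strand == "-":
                    seq = revcomp(seq)
                emit(seq, source="cluster", family_id=cl.cluster_id,
                     strand=strand, cons_5p=g5, length=length, pair_id=-1)

    return reads, pd.DataFrame(prov)


def simulate_counts(
    copy_numbers: Mapping[str, int],
    effect: float,
    noise_dispersion: float,
    seed: int,
    intercept: float = 2.0,
) -> pd.DataFrame:
    """Per-family mRNA counts from a negative-binomial law.

    log10 of the mean is ``intercept + effect * log10(copy_number)``;
    ``noise_dispersion`` is the NB size parameter (variance = mu + mu^2/size),
    with the Poisson limit taken when it is infinite.
    """
    if not noise_dispersion > 0:
        raise ValueError("noise_dispersion must be positive")
    if len(copy_numbers) < 2:
        raise ValueError("need at least 2 families")
    rng = np.random.default_rng(seed)
    families = sorted(copy_numbers)
    cn = np.array([max(copy_numbers[f], 1) for f in families], dtype=float)
    mu = 10.0 ** (intercept + effect * np.log10(cn))
    if np.isinf(noise_dispersion):
        counts = rng.poisson(mu)
    else:
        p = noise_dispersion / (noise_dispersion + mu)
        counts = rng.negative_binomial(noise_dispersion, p)
    return pd.DataFrame(
        {"family_id": families, "count": counts.astype(int), "true_mean": mu}
    )


def default_scenario(seed: int = 1) -> dict:
    """The default simulated study: a 750-kb genome with 10 TE families.

    Families span the contrasts the analyses exercise — young low-divergence
    families rich in full-length copies and older, highly truncated ones —
    plus ten planted piRNA-cluster windows skewed towards ovary-specific
    activity, and ovary/testis libraries with asymmetric per-family budgets
    (so both sex-bias classes occur) and a stronger ovarian ping-pong
    fraction.
    """
    te_classes = ["LTR", "non-LTR", "DNA"]
    lengths = [800, 1200, 1500, 2000, 2500, 3000, 1000, 1800, 2200, 900]
    copies = [5, 8, 10, 12, 15, 20, 25, 30, 6, 18]
    divergences = [0.0, 0.02, 0.04, 0.06, 0.08, 0.1, 0.01, 0.03, 0.05, 0.12]
    fl_fracs = [0.9, 0.7, 0.5, 0.6, 0.4, 0.3, 0.8, 0.5, 0.7, 0.2]
    specs = [
        FamilySpec(
            family_id=f"FAM{i + 1:02d}",
            consensus_length=lengths[i],
            te_class=te_classes[i % 3],
            copy_number=copies[i],
            divergence=divergences[i],
            full_length_fraction=fl_fracs[i],
        )
        for i in range(10)
    ]
    clusters = [ClusterSpec("ovary")] * 7 + [ClusterSpec("testis")] + [ClusterSpec("both")] * 2
    fams = [s.family_id for s in specs]
    ovary_budget = {f: 80 + 30 * i for i, f in enumerate(fams)}
    testis_budget = {f: 80 + 30 * (9 - i) for i, f in enumerate(fams)}
    libraries = {
        "ovary": LibrarySpec(
            tissue="ovary",
            n_mirna_reads=3000,
            te_read_budget=ovary_budget,
            pingpong_fraction=0.4,
            cluster_read_budget=25,
            seed=seed * 1000 + 1,
        ),
        "testis": LibrarySpec(
            tissue="testis",
            n_mirna_reads=2000,
            te_read_budget=testis_budget,
            pingpong_fraction=0.1,
            cluster_read_budget=25,
            seed=seed * 1000 + 2,
        ),
    }
    return {
        "specs": specs,
        "contig_lengths": [250_000, 250_000, 250_000],
        "clusters": clusters,
        "libraries": libraries,
        "seed": seed,
        "mrna": {"effect": 1.0, "noise_dispersion": 5.0, "seed": seed * 1000 + 7},
    }


def simulate_trait_table(
    n_families: int,
    seed: int,
    mrna_effect: float = 0.6,
    length_effect: float = 0.4,
    pi_effect: float = -4.0,
    copy_to_mrna: float = 0.6,
    noise_sd: float = 0.25,
) -> pd.DataFrame:
    """Model-based per-family trait table with the expected dependency web.

    piRNA output increases with mRNA level (itself driven by copy number) and
    family length, and decreases with nucleotide diversity pi (older, more
    degenerate families mount a weaker response).  Used for the statistical
    layer, where sequence-level simulation adds nothing.
    """
    if n_families < 3:
        raise ValueError("need at least 3 families")
    rng = np.random.default_rng(seed)
    cn = np.round(10.0 ** rng.uniform(0.3, 2.0, n_families)).astype(int)
    length = np.round(10.0 ** rng.uniform(2.5, 3.8, n_families))
    pi = rng.uniform(0.0, 0.15, n_families)
    log_mrna = 1.0 + copy_to_mrna * np.log10(cn) + rng.normal(0, noise_sd, n_families)
    log_pirna = (
        0.5
        + mrna_effect * log_mrna
        + length_effect * np.log10(length)
        + pi_effect * pi
        + rng.normal(0, noise_sd, n_families)
    )
    return pd.DataFrame(
        {
            "family_id": [f"FAM{i + 1:03d}" for i in range(n_families)],
            "copy_number": cn,
            "median_length": length,
            "pi": pi,
            "mrna_level": 10.0 ** log_mrna,
            "pirna_level": 10.0 ** log_pirna,
        }
    )
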