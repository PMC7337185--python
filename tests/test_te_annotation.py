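import itertools

import numpy as np
import pytest

from pirnatk import te_annotation as ann
from pirnatk.io_formats import TabularHit


def make_hit(family="F1", contig="c1", start0=0, end0=100, identity=90.0, strand="+"):
    """Hit helper taking a 0-based half-open subject span."""
    return TabularHit(
        query_id=family, subject_id=contig, percent_identity=identity,
        alignment_length=end0 - start0, mismatches=0, gap_openings=0,
        query_start=1, query_end=end0 - start0,
        subject_start=start0 + 1, subject_end=end0,
        e_value=0.0, bit_score=100.0, strand=strand,
    )


class TestFilterHits:
    @pytest.mark.parametrize(
        "identity,kept",
        [(79.9, False), (80.0, True), (95.0, True)],
    )
    def test_identity_boundary(self, identity, kept):
        hits = [make_hit(identity=identity)]
        assert (len(ann.filter_hits(hits)) == 1) is kept

    def test_empty_input(self):
        assert ann.filter_hits([]) == []

    def test_order_preserved(self):
        hits = [make_hit(start0=s, identity=80 + s % 3) for s in range(0, 50, 10)]
        assert ann.filter_hits(hits) == hits


def brute_force_merge(hits, consensus_length):
    """Independent fixpoint merger: repeatedly merge the first qualifying pair
    (sorted order) until no pair satisfies the merge predicate."""
    items = sorted(
        [[h.span0[0], h.span0[1], h.percent_identity * h.alignment_length,
          h.alignment_length, 1] for h in hits]
    )
    changed = True
    while changed:
        changed = False
        items.sort()
        for i, j in itertools.combinations(range(len(items)), 2):
            a, b = items[i], items[j]
            overlap = a[0] < b[1] and b[0] < a[1]
            gap = max(a[0], b[0]) - min(a[1], b[1])
            len_sum = (a[1] - a[0]) + (b[1] - b[0])
            if overlap or len_sum + gap < consensus_length:
                merged = [min(a[0], b[0]), max(a[1], b[1]),
                          a[2] + b[2], a[3] + b[3], a[4] + b[4]]
                items = [items[k] for k in range(len(items)) if k not in (i, j)]
                items.append(merged)
                changed = True
                break
    return sorted((s, e, round(w / al, 9), n) for s, e, w, al, n in items)


class TestMergeFamilyHits:
    def test_gap_rule_merges_when_sum_below_consensus(self):
        # spans 401 + 351 nt with a 49 nt gap: 801 < 1000 -> one insertion
        hits = [make_hit(start0=100, end0=501), make_hit(start0=550, end0=901)]
        (ins,) = ann.merge_family_hits(hits, consensus_length=1000)
        assert (ins.start, ins.end, ins.n_merged_hits) == (100, 901, 2)

    def test_gap_rule_splits_when_sum_reaches_consensus(self):
        hits = [make_hit(start0=100, end0=501), make_hit(start0=550, end0=901)]
        out = ann.merge_family_hits(hits, consensus_length=600)
        assert [(i.start, i.end) for i in out] == [(100, 501), (550, 901)]

    def test_single_hit(self):
        (ins,) = ann.merge_family_hits([make_hit(start0=0, end0=500)], 1000)
        assert ins.completeness == 0.5
        assert ins.n_merged_hits == 1

    def test_overlapping_hits_always_merge(self):
        hits = [make_hit(start0=0, end0=500), make_hit(start0=400, end0=900)]
        (ins,) = ann.merge_family_hits(hits, consensus_length=100)
        assert (ins.start, ins.end) == (0, 900)

    def test_identity_is_length_weighted(self):
        hits = [make_hit(start0=0, end0=300, identity=90.0),
                make_hit(start0=320, end0=420, identity=80.0)]
        (ins,) = ann.merge_family_hits(hits, consensus_length=2000)
        assert ins.identity == pytest.approx((90 * 300 + 80 * 100) / 400)

    def test_mixed_groups_rejected(self):
        with pytest.raises(ValueError):
            ann.merge_family_hits(
                [make_hit(family="F1"), make_hit(family="F2")], 1000)

    def test_matches_bruteforce_fixpoint_on_random_tables(self):
        rng = np.random.default_rng(101)
        for _ in range(200):
            n = int(rng.integers(1, 30))
            consensus_length = int(rng.integers(50, 1500))
            hits = []
            for _ in range(n):
                s = int(rng.integers(0, 3000))
                length = int(rng.integers(10, 600))
                hits.append(make_hit(start0=s, end0=s + length,
                                     identity=float(rng.uniform(80, 100))))
            got = ann.merge_family_hits(hits, consensus_length)
            got_key = sorted(
                (i.start, i.end, round(i.identity, 9), i.n_merged_hits) for i in got
            )
            assert got_key == brute_force_merge(hits, consensus_length)


def _ins(family, start, end, identity, contig="c1"):
    return ann.TEInsertion(family_id=family, contig=contig, start=start, end=end,
                           strand="+", identity=identity, n_merged_hits=1,
                           completeness=0.5, full_length=False)


class TestResolveCrossFamily:
    def test_containment_keeps_highest_identity(self):
        a = _ins("F1", 100, 900, 85.0)
        b = _ins("F2", 50, 1000, 92.0)
        assert ann.resolve_cross_family_overlaps([a, b]) == [b]

    def test_partial_overlap_keeps_both(self):
        a = _ins("F1", 0, 500, 85.0)
        b = _ins("F2", 450, 1000, 92.0)
        out = ann.resolve_cross_family_overlaps([a, b])
        assert sorted(i.family_id for i in out) == ["F1", "F2"]

    def test_reciprocal_overlap_threshold(self):
        # overlap 300 of shorter length 500 = 60% >= 50% -> conflict
        a = _ins("F1", 0, 500, 85.0)
        b = _ins("F2", 200, 900, 92.0)
        assert [i.family_id for i in ann.resolve_cross_family_overlaps([a, b])] == ["F2"]

    def test_tie_break_longer_then_lexicographic(self):
        # equal identity: keep the longer insertion
        a = _ins("F1", 100, 600, 90.0)
        b = _ins("F2", 100, 900, 90.0)
        assert [i.family_id for i in ann.resolve_cross_family_overlaps([a, b])] == ["F2"]
        # equal identity and length: keep the lexicographically smaller family
        c = _ins("FB", 100, 900, 90.0)
        d = _ins("FA", 100, 900, 90.0)
        assert [i.family_id for i in ann.resolve_cross_family_overlaps([c, d])] == ["FA"]

    def test_same_family_overlaps_untouched(self):
        a = _ins("F1", 0, 500, 85.0)
        b = _ins("F1", 100, 400, 90.0)
        assert len(ann.resolve_cross_family_overlaps([a, b])) == 2


def brute_force_pi(aligned, freqs=None):
    n = len(aligned)
    if freqs is None:
        freqs = [1 / n] * n
    total = 0.0
    for i in range(n):
        for j in range(i):
            comp = diff = 0
            for a, b in zip(aligned[i], aligned[j]):
                if a in "-N" or b in "-N":
                    continue
                comp += 1
                diff += a != b
            total += freqs[i] * freqs[j] * (diff / comp if comp else 0.0)
    return 2 * total


class TestNucleotideDiversity:
    def test_identical_copies_give_zero(self):
        assert ann.nucleotide_diversity(["ACGT" * 25] * 4) == 0.0

    def test_hand_case_two_copies_one_difference(self):
        a = "A" * 100
        b = "A" * 99 + "C"
        assert ann.nucleotide_diversity([a, b]) == pytest.approx(0.005, abs=1e-15)

    def test_hand_case_three_copies(self):
        base = "A" * 100
        s1 = base
        s2 = "CC" + base[2:]             # d12 = 2
        s3 = "CC" + "GG" + base[4:]      # d13 = 4, d23 = 2
        pi = ann.nucleotide_diversity([s1, s2, s3])
        assert pi == pytest.approx(2 * (1 / 9) * (0.02 + 0.04 + 0.02), abs=1e-15)

    def test_fewer_than_two_copies(self):
        assert ann.nucleotide_diversity([]) == 0.0
        assert ann.nucleotide_diversity(["ACGT"]) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ann.nucleotide_diversity(["ACGT", "ACG"])

    def test_matches_bruteforce_double_loop(self):
        from conftest import random_alignment

        rng = np.random.default_rng(77)
        for _ in range(60):
            n = int(rng.integers(2, 11))
            length = int(rng.integers(5, 201))
            rows = random_alignment(rng, n, length)
            freqs = rng.dirichlet(np.ones(n)).tolist()
            assert ann.nucleotide_diversity(rows) == pytest.approx(
                brute_force_pi(rows), abs=1e-12)
            assert ann.nucleotide_diversity(rows, freqs) == pytest.approx(
                brute_force_pi(rows, freqs), abs=1e-12)

    def test_monotone_in_divergence(self):
        from pirnatk import synthetic_data as sd

        pis = []
        for d in (0.0, 0.01, 0.05, 0.1):
            spec = sd.FamilySpec("F", 1000, copy_number=20, divergence=d,
                                 full_length_fraction=1.0)
            _, truth = sd.simulate_genome([spec], [80_000], seed=31)
            pis.append(truth.true_family_pi("F"))
        assert pis == sorted(pis)


class TestAlignCopies:
    def test_exact_copy_at_offset_zero(self):
        cons = "ACGTACGTACGT"
        (row,) = ann.align_copies_to_consensus([cons], cons)
        assert row == cons

    def test_truncated_fragment_placed_with_leading_gaps(self):
        rng = np.random.default_rng(5)
        cons = "".join(rng.choice(list("ACGT"), 600))
        frag = cons[200:500]
        (row,) = ann.align_copies_to_consensus([frag], cons)
        assert row == "-" * 200 + frag + "-" * 100

    def test_copy_longer_than_consensus_rejected(self):
        with pytest.raises(ValueError):
            ann.align_copies_to_consensus(["ACGTA"], "ACGT")

    def test_recovers_planted_offset_with_substitutions(self):
        rng = np.random.default_rng(11)
        bases = np.array(list("ACGT"))
        hitrate = 0
        for _ in range(1000):
            cons = "".join(rng.choice(bases, 300))
            off = int(rng.integers(0, 220))
            frag = list(cons[off:off + 80])
            for p in rng.choice(80, 3, replace=False):
                frag[p] = bases[(bases != frag[p])][int(rng.integers(0, 3))]
            (row,) = ann.align_copies_to_consensus(["".join(frag)], cons)
            hitrate += row[off] != "-" and (off == 0 or row[off - 1] == "-")
        assert hitrate >= 990


class TestSummarizeFamily:
    def test_median_of_three_lengths(self):
        ins = [_ins("F", 0, 100, 90), _ins("F", 200, 600, 90), _ins("F", 700, 1600, 90)]
        s = ann.summarize_family("F", ins, [], consensus_length=1000)
        assert s.median_length == 400

    def test_full_length_boundary_at_98_percent(self):
        hits_short = [make_hit(start0=0, end0=979)]
        hits_full = [make_hit(start0=0, end0=980)]
        (short,) = ann.merge_family_hits(hits_short, 1000)
        (full,) = ann.merge_family_hits(hits_full, 1000)
        assert short.completeness == pytest.approx(0.979)
        assert not short.full_length
        assert full.full_length

    def test_single_insertion_pi_zero(self):
        s = ann.summarize_family("F", [_ins("F", 0, 100, 90)], ["ACGT"], 1000)
        assert s.pi == 0.0
        assert s.copy_number == 1
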