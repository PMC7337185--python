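import itertools

import numpy as np
import pytest
from scipy import stats as sps

from pirnatk import synthetic_data as sd
from pirnatk.io_formats import revcomp


def _pairwise_difference_rate(copies: list[str]) -> float:
    """Brute-force mean per-site Hamming difference over all copy pairs."""
    diffs = []
    for a, b in itertools.combinations(copies, 2):
        diffs.append(sum(x != y for x, y in zip(a, b)) / len(a))
    return float(np.mean(diffs))


class TestSimulateGenome:
    def test_zero_copy_family_leaves_no_trace(self):
        spec = sd.FamilySpec("F", 500, copy_number=0)
        genome, truth = sd.simulate_genome([spec], [20_000], seed=1)
        assert truth.insertions == []
        assert truth.consensus["F"] not in genome[0].sequence

    def test_zero_divergence_copies_are_exact(self):
        spec = sd.FamilySpec("F", 500, copy_number=5, divergence=0.0,
                             full_length_fraction=1.0)
        genome, truth = sd.simulate_genome([spec], [30_000], seed=2)
        contig = genome[0].sequence
        assert len(truth.insertions) == 5
        for ins in truth.insertions:
            assert ins.copy_seq == truth.consensus["F"]
            emb = contig[ins.start:ins.end]
            if ins.strand == "-":
                emb = revcomp(emb)
            assert emb == ins.copy_seq
        assert truth.true_family_pi("F") == 0.0

    def test_divergence_matches_bruteforce_pairwise_count(self):
        d = 0.05
        spec = sd.FamilySpec("F", 2000, copy_number=20, divergence=d,
                             full_length_fraction=1.0)
        _, truth = sd.simulate_genome([spec], [120_000], seed=3)
        copies = [i.copy_seq for i in truth.insertions]
        observed = _pairwise_difference_rate(copies)
        # two independently mutated copies differ at a site with prob 2d(1-d)
        # plus the coincident-substitution term 2/3 d^2
        expected = 2 * d * (1 - d) + (2 / 3) * d * d
        assert observed == pytest.approx(expected, rel=0.10)
        # with equal frequencies x_i = 1/n the diversity formula equals
        # (n-1)/n times the mean pairwise difference
        n = len(copies)
        assert truth.true_family_pi("F") == pytest.approx(
            observed * (n - 1) / n, abs=1e-12)

    def test_determinism_byte_identical(self):
        spec = sd.FamilySpec("F", 400, copy_number=6, divergence=0.03)
        g1, t1 = sd.simulate_genome([spec], [25_000], seed=9,
                                    clusters=[sd.ClusterSpec("ovary")])
        g2, t2 = sd.simulate_genome([spec], [25_000], seed=9,
                                    clusters=[sd.ClusterSpec("ovary")])
        assert g1 == g2
        assert t1.insertions == t2.insertions
        assert t1.clusters == t2.clusters

    def test_over_dense_request_rejected(self):
        spec = sd.FamilySpec("F", 1000, copy_number=50, full_length_fraction=1.0)
        with pytest.raises(ValueError, match="80%"):
            sd.simulate_genome([spec], [50_000], seed=1)

    def test_mirna_scaffold_contains_reference_set(self):
        genome, _ = sd.simulate_genome([], [5_000], seed=4)
        scaffold = [r for r in genome if r.id == sd.MIRNA_CONTIG][0]
        for mir in sd.mirna_reference():
            assert mir.sequence in scaffold.sequence


class TestHitsFromTruth:
    def test_hits_cover_every_insertion_and_merge_back(self):
        from pirnatk.io_formats import SequenceRecord
        from pirnatk.te_annotation import annotate_genome

        spec = sd.FamilySpec("F", 800, copy_number=10, divergence=0.04,
                             full_length_fraction=0.5)
        genome, truth = sd.simulate_genome([spec], [60_000], seed=5)
        hits = sd.hits_from_truth(truth, seed=6, split_prob=1.0)
        assert len(hits) == 2 * len(truth.insertions)  # all split in two
        cons = [SequenceRecord(f, s) for f, s in truth.consensus.items()]
        insertions, _ = annotate_genome(hits, cons, genome)
        got = sorted((i.contig, i.start, i.end, i.strand) for i in insertions)
        want = sorted((i.contig, i.start, i.end, i.strand) for i in truth.insertions)
        assert got == want


@pytest.fixture(scope="module")
def planted():
    spec = sd.FamilySpec("F", 1500, copy_number=4, divergence=0.0,
                         full_length_fraction=1.0)
    return sd.simulate_genome([spec], [40_000], seed=7,
                              clusters=[sd.ClusterSpec("ovary")])


class TestSimulateSmallRNA:
    def test_pingpong_pairs_overlap_exactly_ten(self, planted):
        genome, truth = planted
        lib = sd.LibrarySpec("ovary", n_mirna_reads=0, te_read_budget=200,
                             pingpong_fraction=1.0, seed=11)
        _, prov = sd.simulate_smallrna(genome, truth, lib)
        te = prov[prov.source == "te"]
        for _, pair in te.groupby("pair_id"):
            assert len(pair) == 2
            sense = pair[pair.strand == "+"].iloc[0]
            anti = pair[pair.strand == "-"].iloc[0]
            # 5'-5' overlap k = (minus 5') - (plus 5') + 1 == 10
            assert anti.cons_5p - sense.cons_5p + 1 == 10

    def test_null_overlap_histogram_is_flat(self, planted):
        """With no planted ping-pong the 5'-5' overlap histogram over
        offsets 1..20 shows no structure (chi-square GOF)."""
        from pirnatk.pingpong import overlap_distribution
        from pirnatk.smallrna import ConsensusAlignment

        genome, truth = planted
        lib = sd.LibrarySpec("ovary", n_mirna_reads=0, te_read_budget=10_000,
                             pingpong_fraction=0.0, seed=13)
        _, prov = sd.simulate_smallrna(genome, truth, lib)
        alns = [
            ConsensusAlignment(r.read_id, "F", int(r.cons_5p if r.strand == "+"
                                                   else r.cons_5p - r.length + 1),
                               r.strand, 0, int(r.length))
            for r in prov.itertuples()
        ]
        counts = overlap_distribution(alns, k_max=20)
        chi = sps.chisquare(counts)
        assert chi.pvalue > 0.01

    def test_mirna_reads_trace_to_reference(self, planted):
        genome, truth = planted
        lib = sd.LibrarySpec("ovary", n_mirna_reads=1000, te_read_budget=0, seed=17)
        reads, prov = sd.simulate_smallrna(genome, truth, lib)
        assert (prov.source == "mirna").sum() == 1000
        mirna_seqs = {m.sequence for m in sd.mirna_reference()}
        assert all(r.sequence in mirna_seqs for r in reads)

    def test_read_conservation_and_provenance(self, planted):
        genome, truth = planted
        lib = sd.LibrarySpec("ovary", n_mirna_reads=100, te_read_budget=250,
                             pingpong_fraction=0.3, cluster_read_budget=40, seed=19)
        reads, prov = sd.simulate_smallrna(genome, truth, lib)
        assert len(reads) == len(prov) == 100 + 250 + 40
        assert prov.read_id.is_unique

    def test_budget_without_copies_errors(self, planted):
        genome, truth = planted
        empty_truth = sd.GroundTruth(consensus=truth.consensus, specs=truth.specs)
        lib = sd.LibrarySpec("ovary", n_mirna_reads=0, te_read_budget=10, seed=1)
        with pytest.raises(ValueError, match="no planted copies"):
            sd.simulate_smallrna(genome, empty_truth, lib)


class TestSimulateCounts:
    def test_null_effect_gives_no_correlation(self):
        cn = {f"F{i}": int(c) for i, c in
              enumerate(np.random.default_rng(0).integers(2, 100, 50))}
        df = sd.simulate_counts(cn, effect=0.0, noise_dispersion=5.0, seed=23)
        r = np.corrcoef(np.log10(df["count"] + 1),
                        np.log10([max(cn[f], 1) for f in df.family_id]))[0, 1]
        assert abs(r) < 0.3

    def test_strong_effect_recovered(self):
        cn = {f"F{i}": int(c) for i, c in
              enumerate(np.random.default_rng(1).integers(2, 100, 50))}
        df = sd.simulate_counts(cn, effect=1.0, noise_dispersion=50.0, seed=29)
        r = np.corrcoef(np.log10(df["count"] + 1),
                        np.log10([cn[f] for f in df.family_id]))[0, 1]
        assert r > 0.8

    def test_poisson_limit_variance_equals_mean(self):
        cn = {"A": 10, "B": 10}
        draws = np.array([
            sd.simulate_counts(cn, effect=0.0, noise_dispersion=np.inf, seed=s,
                               intercept=2.0)["count"].to_numpy()
            for s in range(1000)
        ])
        assert draws.var(axis=0).mean() == pytest.approx(draws.mean(), rel=0.15)

    def test_nonpositive_dispersion_rejected(self):
        with pytest.raises(ValueError, match="dispersion"):
            sd.simulate_counts({"A": 5, "B": 6}, effect=1.0, noise_dispersion=0.0, seed=1)
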