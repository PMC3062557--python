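import numpy as np
import pytest

from cassette import seqs, simulate, synteny
from cassette.synteny import (
    chain_and_extend,
    classify_contigs_by_composition,
    compare_genomes,
    detect_breaks,
    find_anchors,
    map_contigs,
    verify_order_with_mates,
)

from .conftest import oracle_identity, small_population


def rand_seq(n, seed):
    return simulate.generate_backbone(n, np.random.default_rng(seed))


class TestAnchors:
    def test_identical_sequences_single_full_anchor(self):
        s = rand_seq(10_000, 0)
        anchors = [a for a in find_anchors(s, s) if a.strand == "+"]
        longest = max(anchors, key=lambda a: a.length)
        assert (longest.ref_pos, longest.qry_pos, longest.length) == (0, 0, len(s))

    def test_revcomp_minus_strand_anchor(self):
        s = rand_seq(5000, 1)
        anchors = find_anchors(s, seqs.revcomp(s))
        minus = [a for a in anchors if a.strand == "-"]
        longest = max(minus, key=lambda a: a.length)
        assert longest.length == len(s)

    def test_shuffled_anchor_count_poisson_bound(self):
        s = rand_seq(20_000, 2)
        rng = np.random.default_rng(3)
        shuffled = "".join(rng.permutation(list(s)))
        anchors = find_anchors(s, shuffled, k=15, both_strands=True)
        # expected random 15-mer collisions: 2 * n*m/4^15 ~ 0.75
        expected = 2 * len(s) * len(shuffled) / 4**15
        assert len(anchors) <= expected + 6 * np.sqrt(expected) + 5

    def test_anchor_substring_invariant(self):
        ref = rand_seq(4000, 4)
        qry, _ = simulate.derive_strain(ref, 0.97, np.random.default_rng(5))
        for a in find_anchors(ref, qry)[:200]:
            target = qry if a.strand == "+" else seqs.revcomp(qry)
            assert ref[a.ref_pos : a.ref_end] == target[a.qry_pos : a.qry_end]

    def test_k_minimum(self):
        with pytest.raises(ValueError):
            find_anchors("ACGT" * 100, "ACGT" * 100, k=5)


class TestChaining:
    def test_uniform_pair_single_block(self):
        ref = rand_seq(20_000, 6)
        qry, _ = simulate.derive_strain(ref, 0.97, np.random.default_rng(7), indel_frac=0.0)
        blocks = chain_and_extend(find_anchors(ref, qry), ref, qry)
        main = max(blocks, key=lambda b: b.ref_len)
        assert main.ref_len > 0.99 * len(ref)
        assert main.identity == pytest.approx(0.97, abs=0.005)

    def test_insertion_splits_blocks(self):
        left = rand_seq(8000, 8)
        right = rand_seq(8000, 9)
        cassette = rand_seq(10_000, 10)
        ref = left + cassette + right
        qry = left + right
        blocks = chain_and_extend(find_anchors(ref, qry), ref, qry)
        big = sorted(
            (b for b in blocks if b.ref_len > 1000), key=lambda b: b.ref_start
        )
        assert len(big) == 2
        ref_gap = big[1].ref_start - big[0].ref_end
        qry_gap = big[1].qry_start - big[0].qry_end
        assert ref_gap == pytest.approx(len(cassette), abs=50)
        assert abs(qry_gap) <= 50

    def test_empty_anchors_empty_blocks(self):
        assert chain_and_extend([], "ACGT" * 100, "ACGT" * 100) == []

    def test_colinearity_invariant(self):
        ref = rand_seq(15_000, 11)
        qry, _ = simulate.derive_strain(ref, 0.96, np.random.default_rng(12))
        blocks = chain_and_extend(find_anchors(ref, qry), ref, qry)
        plus = sorted((b for b in blocks if b.strand == "+"), key=lambda b: b.ref_start)
        for a, b in zip(plus, plus[1:]):
            assert a.ref_end <= b.ref_start + 50
            assert a.qry_end <= b.qry_start + 50


class TestAverageIdentity:
    def test_self_comparison(self):
        s = rand_seq(10_000, 13)
        _, ani, cov = compare_genomes(s, s)
        assert ani == 1.0
        assert cov == 1.0

    def test_backbone_identity_recovery(self):
        pop = small_population(14, occupancy="random:0.0", with_crossover=False)
        _, ani, _ = compare_genomes(pop.genomes["P1"], pop.genomes["P2"])
        assert ani == pytest.approx(0.97, abs=0.005)

    def test_identity_ordering_matches_configuration(self):
        pop = small_population(
            15, occupancy="random:0.0", with_crossover=False,
            divergences=(0.015, 0.01, 0.01),
        )
        _, ani_12, _ = compare_genomes(pop.genomes["P1"], pop.genomes["P2"])
        _, ani_23, _ = compare_genomes(pop.genomes["P2"], pop.genomes["P3"])
        assert ani_23 > ani_12
        assert ani_23 == pytest.approx(0.98, abs=0.005)
        assert ani_12 == pytest.approx(0.975, abs=0.005)

    def test_symmetry(self):
        pop = small_population(16, occupancy="random:0.0", with_crossover=False)
        _, ab, _ = compare_genomes(pop.genomes["P1"], pop.genomes["P2"])
        _, ba, _ = compare_genomes(pop.genomes["P2"], pop.genomes["P1"])
        assert ab == pytest.approx(ba, abs=0.002)

    def test_empty_blocks_error(self):
        with pytest.raises(ValueError):
            synteny.average_identity([], 100)

    @pytest.mark.parametrize("target", [0.95, 0.97, 0.99])
    def test_quadratic_oracle_agreement(self, target):
        # seed-chain-extend identity vs full alignment, <= 5 kbp
        ref = rand_seq(4000, 17)
        qry, _ = simulate.derive_strain(
            ref, target, np.random.default_rng(int(target * 1000))
        )
        blocks = chain_and_extend(find_anchors(ref, qry), ref, qry)
        ani, _ = synteny.average_identity(blocks, len(ref))
        assert ani == pytest.approx(oracle_identity(ref, qry), abs=0.005)


class TestBreaks:
    def test_planted_absence_is_cassette_candidate(self):
        pop = small_population(18, occupancy={
            "P1": {"c1": True, "rib": True, "cyb": True},
            "P2": {"c1": False, "rib": True, "cyb": True},
            "P3": {"c1": True, "rib": True, "cyb": True},
        })
        blocks, _, _ = compare_genomes(pop.genomes["P1"], pop.genomes["P2"])
        report = detect_breaks(blocks)
        cassette = report.of_class("cassette-candidate")
        assert len(cassette) >= 1
        iv = pop.cluster_interval("P1", "c1")
        assert any(
            abs(b.ref_gap_start - iv[0]) < 200 and abs(b.ref_gap_end - iv[1]) < 200
            for b in cassette
        )

    def test_no_breaks_on_unperturbed_backbone(self):
        for seed in range(3):
            pop = small_population(100 + seed, occupancy="random:0.0",
                                   with_crossover=False)
            blocks, _, _ = compare_genomes(pop.genomes["P1"], pop.genomes["P2"])
            report = detect_breaks(blocks)
            assert report.breaks == []


class TestMapContigs:
    def test_truth_offsets_recovered(self):
        pop = small_population(19, occupancy="random:1.0")
        simulate.add_fragmentation(pop, n50=4000, n_pairs=100)
        gid = "P2"
        placements = map_contigs(pop.genomes[gid], pop.contigs[gid])
        cmap = pop.contig_maps[gid].set_index("contig")
        eligible = [n for n, s in pop.contigs[gid].items() if len(s) >= 1000]
        good = 0
        for name in eligible:
            p = placements[name]
            if p.status == "placed" and abs(p.ref_start - cmap.loc[name].start) <= 10:
                good += 1
        assert good >= 0.95 * len(eligible)

    def test_pure_repeat_contig_ambiguous(self):
        repeat = rand_seq(2000, 20)
        genome = rand_seq(5000, 21) + repeat + rand_seq(5000, 22) + repeat + rand_seq(5000, 23)
        placements = map_contigs(genome, {"rpt": repeat}, min_len=500)
        assert placements["rpt"].status == "ambiguous"

    def test_unrelated_contig_unplaced(self):
        genome = rand_seq(20_000, 24)
        alien = rand_seq(3000, 25)
        placements = map_contigs(genome, {"alien": alien})
        assert placements["alien"].status == "unplaced"


class TestMateVerification:
    def test_truth_consistent_placements_concordant(self):
        pop = small_population(26, occupancy="random:1.0")
        simulate.add_fragmentation(pop, n50=4000, insert_mean=3000,
                                   insert_sd=300, n_pairs=300)
        gid = "P1"
        placements = map_contigs(pop.genomes[gid], pop.contigs[gid])
        report = verify_order_with_mates(
            placements, pop.mate_links[gid], insert_mean=3000, insert_sd=300
        )
        assert report.n_evaluable > 50
        assert report.concordant_fraction >= 0.99

    def test_swapped_contigs_discordant(self):
        pop = small_population(27, occupancy="random:1.0")
        simulate.add_fragmentation(pop, n50=4000, n_pairs=300)
        gid = "P1"
        placements = map_contigs(pop.genomes[gid], pop.contigs[gid])
        placed = [p for p in placements.values() if p.status == "placed"]
        placed.sort(key=lambda p: p.ref_start)
        a, b = placed[0], placed[-1]
        a.ref_start, b.ref_start = b.ref_start, a.ref_start
        a.ref_end, b.ref_end = b.ref_end, a.ref_end
        report = verify_order_with_mates(
            placements, pop.mate_links[gid], insert_mean=3000, insert_sd=300
        )
        crossing = [
            r for r in pop.mate_links[gid].itertuples()
            if {r.contig_a, r.contig_b} & {a.contig, b.contig}
            and r.contig_a != r.contig_b
        ]
        if crossing:
            assert report.concordant_fraction < 1.0

    def test_no_links_empty_report(self):
        import pandas as pd

        report = verify_order_with_mates(
            {}, pd.DataFrame(columns=["pair", "contig_a", "pos_a", "strand_a",
                                      "contig_b", "pos_b", "strand_b", "span"]),
            3000, 300,
        )
        assert report.n_evaluable == 0
        assert np.isnan(report.concordant_fraction)


def gc_shifted_seq(n, seed, gc=0.7):
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=probs)])


class TestComposition:
    def test_backbone_vs_contaminant_separation(self):
        backbone = rand_seq(50_000, 28)
        contaminant = gc_shifted_seq(50_000, 29)
        refs = {"symbiont": [backbone[:25_000]], "contaminant": [contaminant[:25_000]]}
        contigs = {}
        truth = {}
        rng = np.random.default_rng(30)
        for i in range(20):
            s = int(rng.integers(25_000, 45_000))
            contigs[f"s{i}"] = backbone[s : s + 5000]
            truth[f"s{i}"] = "symbiont"
            contigs[f"c{i}"] = contaminant[s : s + 5000]
            truth[f"c{i}"] = "contaminant"
        result = classify_contigs_by_composition(contigs, refs)
        correct = sum(
            1 for row in result.itertuples() if row.label == truth[row.contig]
        )
        assert correct >= 0.95 * len(contigs)

    def test_centroid_source_identity(self):
        a = rand_seq(20_000, 31)
        b = gc_shifted_seq(20_000, 32)
        result = classify_contigs_by_composition({"x": a}, {"A": [a], "B": [b]})
        assert result.iloc[0].label == "A"
        assert not result.iloc[0].low_confidence

    def test_short_contig_low_confidence(self):
        a = rand_seq(20_000, 33)
        b = gc_shifted_seq(20_000, 34)
        result = classify_contigs_by_composition({"x": a[:500]}, {"A": [a], "B": [b]})
        assert bool(result.iloc[0].low_confidence)
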