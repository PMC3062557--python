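import json

import numpy as np
import pytest

from cassette import seqs, simulate
from cassette.simulate import (
    ClusterTemplate,
    CrossoverTemplate,
    PrecursorTemplate,
    derive_strain,
    fragment_with_mates,
    generate_backbone,
)

from .conftest import oracle_identity, small_population


class TestBackbone:
    def test_determinism(self):
        a = generate_backbone(10000, np.random.default_rng(7))
        b = generate_backbone(10000, np.random.default_rng(7))
        assert a == b

    def test_gc_fraction_binomial_bound(self):
        seq = generate_backbone(1_000_000, np.random.default_rng(0))
        assert seqs.gc_fraction(seq) == pytest.approx(0.5, abs=0.01)

    def test_zero_length_errors(self):
        with pytest.raises(ValueError):
            generate_backbone(0, np.random.default_rng(0))


class TestDeriveStrain:
    def test_substitution_identity_on_100kb(self):
        backbone = generate_backbone(100_000, np.random.default_rng(1))
        strain, _ = derive_strain(backbone, 0.97, np.random.default_rng(2), indel_frac=0.0)
        assert seqs.hamming_identity(backbone, strain) == pytest.approx(0.97, abs=0.002)

    def test_identity_with_indels_alignment_oracle(self):
        backbone = generate_backbone(5000, np.random.default_rng(3))
        strain, _ = derive_strain(backbone, 0.97, np.random.default_rng(4))
        assert oracle_identity(backbone, strain) == pytest.approx(0.97, abs=0.01)

    def test_target_one_is_identity(self):
        backbone = generate_backbone(5000, np.random.default_rng(5))
        strain, posmap = derive_strain(backbone, 1.0, np.random.default_rng(6))
        assert strain == backbone
        assert posmap.events == []

    def test_two_seeds_differ(self):
        backbone = generate_backbone(20_000, np.random.default_rng(7))
        s1, _ = derive_strain(backbone, 0.97, np.random.default_rng(8), indel_frac=0.0)
        s2, _ = derive_strain(backbone, 0.97, np.random.default_rng(9), indel_frac=0.0)
        assert s1 != s2
        for s in (s1, s2):
            assert seqs.hamming_identity(backbone, s) == pytest.approx(0.97, abs=0.002)

    def test_out_of_band_target(self):
        backbone = generate_backbone(1000, np.random.default_rng(0))
        with pytest.raises(ValueError):
            derive_strain(backbone, 0.8, np.random.default_rng(0))

    def test_protected_intervals_untouched(self):
        backbone = generate_backbone(20_000, np.random.default_rng(10))
        protected = [(5000, 6000), (12000, 12500)]
        strain, posmap = derive_strain(
            backbone, 0.95, np.random.default_rng(11), protected=protected
        )
        for start, end in protected:
            out = posmap.forward(start)
            assert strain[out : out + (end - start)] == backbone[start:end]


class TestClusterTemplates:
    def test_slot_inside_gene_enforced(self):
        with pytest.raises(ValueError):
            ClusterTemplate(
                "x", "A" * 1000,
                precursor=PrecursorTemplate(100, 200, [(150, 260)]),
            )

    def test_slot_length_cap(self):
        with pytest.raises(ValueError):
            ClusterTemplate(
                "x", "A" * 1000,
                precursor=PrecursorTemplate(100, 300, [(120, 170)]),
            )

    def test_crossover_strictly_inside(self):
        with pytest.raises(ValueError):
            ClusterTemplate("x", "A" * 1000, crossover=CrossoverTemplate(0, 500))


class TestPopulation:
    def test_seed_reproducibility_byte_identical(self, tmp_path):
        p1 = small_population(3)
        p2 = small_population(3)
        assert p1.genomes == p2.genomes
        d1, d2 = tmp_path / "a", tmp_path / "b"
        p1.write(d1)
        p2.write(d2)
        for f in sorted(d1.iterdir()):
            assert (d2 / f.name).read_bytes() == f.read_bytes()

    def test_truth_coordinates_valid(self):
        pop = small_population(4)
        for row in pop.features.itertuples():
            glen = len(pop.genomes[row.genome])
            assert 0 <= row.start <= row.end <= glen

    def test_occupancy_all_true(self):
        pop = small_population(5, occupancy="random:1.0")
        for gid in pop.config.genome_ids:
            for row in pop.locus_table.itertuples():
                seq = pop.cluster_sequence(gid, row.cluster_id)
                assert seq is not None
                assert abs(len(seq) - row.cluster_len) < 0.1 * row.cluster_len

    def test_shared_cluster_identity_above_99(self):
        pop = small_population(6, occupancy="random:1.0")
        a = pop.cluster_sequence("P1", "c1")
        b = pop.cluster_sequence("P2", "c1")
        assert oracle_identity(a, b) >= 0.99

    def test_unoccupied_locus_flanks_adjoin(self):
        pop = small_population(7, occupancy="random:0.0", with_crossover=False)
        for gid in pop.config.genome_ids:
            junctions = pop.genome_features(gid, "junction")
            assert len(junctions) == len(pop.locus_table)
            for row in junctions.itertuples():
                assert row.start == row.end

    def test_flank_sequences_match_truth(self):
        pop = small_population(8, occupancy="random:1.0")
        for gid in pop.config.genome_ids:
            flanks = pop.genome_features(gid, "locus_flank_left")
            for frow in flanks.itertuples():
                emitted = pop.genomes[gid][frow.start : frow.end]
                expected = pop.locus_table.set_index("locus_id").loc[frow.id].left_flank
                assert emitted == expected  # flanks are mutation-protected


class TestCrossoverAndCores:
    def test_breakpoint_offsets_recorded(self):
        pop = small_population(9)
        cx = pop.features[pop.features.type == "crossover_center"]
        offsets = {
            row.genome: tuple(json.loads(row.attrs)["offsets"])
            for row in cx.itertuples()
        }
        assert offsets == {"P2": (0, 0), "P3": (5, 300)}
        spans = {row.genome: (row.start, row.end) for row in cx.itertuples()}
        # breakpoints differ by the configured scar offsets
        tpl = pop.clusters["cyb"]
        c2 = pop.cluster_interval("P2", "cyb")
        c3 = pop.cluster_interval("P3", "cyb")
        rel2 = (spans["P2"][0] - c2[0], spans["P2"][1] - c2[0])
        rel3 = (spans["P3"][0] - c3[0], spans["P3"][1] - c3[0])
        assert rel3[0] - rel2[0] == 5
        assert rel3[1] - rel2[1] == 300
        assert rel2 == (tpl.crossover.start, tpl.crossover.end)

    def test_center_identity_in_band(self):
        pop = small_population(10)
        tpl = pop.clusters["cyb"]
        c1 = pop.cluster_sequence("P1", "cyb")
        c2 = pop.cluster_sequence("P2", "cyb")
        center1 = c1[tpl.crossover.start : tpl.crossover.end]
        center2 = c2[tpl.crossover.start : tpl.crossover.end]
        ident = seqs.hamming_identity(center1, center2)
        assert 0.25 <= ident <= 0.77

    def test_leaders_identical_cores_differ(self):
        pop = small_population(11, occupancy="random:1.0")
        slots = pop.features[pop.features.type == "cassette_slot"]
        rib = slots[slots.id == "rib_slot0"]
        assert len(rib) == 3
        dnas = {
            row.genome: json.loads(row.attrs)["dna"] for row in rib.itertuples()
        }
        assert len(set(dnas.values())) == 3
        # recognition motifs around every slot are identical across genomes
        for row in rib.itertuples():
            g = pop.genomes[row.genome]
            left = g[row.start - len(simulate.SLOT_LEFT_MOTIF) : row.start]
            right = g[row.end : row.end + len(simulate.SLOT_RIGHT_MOTIF)]
            assert left == simulate.SLOT_LEFT_MOTIF
            assert right == simulate.SLOT_RIGHT_MOTIF

    def test_24bp_cassette_at_46_percent(self):
        # plant two 24-bp cassettes that agree at exactly 11 positions
        # and check the generator carries them through verbatim
        a = "ATTACAGTGTGTATCTCAGTGTGC"
        flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
        b = "".join(flip[ch] if i < 13 else ch for i, ch in enumerate(a))
        same = sum(x == y for x, y in zip(a, b))
        assert same == 11
        assert round(same / 24, 2) == 0.46
        pop = small_population(
            30,
            occupancy="random:1.0",
            cores={
                "P1": {"cyb": ["TSIAPF"], "rib": [a]},
                "P2": {"cyb": ["TTVTAC"], "rib": [b]},
                "P3": {"cyb": ["TLSPFC"], "rib": [b]},
            },
        )
        s1 = pop.genome_features("P1", "cassette_slot")
        s2 = pop.genome_features("P2", "cassette_slot")
        r1 = s1[s1.id == "rib_slot0"].iloc[0]
        r2 = s2[s2.id == "rib_slot0"].iloc[0]
        dna1 = pop.genomes["P1"][r1.start : r1.end]
        dna2 = pop.genomes["P2"][r2.start : r2.end]
        assert dna1 == a and dna2 == b
        assert seqs.hamming_identity(dna1, dna2) == pytest.approx(11 / 24)

    def test_core_dna_translates_to_requested_peptide(self):
        pop = small_population(12)
        slots = pop.features[pop.features.type == "cassette_slot"]
        for row in slots.itertuples():
            attrs = json.loads(row.attrs)
            if set(attrs["core"]) <= set("ACGT") and len(attrs["core"]) == row.end - row.start:
                continue  # literal DNA core
            assert seqs.translate_dna(attrs["dna"]) == attrs["core"]


class TestRepeats:
    def test_repeat_confounded_flank_multicopy(self):
        pop = small_population(13, repeat_confounded=True)
        row = pop.locus_table.set_index("locus_id").loc["L1"]
        assert row.repeat_confounded
        g = pop.genomes["P1"]
        assert g.count(row.left_flank) > 1


class TestFragmentation:
    def test_length_conservation(self):
        genome = generate_backbone(60_000, np.random.default_rng(20))
        contigs, cmap, _ = fragment_with_mates(
            genome, 5000, np.random.default_rng(21), genome_id="G"
        )
        assert sum(len(s) for s in contigs.values()) == len(genome)
        rebuilt = "".join(contigs[r.contig] for r in cmap.itertuples())
        assert rebuilt == genome

    def test_n50_within_20_percent(self):
        rng = np.random.default_rng(22)
        n50s = []
        for _ in range(8):
            genome = generate_backbone(80_000, rng)
            _, cmap, _ = fragment_with_mates(genome, 6000, rng)
            n50s.append(simulate.contig_n50(cmap.length))
        assert np.mean(n50s) == pytest.approx(6000, rel=0.2)

    def test_mate_span_mean(self):
        genome = generate_backbone(60_000, np.random.default_rng(23))
        _, _, links = fragment_with_mates(
            genome, 5000, np.random.default_rng(24),
            insert_mean=3000, insert_sd=300, n_pairs=400,
        )
        se = 300 / np.sqrt(len(links))
        assert links.span.mean() == pytest.approx(3000, abs=2 * se + 1)

    def test_n50_minimum(self):
        with pytest.raises(ValueError):
            fragment_with_mates("ACGT" * 1000, 500, np.random.default_rng(0))


class TestConfigValidation:
    def test_loci_too_close(self):
        rng = np.random.default_rng(0)
        clusters = {"c": simulate.make_cluster_template(rng, "c", 1500)}
        cfg = simulate.PopulationConfig(
            backbone_length=10000,
            loci=[
                simulate.LocusConfig("L1", 4000, "c"),
                simulate.LocusConfig("L2", 4300, "c"),
            ],
        )
        with pytest.raises(ValueError):
            cfg.validate(clusters)

    def test_identity_band(self):
        cfg = simulate.PopulationConfig(pairwise_identity=0.85)
        with pytest.raises(ValueError):
            cfg.validate({})
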