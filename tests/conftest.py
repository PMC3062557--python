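"""Shared fixtures: demo population and an independent alignment oracle."""

from __future__ import annotations

import numpy as np
import pytest
from Bio import Align

from cassette import simulate


def oracle_identity(a: str, b: str) -> float:
    """Quadratic global-alignment identity, independent of the package's
    seed-chain-extend path (uses Biopython's alignment counts)."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    return counts.identities / aln.length


@pytest.fixture(scope="session")
def demo_pop():
    return simulate.demo_population(seed=1)


def small_clusters(rng: np.random.Generator) -> dict[str, simulate.ClusterTemplate]:
    """Compact cluster library for fast multi-seed runs."""
    return {
        "c1": simulate.make_cluster_template(rng, "c1", 2400, kind="nrps"),
        "rib": simulate.make_cluster_template(rng, "rib", 1800, kind="ribosomal",
                                              n_slots=1, core_len_aa=8),
        "cyb": simulate.make_cluster_template(
            rng, "cyb", 3000, kind="cyanobactin",
            n_slots=1, core_len_aa=6,
            crossover_frac=(0.35, 0.65), crossover_identity=0.5,
        ),
    }


def small_population(seed: int, occupancy="random:0.5", with_crossover=True,
                     repeat_confounded=False, cores=None, **cfg_kw) -> simulate.Population:
    rng = np.random.default_rng(seed + 31_337)
    clusters = small_clusters(rng)
    if cores is None:
        cores = {
            "P1": {"cyb": ["TSIAPF"], "rib": ["ITVCISVC"]},
            "P2": {"cyb": ["TTVTAC"], "rib": ["ITACITFC"]},
            "P3": {"cyb": ["TLSPFC"], "rib": ["TVCGSYLC"]},
        }
    config = simulate.PopulationConfig(
        backbone_length=18000,
        genome_ids=("P1", "P2", "P3"),
        loci=[
            simulate.LocusConfig("L1", 4000, "c1", repeat_confounded=repeat_confounded),
            simulate.LocusConfig("L2", 9000, "rib"),
            simulate.LocusConfig("L3", 14000, "cyb"),
        ],
        occupancy=occupancy,
        crossover_variants={"P2": (0, 0), "P3": (5, 300)} if with_crossover else {},
        cores=cores,
        seed=seed,
        **cfg_kw,
    )
    return simulate.generate_population(config, clusters)
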