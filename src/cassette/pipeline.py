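"""End-to-end orchestration: generate -> compare -> call -> genotype ->
predict chemistry, with a reproducible run manifest."""

from __future__ import annotations

import hashlib
import itertools
import json
import sys
import time
from pathlib import Path

import pandas as pd

from . import __version__, chem, pcr, seqs, simulate, synteny, variation

LEADER_MODEL = {
    "left": simulate.SLOT_LEFT_MOTIF,
    "right": simulate.SLOT_RIGHT_MOTIF,
    "max_core": 30,
}


def _config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def build_population(config: dict, seed: int) -> simulate.Population:
    pop_cfg = config.get("population", {})
    fragment = bool(pop_cfg.get("fragment", False))
    if pop_cfg.get("preset") == "empty":
        # no pathways: pure backbone population
        cfg = simulate.PopulationConfig(
            backbone_length=int(pop_cfg.get("backbone_length", 20000)),
            loci=[], seed=seed,
        )
        pop = simulate.generate_population(cfg, {})
        if fragment:
            simulate.add_fragmentation(pop, n50=5000)
        return pop
    pop = simulate.demo_population(seed=seed, fragment=fragment)
    return pop


def stage_synteny(pop: simulate.Population, outdir: Path) -> pd.DataFrame:
    rows = []
    for a, b in itertools.combinations(pop.config.genome_ids, 2):
        blocks, ani, cov = synteny.compare_genomes(pop.genomes[a], pop.genomes[b])
        synteny.blocks_to_frame(blocks).to_csv(
            outdir / f"blocks_{a}_{b}.tsv", sep="\t", index=False
        )
        report = synteny.detect_breaks(blocks)
        pd.DataFrame(
            [
                dict(ref_gap_start=x.ref_gap_start, ref_gap_end=x.ref_gap_end,
                     qry_gap_start=x.qry_gap_start, qry_gap_end=x.qry_gap_end,
                     classification=x.classification)
                for x in report.breaks
            ],
            columns=["ref_gap_start", "ref_gap_end", "qry_gap_start",
                     "qry_gap_end", "classification"],
        ).to_csv(outdir / f"breaks_{a}_{b}.tsv", sep="\t", index=False)
        rows.append(dict(ref=a, qry=b, ani=round(ani, 5), coverage=round(cov, 4),
                         n_blocks=len(blocks)))
    summary = pd.DataFrame(rows, columns=["ref", "qry", "ani", "coverage", "n_blocks"])
    summary.to_csv(outdir / "identity_summary.tsv", sep="\t", index=False)
    return summary


def stage_variation(pop: simulate.Population, outdir: Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    loci = variation.loci_from_table(pop.locus_table)
    locus_calls: dict[tuple[str, str], variation.LocusCall] = {}
    all_calls = []
    ref_clusters = {
        locus.cluster_id: pop.clusters[locus.cluster_id].sequence for locus in loci
    }
    for gid in pop.config.genome_ids:
        locations = variation.locate_loci(pop.genomes[gid], loci)
        for locus in loci:
            call = variation.call_occupancy(
                pop.genomes[gid], gid, locus,
                locations[locus.id], ref_clusters[locus.cluster_id],
            )
            locus_calls[(gid, locus.id)] = call
            all_calls.append(call)
    var_calls = []
    for locus in loci:
        cid = locus.cluster_id
        tpl = pop.clusters[cid]
        slot_intervals = tpl.precursor.slots if tpl.precursor else None
        for a, b in itertools.combinations(pop.config.genome_ids, 2):
            ca = locus_calls[(a, locus.id)]
            cb = locus_calls[(b, locus.id)]
            profile = cores_a = cores_b = None
            if ca.state == cb.state == "present":
                seq_a = pop.cluster_sequence(a, cid)
                seq_b = pop.cluster_sequence(b, cid)
                profile = variation.crossover_profile(seq_a, seq_b)
                if tpl.precursor:
                    cores_a = variation.extract_cores(seq_a, LEADER_MODEL)
                    cores_b = variation.extract_cores(seq_b, LEADER_MODEL)
            var_calls.extend(
                variation.classify_variation(
                    cid, ca, cb, profile, cores_a, cores_b, slot_intervals
                )
            )
            if profile is not None:
                profile.windows.to_csv(
                    outdir / f"profile_{cid}_{a}_{b}.tsv", sep="\t", index=False
                )
    lframe = variation.locus_calls_frame(all_calls)
    vframe = variation.variation_calls_frame(var_calls)
    lframe.to_csv(outdir / "locus_calls.tsv", sep="\t", index=False)
    vframe.to_csv(outdir / "variation_calls.tsv", sep="\t", index=False)
    return lframe, vframe


def stage_pcr(pop: simulate.Population, outdir: Path, config: dict) -> dict:
    pcr_cfg = config.get("pcr", {})
    max_product = int(pcr_cfg.get("max_product", 2000))
    n_perm = int(pcr_cfg.get("n_perm", 500))
    assays: dict[str, pcr.AssayPair] = {}
    for row in pop.locus_table.itertuples():
        cid = row.cluster_id
        carriers = [g for g in pop.config.genome_ids if pop.occupancy.loc[g, cid]]
        cluster_seq = (
            pop.cluster_sequence(carriers[0], cid)
            if carriers
            else pop.clusters[cid].sequence
        )
        assays[cid] = pcr.design_assays(
            cid, cluster_seq, row.left_flank, row.right_flank,
            pop.genomes, max_product=max_product,
            avoid=pop.clusters[cid].hypervariable_intervals(),
        )
    matrix = pcr.screen_genomes(pop.genomes, assays)
    matrix.cells.to_csv(outdir / "genotype_matrix.tsv", sep="\t")
    assay_rows = []
    for cid, pair in assays.items():
        for mode, assay, flag in (
            ("presence-internal", pair.presence, pair.presence_flag),
            ("absence-spanning", pair.absence, pair.absence_flag),
        ):
            assay_rows.append(
                dict(pathway=cid, mode=mode,
                     forward=assay.forward if assay else "",
                     reverse=assay.reverse if assay else "",
                     max_product=assay.max_product if assay else "",
                     flag=flag)
            )
    pd.DataFrame(assay_rows).to_csv(outdir / "assays.tsv", sep="\t", index=False)
    summary: dict = {
        "recovery_vs_truth": matrix.recovery(pop.occupancy),
        "prevalence": {k: (None if pd.isna(v) else round(float(v), 3))
                       for k, v in matrix.prevalence().items()},
    }
    if matrix.cells.shape[1] >= 2:
        assoc = pcr.cooccurrence_test(matrix.cells, n_perm=n_perm, seed=pop.config.seed)
        assoc.to_csv(outdir / "cooccurrence.tsv", sep="\t", index=False)
        summary["n_association_pairs"] = int(len(assoc))
    return summary


def report_chem(
    core_table: list[dict],
    observed_peaks: list[dict],
    tol_ppm: float = 5.0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Candidate products, best peak matches and fragment ladders.

    ``core_table`` rows: {id, core, class}; ``observed_peaks`` rows:
    {id, mz}. Returns (products, matches, ladders) frames with m/z to 5
    decimals and ppm to 1 decimal, the usual reporting precision.
    """
    products = []
    ladders = []
    candidates: list[tuple[str, chem.CyanobactinProduct]] = []
    for row in core_table:
        for cand in chem.enumerate_candidates(row["core"], row["class"]):
            candidates.append((row["id"], cand))
            products.append(
                dict(core_id=row["id"], core=cand.core, spec=cand.spec.describe(),
                     formula=cand.formula.hill(),
                     mz_mh=round(cand.mz_mh, 5))
            )
            for k, formula, mz in chem.isoprene_ladder(cand).steps:
                ladders.append(
                    dict(core_id=row["id"], spec=cand.spec.describe(),
                         isoprenes_lost=k, formula=formula.hill(),
                         mz_mh=round(mz, 5))
                )
    matches = []
    for peak in observed_peaks:
        best = None
        for core_id, cand in candidates:
            ppm = chem.ppm_error(peak["mz"], cand.mz_mh)
            if abs(ppm) <= tol_ppm and (best is None or abs(ppm) < abs(best[2])):
                best = (core_id, cand, ppm)
        if best:
            core_id, cand, ppm = best
            matches.append(
                dict(peak_id=peak["id"], observed_mz=peak["mz"], core_id=core_id,
                     spec=cand.spec.describe(), formula=cand.formula.hill(),
                     predicted_mz=round(cand.mz_mh, 5), ppm=round(ppm, 1),
                     matched=True)
            )
        else:
            matches.append(
                dict(peak_id=peak["id"], observed_mz=peak["mz"], core_id="",
                     spec="", formula="", predicted_mz="", ppm="", matched=False)
            )
    cols_p = ["core_id", "core", "spec", "formula", "mz_mh"]
    cols_m = ["peak_id", "observed_mz", "core_id", "spec", "formula",
              "predicted_mz", "ppm", "matched"]
    cols_l = ["core_id", "spec", "isoprenes_lost", "formula", "mz_mh"]
    return (
        pd.DataFrame(products, columns=cols_p),
        pd.DataFrame(matches, columns=cols_m),
        pd.DataFrame(ladders, columns=cols_l),
    )


def stage_chem(pop: simulate.Population, outdir: Path, config: dict) -> dict:
    chem_cfg = config.get("chem", {})
    core_table = list(chem_cfg.get("cores", []))
    # cores recovered from the genomes themselves (cyanobactin precursors)
    for gid in pop.config.genome_ids:
        for row in pop.locus_table.itertuples():
            tpl = pop.clusters[row.cluster_id]
            if tpl.kind != "cyanobactin" or not tpl.precursor:
                continue
            cseq = pop.cluster_sequence(gid, row.cluster_id)
            if cseq is None:
                continue
            for i, core in enumerate(variation.extract_cores(cseq, LEADER_MODEL)):
                if core.peptide and "*" not in core.peptide:
                    core_table.append(
                        dict(id=f"{gid}:{row.cluster_id}:{i}",
                             core=core.peptide, **{"class": "tru"})
                    )
    observed = list(chem_cfg.get("observed", []))
    products, matches, ladders = report_chem(core_table, observed)
    products.to_csv(outdir / "chem_products.tsv", sep="\t", index=False)
    matches.to_csv(outdir / "chem_matches.tsv", sep="\t", index=False)
    ladders.to_csv(outdir / "chem_ladders.tsv", sep="\t", index=False)
    return {"n_cores": len(core_table), "n_products": int(len(products)),
            "n_matched_peaks": int(matches["matched"].sum()) if len(matches) else 0}


def run_all(config: dict, outdir: str | Path) -> dict:
    """Run every stage; returns the manifest (also written to disk)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    timings: dict[str, float] = {}
    summary: dict = {}

    t0 = time.perf_counter()
    pop = build_population(config, seed)
    pop.write(outdir / "population")
    timings["generate"] = round(time.perf_counter() - t0, 3)

    t0 = time.perf_counter()
    identity = stage_synteny(pop, outdir)
    summary["identity"] = identity.to_dict(orient="records")
    timings["synteny"] = round(time.perf_counter() - t0, 3)

    t0 = time.perf_counter()
    lframe, vframe = stage_variation(pop, outdir)
    summary["locus_calls"] = int(len(lframe))
    summary["variation_levels"] = sorted(vframe["level"].unique().tolist()) if len(vframe) else []
    timings["variation"] = round(time.perf_counter() - t0, 3)

    t0 = time.perf_counter()
    summary["pcr"] = stage_pcr(pop, outdir, config)
    timings["pcr"] = round(time.perf_counter() - t0, 3)

    t0 = time.perf_counter()
    summary["chem"] = stage_chem(pop, outdir, config)
    timings["chem"] = round(time.perf_counter() - t0, 3)

    for stage, dt in timings.items():
        print(f"[{stage}] {dt:.3f}s", file=sys.stderr)
    # timings stay out of the manifest so equal-seed runs are byte-identical
    manifest = {
        "config_hash": _config_hash(config),
        "seed": seed,
        "version": __version__,
        "summary": summary,
        "files": sorted(
            str(p.relative_to(outdir)) for p in outdir.rglob("*") if p.is_file()
        ),
    }
    (outdir / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str)
    )
    return manifest
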