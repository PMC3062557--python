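"""Clonal symbiont-genome population generator with ground truth.

Emulates the statistical structure the downstream analyses assume:

- a shared backbone at configurable pairwise identity (default 0.97),
  with conserved (mutation-protected) genes flanking each integration
  locus;
- secondary-metabolite clusters that are >99% identical when shared and
  inserted/absent at identical backbone loci;
- an optional diverged central "crossover" region inside one cluster
  pair, with per-genome breakpoint offsets (scars);
- short hypervariable core cassettes inside otherwise identical
  precursor genes;
- near-identical repeat elements that can confound a locus;
- gap-free contig fragmentation with mate-pair links.

Coordinates are 0-based half-open; all planted features are on the
forward strand. One numpy RNG stream per run; regeneration with the
same seed is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from . import seqs

DNA = np.array(list("ACGT"))

_CODON_CHOICES: dict[str, list[str]] = {}
for codon, aa in CodonTable.unambiguous_dna_by_id[11].forward_table.items():
    _CODON_CHOICES.setdefault(aa, []).append(codon)
for _aa in _CODON_CHOICES:
    _CODON_CHOICES[_aa].sort()

#: Conserved DNA recognition motifs flanking every core cassette slot
#: (in frame, 24 bp each); the leader-model analogue used downstream.
SLOT_LEFT_MOTIF = "GGTGTTGAAGCTTCTGTTACTGCT"
SLOT_RIGHT_MOTIF = "GCTTACGATGGTGTTGAACCTTCT"


# ---------------------------------------------------------------------------
# low-level sequence edits


def generate_backbone(length: int, rng: np.random.Generator) -> str:
    """Uniform-composition random ancestral sequence."""
    return seqs.random_seq(rng, length)


def reverse_translate(aa_seq: str, rng: np.random.Generator) -> str:
    out = []
    for aa in aa_seq:
        choices = _CODON_CHOICES[aa.upper()]
        out.append(choices[rng.integers(0, len(choices))])
    return "".join(out)


def _allowed_positions(length: int, protected) -> np.ndarray:
    mask = np.ones(length, dtype=bool)
    for start, end in protected:
        mask[max(0, start) : min(length, end)] = False
    return np.flatnonzero(mask)


def mutate_substitutions(
    seq: str,
    n_sub: int,
    rng: np.random.Generator,
    protected=(),
) -> tuple[str, np.ndarray]:
    """Substitute exactly ``n_sub`` distinct unprotected positions."""
    allowed = _allowed_positions(len(seq), protected)
    n_sub = min(n_sub, allowed.size)
    pos = rng.choice(allowed, size=n_sub, replace=False)
    arr = np.array(list(seq))
    for p in pos:
        alt = [b for b in "ACGT" if b != arr[p]]
        arr[p] = alt[rng.integers(0, 3)]
    return "".join(arr), np.sort(pos)


@dataclass
class PosMap:
    """Maps coordinates on an original sequence to its edited version."""

    # sorted (orig_pos, shift_delta): after orig_pos the cumulative shift
    # changes by delta (insertion +len, deletion -len)
    events: list[tuple[int, int]] = field(default_factory=list)

    def forward(self, pos: int) -> int:
        shift = 0
        for p, d in self.events:
            if p <= pos:
                shift += d
            else:
                break
        return pos + shift


def derive_strain(
    backbone: str,
    identity_target: float,
    rng: np.random.Generator,
    protected=(),
    indel_frac: float = 0.05,
) -> tuple[str, PosMap]:
    """Mutate a backbone copy down to ``identity_target``.

    95% of the mutated-base budget goes to substitutions, the rest to
    small indels with geometric lengths. Protected intervals (locus
    flanks) are never touched.
    """
    if not 0.9 < identity_target <= 1.0:
        raise ValueError("identity_target must lie in (0.9, 1.0]")
    length = len(backbone)
    budget = int(round(length * (1.0 - identity_target)))
    if budget == 0:
        return backbone, PosMap()
    n_sub = int(round(budget * (1.0 - indel_frac)))
    indel_budget = budget - n_sub
    mutated, _ = mutate_substitutions(backbone, n_sub, rng, protected)

    # indel events; each is (pos, +len insertion) or (pos, -len deletion)
    events: list[tuple[int, int, str]] = []
    allowed = set(_allowed_positions(length, protected).tolist())
    spent = 0
    attempts = 0
    while spent < indel_budget and attempts < 1000:
        attempts += 1
        ilen = int(rng.geometric(0.5))
        pos = int(rng.integers(0, length))
        if rng.random() < 0.5:  # insertion
            if pos not in allowed:
                continue
            ins = seqs.random_seq(rng, ilen)
            events.append((pos, ilen, ins))
        else:  # deletion
            if not all(p in allowed for p in range(pos, min(pos + ilen, length))):
                continue
            events.append((pos, -ilen, ""))
        spent += ilen
    events.sort(key=lambda e: e[0])

    out = []
    cursor = 0
    posmap = PosMap()
    shift = 0
    for pos, delta, payload in events:
        if pos < cursor:
            continue
        out.append(mutated[cursor:pos])
        if delta > 0:
            out.append(payload)
            cursor = pos
        else:
            cursor = min(pos - delta, length)
            delta = -(cursor - pos)
            if delta == 0:
                continue
        shift += delta
        posmap.events.append((pos, delta))
    out.append(mutated[cursor:])
    return "".join(out), posmap


# ---------------------------------------------------------------------------
# cluster templates


@dataclass
class PrecursorTemplate:
    gene_start: int
    gene_end: int
    slots: list[tuple[int, int]]  # cassette slot intervals, cluster coords


@dataclass
class CrossoverTemplate:
    start: int  # central region, cluster coords
    end: int
    identity: float = 0.5  # divergence target of the alternative center


@dataclass
class ClusterTemplate:
    id: str
    sequence: str
    kind: str = "nrps"
    precursor: PrecursorTemplate | None = None
    crossover: CrossoverTemplate | None = None

    def __post_init__(self):
        if self.precursor:
            for s, e in self.precursor.slots:
                if not (
                    self.precursor.gene_start <= s < e <= self.precursor.gene_end
                ):
                    raise ValueError("cassette slot outside precursor gene")
                if e - s > 30:
                    raise ValueError("cassette slot exceeds 30 bp")
        if self.crossover:
            if not 0 < self.crossover.start < self.crossover.end < len(self.sequence):
                raise ValueError("crossover interval must lie strictly inside cluster")

    def hypervariable_intervals(self, margin: int = 400) -> list[tuple[int, int]]:
        """Regions that vary between genomes (unfit for primer design)."""
        out: list[tuple[int, int]] = []
        if self.precursor:
            for s, e in self.precursor.slots:
                out.append((s - len(SLOT_LEFT_MOTIF), e + len(SLOT_RIGHT_MOTIF)))
        if self.crossover:
            out.append((self.crossover.start - margin, self.crossover.end + margin))
        return out


def make_cluster_template(
    rng: np.random.Generator,
    cluster_id: str,
    length: int,
    kind: str = "nrps",
    n_slots: int = 0,
    core_len_aa: int = 6,
    crossover_frac: tuple[float, float] | None = None,
    crossover_identity: float = 0.5,
) -> ClusterTemplate:
    """Random cluster sequence, optionally with precursor slots and a
    designated crossover center."""
    sequence = seqs.random_seq(rng, length)
    precursor = None
    if n_slots:
        slot_len = 3 * core_len_aa
        unit = len(SLOT_LEFT_MOTIF) + slot_len + len(SLOT_RIGHT_MOTIF)
        gene_start = 60
        gene_len = 90 + n_slots * (unit + 30)
        gene_end = gene_start + gene_len
        if gene_end >= length:
            raise ValueError("cluster too short for requested precursor")
        parts = [sequence[:gene_start]]
        cursor = gene_start
        slots = []
        parts.append(seqs.random_seq(rng, 90))  # leader-coding region
        cursor += 90
        for _ in range(n_slots):
            parts.append(SLOT_LEFT_MOTIF)
            cursor += len(SLOT_LEFT_MOTIF)
            slots.append((cursor, cursor + slot_len))
            parts.append(seqs.random_seq(rng, slot_len))
            cursor += slot_len
            parts.append(SLOT_RIGHT_MOTIF)
            cursor += len(SLOT_RIGHT_MOTIF)
            parts.append(seqs.random_seq(rng, 30))
            cursor += 30
        parts.append(sequence[cursor:])
        sequence = "".join(parts)
        precursor = PrecursorTemplate(gene_start, gene_end, slots)
    crossover = None
    if crossover_frac:
        start = int(length * crossover_frac[0])
        end = int(length * crossover_frac[1])
        if precursor and start < precursor.gene_end:
            start = precursor.gene_end + 30
        crossover = CrossoverTemplate(start, end, crossover_identity)
    return ClusterTemplate(cluster_id, sequence, kind, precursor, crossover)


def make_alt_center(
    template: ClusterTemplate,
    rng: np.random.Generator,
    margin: int = 400,
) -> tuple[str, int]:
    """Diverged alternative for the crossover center plus margins.

    Returns (sequence, origin) where origin is the cluster coordinate
    of the first base. Divergence is substitution-only so alignment
    columns stay in register for breakpoint localization.
    """
    cx = template.crossover
    if cx is None:
        raise ValueError("template has no crossover region")
    start = max(0, cx.start - margin)
    end = min(len(template.sequence), cx.end + margin)
    src = template.sequence[start:end]
    n_sub = int(round(len(src) * (1.0 - cx.identity)))
    alt, _ = mutate_substitutions(src, n_sub, rng)
    return alt, start


def build_cluster_copy(
    template: ClusterTemplate,
    rng: np.random.Generator,
    cores: list[str] | None = None,
    crossover_offsets: tuple[int, int] | None = None,
    alt_center: tuple[str, int] | None = None,
    mutation_rate: float = 0.003,
) -> tuple[str, dict]:
    """One genome's copy of a cluster.

    ``cores``: per-slot replacement content — amino-acid strings
    (reverse-translated) or literal DNA of exactly the slot length.
    ``crossover_offsets``: (d5, d3) breakpoint shifts for a variant
    genome whose center is replaced from ``alt_center``.
    Background substitutions at ``mutation_rate`` keep shared copies
    >99% identical; slots and their recognition motifs are protected.
    """
    arr = list(template.sequence)
    info: dict = {"slots": [], "crossover": None}
    if template.precursor and cores:
        if len(cores) != len(template.precursor.slots):
            raise ValueError("need one core per cassette slot")
        for (s, e), core in zip(template.precursor.slots, cores):
            if set(core.upper()) <= set("ACGT") and len(core) == e - s:
                dna = core.upper()
            else:
                dna = reverse_translate(core, rng)
            if len(dna) != e - s:
                raise ValueError(f"core {core!r} does not fit slot of {e - s} bp")
            arr[s:e] = list(dna)
            info["slots"].append({"interval": (s, e), "core": core, "dna": dna})
    if crossover_offsets is not None:
        if alt_center is None or template.crossover is None:
            raise ValueError("crossover replacement needs alt_center and template.crossover")
        d5, d3 = crossover_offsets
        alt_seq, origin = alt_center
        b5 = template.crossover.start + d5
        b3 = template.crossover.end + d3
        if not origin <= b5 < b3 <= origin + len(alt_seq):
            raise ValueError("crossover offsets exceed alt_center margins")
        arr[b5:b3] = list(alt_seq[b5 - origin : b3 - origin])
        info["crossover"] = {"break5": b5, "break3": b3, "offsets": (d5, d3)}
    protected = []
    if template.precursor:
        for s, e in template.precursor.slots:
            protected.append((s - len(SLOT_LEFT_MOTIF), e + len(SLOT_RIGHT_MOTIF)))
    seq = "".join(arr)
    n_sub = int(round(len(seq) * mutation_rate))
    seq, sub_pos = mutate_substitutions(seq, n_sub, rng, protected)
    info["n_substitutions"] = int(len(sub_pos))
    return seq, info


# ---------------------------------------------------------------------------
# population config


@dataclass
class LocusConfig:
    id: str
    backbone_pos: int
    cluster_id: str
    repeat_confounded: bool = False


@dataclass
class PopulationConfig:
    """Everything needed to regenerate a population deterministically."""

    backbone_length: int = 40000
    genome_ids: tuple[str, ...] = ("P1", "P2", "P3")
    # per-genome divergence from the ancestor; pairwise identity between
    # genomes i,j is approximately 1 - (d_i + d_j)
    divergences: tuple[float, ...] | None = None
    pairwise_identity: float = 0.97
    loci: list[LocusConfig] = field(default_factory=list)
    occupancy: dict[str, dict[str, bool]] | str = "random:0.5"
    flank_len: int = 300
    cluster_mut_rate: float = 0.003
    repeat_flank_prob: float = 0.0
    repeat_length: int = 500
    indel_frac: float = 0.05
    # genome_id -> (d5, d3) crossover breakpoint offsets (variant genomes)
    crossover_variants: dict[str, tuple[int, int]] = field(default_factory=dict)
    # genome_id -> cluster_id -> list of per-slot cores (AA or DNA)
    cores: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    seed: int = 0

    def validate(self, clusters: dict[str, ClusterTemplate]) -> None:
        if not 0.9 < self.pairwise_identity <= 1.0:
            raise ValueError("pairwise_identity must lie in (0.9, 1.0]")
        pos = sorted(l.backbone_pos for l in self.loci)
        for a, b in zip(pos, pos[1:]):
            if b - a < 2 * self.flank_len:
                raise ValueError("loci closer than two flank lengths")
        for l in self.loci:
            if not self.flank_len <= l.backbone_pos <= self.backbone_length - self.flank_len:
                raise ValueError(f"locus {l.id} too close to a backbone end")
            if l.cluster_id not in clusters:
                raise ValueError(f"locus {l.id} references unknown cluster {l.cluster_id}")

    def genome_divergences(self) -> dict[str, float]:
        if self.divergences is not None:
            return dict(zip(self.genome_ids, self.divergences))
        d = (1.0 - self.pairwise_identity) / 2.0
        return {g: d for g in self.genome_ids}


# ---------------------------------------------------------------------------
# population


@dataclass
class Population:
    config: PopulationConfig
    clusters: dict[str, ClusterTemplate]
    backbone: str
    genomes: dict[str, str]
    occupancy: pd.DataFrame  # genomes x cluster ids (bool)
    features: pd.DataFrame  # genome, type, id, start, end, attrs(json)
    locus_table: pd.DataFrame
    contigs: dict[str, dict[str, str]] = field(default_factory=dict)
    contig_maps: dict[str, pd.DataFrame] = field(default_factory=dict)
    mate_links: dict[str, pd.DataFrame] = field(default_factory=dict)

    def genome_features(self, genome_id: str, ftype: str | None = None) -> pd.DataFrame:
        df = self.features[self.features.genome == genome_id]
        if ftype:
            df = df[df.type == ftype]
        return df.reset_index(drop=True)

    def cluster_interval(self, genome_id: str, cluster_id: str) -> tuple[int, int] | None:
        df = self.genome_features(genome_id, "cluster")
        df = df[df.id == cluster_id]
        if df.empty:
            return None
        row = df.iloc[0]
        return int(row.start), int(row.end)

    def cluster_sequence(self, genome_id: str, cluster_id: str) -> str | None:
        iv = self.cluster_interval(genome_id, cluster_id)
        if iv is None:
            return None
        return self.genomes[genome_id][iv[0] : iv[1]]

    def write(self, outdir: str | Path) -> dict:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        inventory = {}
        for gid, seq in self.genomes.items():
            p = outdir / f"{gid}.fasta"
            seqs.write_fasta(p, [(gid, seq)])
            inventory[f"genome:{gid}"] = p.name
        feat = self.features.copy()
        feat.to_csv(outdir / "features.tsv", sep="\t", index=False)
        self.occupancy.to_csv(outdir / "occupancy.tsv", sep="\t")
        self.locus_table.to_csv(outdir / "loci.tsv", sep="\t", index=False)
        for gid, cmap in self.contig_maps.items():
            cmap.to_csv(outdir / f"{gid}.contigs.tsv", sep="\t", index=False)
            seqs.write_fasta(
                outdir / f"{gid}.contigs.fasta",
                [(row.contig, self.contigs[gid][row.contig]) for row in cmap.itertuples()],
            )
        for gid, links in self.mate_links.items():
            links.to_csv(outdir / f"{gid}.mates.tsv", sep="\t", index=False)
        manifest = {
            "seed": self.config.seed,
            "genome_ids": list(self.config.genome_ids),
            "backbone_length": self.config.backbone_length,
            "files": sorted(p.name for p in outdir.iterdir()),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        inventory["manifest"] = "manifest.json"
        return manifest


def _resolve_occupancy(
    config: PopulationConfig, clusters: dict[str, ClusterTemplate], rng
) -> pd.DataFrame:
    cluster_ids = [l.cluster_id for l in config.loci]
    if isinstance(config.occupancy, str):
        if not config.occupancy.startswith("random:"):
            raise ValueError(f"bad occupancy spec {config.occupancy!r}")
        p = float(config.occupancy.split(":", 1)[1])
        data = rng.random((len(config.genome_ids), len(cluster_ids))) < p
        occ = pd.DataFrame(data, index=list(config.genome_ids), columns=cluster_ids)
    else:
        occ = pd.DataFrame(config.occupancy).T.reindex(
            index=list(config.genome_ids), columns=cluster_ids
        )
        if occ.isna().any().any():
            raise ValueError("occupancy matrix incomplete")
        occ = occ.astype(bool)
    # crossover-variant genomes must carry the crossover cluster
    for gid in config.crossover_variants:
        for l in config.loci:
            if clusters[l.cluster_id].crossover is not None:
                occ.loc[gid, l.cluster_id] = True
    return occ


def generate_population(
    config: PopulationConfig, clusters: dict[str, ClusterTemplate]
) -> Population:
    """Run the whole generator; single RNG stream, fully deterministic."""
    config.validate(clusters)
    rng = np.random.default_rng(config.seed)
    backbone = generate_backbone(config.backbone_length, rng)

    # plant repeat elements into the flanks of repeat-confounded loci and
    # at decoy positions elsewhere
    repeat_elem = seqs.random_seq(rng, config.repeat_length)
    arr = list(backbone)
    repeat_intervals: list[tuple[int, int]] = []
    confounded = [l for l in config.loci if l.repeat_confounded]
    if confounded:
        for l in confounded:
            for start in (l.backbone_pos - config.repeat_length, l.backbone_pos):
                arr[start : start + config.repeat_length] = list(repeat_elem)
                repeat_intervals.append((start, start + config.repeat_length))
        # decoy copies away from all loci
        locus_pos = [l.backbone_pos for l in config.loci]
        planted = 0
        while planted < 2:
            start = int(rng.integers(0, config.backbone_length - config.repeat_length))
            if all(
                abs(start - p) > 2 * config.repeat_length + 2 * config.flank_len
                for p in locus_pos
            ) and all(
                start + config.repeat_length <= s or start >= e
                for s, e in repeat_intervals
            ):
                arr[start : start + config.repeat_length] = list(repeat_elem)
                repeat_intervals.append((start, start + config.repeat_length))
                planted += 1
    backbone = "".join(arr)

    occupancy = _resolve_occupancy(config, clusters, rng)

    # shared diverged centers for crossover clusters
    alt_centers = {
        cid: make_alt_center(tpl, rng)
        for cid, tpl in clusters.items()
        if tpl.crossover is not None
    }

    protected = [
        (l.backbone_pos - config.flank_len, l.backbone_pos + config.flank_len)
        for l in config.loci
    ] + repeat_intervals

    divergences = config.genome_divergences()
    genomes: dict[str, str] = {}
    feature_rows: list[dict] = []
    loci_sorted = sorted(config.loci, key=lambda l: l.backbone_pos)

    for gid in config.genome_ids:
        strain, posmap = derive_strain(
            backbone,
            1.0 - divergences[gid],
            rng,
            protected=protected,
            indel_frac=config.indel_frac,
        )
        pieces: list[str] = []
        cursor = 0
        out_len = 0
        for l in loci_sorted:
            pos = posmap.forward(l.backbone_pos)
            pieces.append(strain[cursor:pos])
            out_len += pos - cursor
            cursor = pos
            feature_rows.append(
                dict(
                    genome=gid,
                    type="locus_flank_left",
                    id=l.id,
                    start=out_len - config.flank_len,
                    end=out_len,
                    attrs="{}",
                )
            )
            if bool(occupancy.loc[gid, l.cluster_id]):
                tpl = clusters[l.cluster_id]
                cores = config.cores.get(gid, {}).get(l.cluster_id)
                offsets = (
                    config.crossover_variants.get(gid)
                    if tpl.crossover is not None
                    else None
                )
                copy_seq, info = build_cluster_copy(
                    tpl,
                    rng,
                    cores=cores,
                    crossover_offsets=offsets,
                    alt_center=alt_centers.get(l.cluster_id),
                    mutation_rate=config.cluster_mut_rate,
                )
                flank_repeat = (
                    not l.repeat_confounded
                    and config.repeat_flank_prob > 0
                    and rng.random() < config.repeat_flank_prob
                )
                if flank_repeat:
                    feature_rows.append(
                        dict(
                            genome=gid, type="repeat", id=f"{l.id}_rpt5",
                            start=out_len, end=out_len + config.repeat_length,
                            attrs="{}",
                        )
                    )
                    pieces.append(repeat_elem)
                    out_len += config.repeat_length
                cstart = out_len
                pieces.append(copy_seq)
                out_len += len(copy_seq)
                attrs = {"locus": l.id, "n_substitutions": info["n_substitutions"]}
                if info["crossover"]:
                    attrs["crossover"] = info["crossover"]
                feature_rows.append(
                    dict(
                        genome=gid, type="cluster", id=l.cluster_id,
                        start=cstart, end=out_len, attrs=json.dumps(attrs),
                    )
                )
                for i, slot in enumerate(info["slots"]):
                    s, e = slot["interval"]
                    feature_rows.append(
                        dict(
                            genome=gid, type="cassette_slot",
                            id=f"{l.cluster_id}_slot{i}",
                            start=cstart + s, end=cstart + e,
                            attrs=json.dumps({"core": slot["core"], "dna": slot["dna"]}),
                        )
                    )
                if info["crossover"]:
                    feature_rows.append(
                        dict(
                            genome=gid, type="crossover_center",
                            id=l.cluster_id,
                            start=cstart + info["crossover"]["break5"],
                            end=cstart + info["crossover"]["break3"],
                            attrs=json.dumps({"offsets": list(info["crossover"]["offsets"])}),
                        )
                    )
                if flank_repeat:
                    feature_rows.append(
                        dict(
                            genome=gid, type="repeat", id=f"{l.id}_rpt3",
                            start=out_len, end=out_len + config.repeat_length,
                            attrs="{}",
                        )
                    )
                    pieces.append(repeat_elem)
                    out_len += config.repeat_length
            else:
                feature_rows.append(
                    dict(
                        genome=gid, type="junction", id=l.id,
                        start=out_len, end=out_len, attrs="{}",
                    )
                )
            feature_rows.append(
                dict(
                    genome=gid, type="locus_flank_right", id=l.id,
                    start=out_len, end=out_len + config.flank_len, attrs="{}",
                )
            )
        pieces.append(strain[cursor:])
        out_len += len(strain) - cursor
        genomes[gid] = "".join(pieces)
        assert out_len == len(genomes[gid])

    features = pd.DataFrame(
        feature_rows, columns=["genome", "type", "id", "start", "end", "attrs"]
    )
    locus_rows = []
    for l in loci_sorted:
        locus_rows.append(
            dict(
                locus_id=l.id,
                cluster_id=l.cluster_id,
                cluster_len=len(clusters[l.cluster_id].sequence),
                left_flank=backbone[l.backbone_pos - config.flank_len : l.backbone_pos],
                right_flank=backbone[l.backbone_pos : l.backbone_pos + config.flank_len],
                repeat_confounded=l.repeat_confounded,
            )
        )
    locus_table = pd.DataFrame(
        locus_rows,
        columns=[
            "locus_id", "cluster_id", "cluster_len",
            "left_flank", "right_flank", "repeat_confounded",
        ],
    )
    return Population(
        config=config,
        clusters=clusters,
        backbone=backbone,
        genomes=genomes,
        occupancy=occupancy,
        features=features,
        locus_table=locus_table,
    )


# ---------------------------------------------------------------------------
# fragmentation + mate pairs


def fragment_with_mates(
    genome: str,
    n50: int,
    rng: np.random.Generator,
    insert_mean: float = 3000.0,
    insert_sd: float = 300.0,
    n_pairs: int = 200,
    genome_id: str = "G",
) -> tuple[dict[str, str], pd.DataFrame, pd.DataFrame]:
    """Gap-free fragmentation into contigs plus sampled mate-pair links.

    Contig lengths are exponential around the N50 target; links record
    an FR pair with positions relative to their contigs.
    """
    if n50 < 1000:
        raise ValueError("N50 must be >= 1 kbp")
    length = len(genome)
    mean_len = n50 / 1.678  # exponential length-weighted median -> N50
    bounds = [0]
    while bounds[-1] < length:
        ell = max(200, int(rng.exponential(mean_len)))
        bounds.append(min(length, bounds[-1] + ell))
    if bounds[-1] - bounds[-2] < 200 and len(bounds) > 2:
        bounds.pop(-2)
    contigs: dict[str, str] = {}
    rows = []
    for i, (s, e) in enumerate(zip(bounds, bounds[1:])):
        name = f"{genome_id}_c{i:04d}"
        contigs[name] = genome[s:e]
        rows.append(dict(contig=name, start=s, end=e, length=e - s))
    cmap = pd.DataFrame(rows, columns=["contig", "start", "end", "length"])
    starts = cmap.start.to_numpy()

    def locate(pos: int) -> tuple[str, int]:
        idx = int(np.searchsorted(starts, pos, side="right") - 1)
        row = cmap.iloc[idx]
        return row.contig, int(pos - row.start)

    link_rows = []
    for pid in range(n_pairs):
        ins = max(500.0, rng.normal(insert_mean, insert_sd))
        p1 = int(rng.integers(0, max(1, length - int(ins) - 1)))
        p2 = p1 + int(ins)
        ca, pa = locate(p1)
        cb, pb = locate(p2)
        link_rows.append(
            dict(
                pair=f"{genome_id}_m{pid:05d}",
                contig_a=ca, pos_a=pa, strand_a="+",
                contig_b=cb, pos_b=pb, strand_b="-",
                span=p2 - p1,
            )
        )
    links = pd.DataFrame(
        link_rows,
        columns=["pair", "contig_a", "pos_a", "strand_a",
                 "contig_b", "pos_b", "strand_b", "span"],
    )
    return contigs, cmap, links


def add_fragmentation(
    pop: Population,
    n50: int,
    insert_mean: float = 3000.0,
    insert_sd: float = 300.0,
    n_pairs: int = 200,
    seed_offset: int = 1_000_003,
) -> None:
    """Fragment every genome in place (deterministic per population seed)."""
    for i, gid in enumerate(pop.config.genome_ids):
        rng = np.random.default_rng(pop.config.seed + seed_offset + i)
        contigs, cmap, links = fragment_with_mates(
            pop.genomes[gid], n50, rng,
            insert_mean=insert_mean, insert_sd=insert_sd,
            n_pairs=n_pairs, genome_id=gid,
        )
        pop.contigs[gid] = contigs
        pop.contig_maps[gid] = cmap
        pop.mate_links[gid] = links


def contig_n50(lengths) -> int:
    arr = np.sort(np.asarray(list(lengths)))[::-1]
    half = arr.sum() / 2
    csum = np.cumsum(arr)
    return int(arr[np.searchsorted(csum, half)])


# ---------------------------------------------------------------------------
# canned configurations


def demo_clusters(rng: np.random.Generator) -> dict[str, ClusterTemplate]:
    """Five-pathway library including one cyanobactin crossover pair."""
    lib = {
        "nkd": make_cluster_template(rng, "nkd", 3000, kind="nrps"),
        "pyr": make_cluster_template(rng, "pyr", 2500, kind="nrps"),
        "gaz": make_cluster_template(rng, "gaz", 2800, kind="pks"),
        # ribosomal pathway with a 24-bp hypervariable core cassette
        "hyd": make_cluster_template(rng, "hyd", 2200, kind="ribosomal",
                                     n_slots=1, core_len_aa=8),
        "cyn": make_cluster_template(
            rng, "cyn", 6000, kind="cyanobactin",
            n_slots=1, core_len_aa=6,
            crossover_frac=(0.35, 0.65), crossover_identity=0.5,
        ),
    }
    return lib


def demo_population(seed: int = 0, fragment: bool = False) -> Population:
    """Three genomes, five loci, crossover variants with 5/300 bp scars."""
    rng = np.random.default_rng(seed + 7_777_777)
    clusters = demo_clusters(rng)
    config = PopulationConfig(
        backbone_length=40000,
        genome_ids=("P1", "P2", "P3"),
        divergences=(0.015, 0.01, 0.01),
        loci=[
            LocusConfig("L1", 5000, "nkd"),
            LocusConfig("L2", 12000, "pyr"),
            LocusConfig("L3", 19000, "gaz"),
            LocusConfig("L4", 26000, "hyd"),
            LocusConfig("L5", 33000, "cyn"),
        ],
        occupancy={
            "P1": {"nkd": False, "pyr": False, "gaz": True, "hyd": True, "cyn": True},
            "P2": {"nkd": False, "pyr": True, "gaz": True, "hyd": True, "cyn": True},
            "P3": {"nkd": True, "pyr": True, "gaz": True, "hyd": True, "cyn": True},
        },
        crossover_variants={"P2": (0, 0), "P3": (5, 300)},
        cores={
            "P1": {"cyn": ["TSIAPF"], "hyd": ["ITVCISVC"]},
            "P2": {"cyn": ["TTVTAC"], "hyd": ["ITACITFC"]},
            "P3": {"cyn": ["TLSPFC"], "hyd": ["TVCGSYLC"]},
        },
        seed=seed,
    )
    pop = generate_population(config, clusters)
    if fragment:
        add_fragmentation(pop, n50=5000)
    return pop
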