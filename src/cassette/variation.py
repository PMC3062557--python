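"""Integration-locus occupancy calls and three-level variation typing.

Loci are anchored by conserved flanking sequence. Between two genomes a
shared cluster is compared by a windowed identity profile; differences
fall into three levels:

1. presence/absence of the whole cluster at the locus;
2. a diverged internal segment (function swap / crossover) between
   near-identical flanking segments;
3. near-identity everywhere except short (<=30 bp) hypervariable core
   cassettes inside the precursor gene.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import seqs, synteny

JUNCTION_TOL = 50  # bp; "absent" means flank-to-flank within this
FLANK_MISMATCH_MAX = 0.02
LEVEL2_MIN_SEGMENT = 500
LEVEL2_DIVERGED_MAX = 0.90
FLANK_TIER_MIN = 0.99
DEFAULT_WINDOW = 100
DEFAULT_STEP = 20


@dataclass(frozen=True)
class IntegrationLocus:
    id: str
    left_flank: str
    right_flank: str
    cluster_id: str
    cluster_len: int


def loci_from_table(table: pd.DataFrame) -> list[IntegrationLocus]:
    return [
        IntegrationLocus(
            id=row.locus_id,
            left_flank=row.left_flank,
            right_flank=row.right_flank,
            cluster_id=row.cluster_id,
            cluster_len=int(row.cluster_len),
        )
        for row in table.itertuples()
    ]


@dataclass
class FlankHit:
    start: int
    end: int
    n_hits: int
    mismatches: int


@dataclass
class LocusLocation:
    locus_id: str
    status: str  # located | repeat-confounded | unresolved
    left: FlankHit | None = None
    right: FlankHit | None = None


def _approx_find(genome: str, probe: str, max_mismatch_frac: float) -> list[tuple[int, int]]:
    """All placements of probe with <= max_mismatch_frac mismatches.

    Exact matches via str.find; otherwise k-mer seeded Hamming checks.
    Returns list of (position, mismatches).
    """
    hits = []
    start = 0
    while True:
        i = genome.find(probe, start)
        if i < 0:
            break
        hits.append((i, 0))
        start = i + 1
    if hits:
        return hits
    max_mm = int(len(probe) * max_mismatch_frac)
    if max_mm == 0:
        return hits
    k = 21
    garr = seqs.seq_to_array(genome)
    parr = seqs.seq_to_array(probe)
    candidates = set()
    for off in range(0, len(probe) - k + 1, k):
        seed = probe[off : off + k]
        start = 0
        while True:
            i = genome.find(seed, start)
            if i < 0:
                break
            candidates.add(i - off)
            start = i + 1
    for pos in sorted(candidates):
        if pos < 0 or pos + len(probe) > len(genome):
            continue
        mm = int(np.count_nonzero(garr[pos : pos + len(probe)] != parr))
        if mm <= max_mm:
            hits.append((pos, mm))
    return hits


def locate_loci(
    genome: str,
    loci: list[IntegrationLocus],
    max_mismatch_frac: float = FLANK_MISMATCH_MAX,
) -> dict[str, LocusLocation]:
    """Place both flank anchors of every locus in a genome.

    A flank hitting more than one position flags the locus
    repeat-confounded; a missing flank leaves it unresolved.
    """
    out: dict[str, LocusLocation] = {}
    for locus in loci:
        if len(locus.left_flank) < 200 or len(locus.right_flank) < 200:
            raise ValueError(f"locus {locus.id}: flank anchors must be >= 200 bp")
        lhits = _approx_find(genome, locus.left_flank, max_mismatch_frac)
        rhits = _approx_find(genome, locus.right_flank, max_mismatch_frac)
        if len(lhits) > 1 or len(rhits) > 1:
            out[locus.id] = LocusLocation(locus.id, "repeat-confounded")
            continue
        if not lhits or not rhits:
            out[locus.id] = LocusLocation(locus.id, "unresolved")
            continue
        (lp, lmm), (rp, rmm) = lhits[0], rhits[0]
        if rp + len(locus.right_flank) <= lp:
            out[locus.id] = LocusLocation(locus.id, "unresolved")
            continue
        out[locus.id] = LocusLocation(
            locus.id,
            "located",
            left=FlankHit(lp, lp + len(locus.left_flank), len(lhits), lmm),
            right=FlankHit(rp, rp + len(locus.right_flank), len(rhits), rmm),
        )
    return out


@dataclass
class LocusCall:
    genome_id: str
    locus_id: str
    state: str  # present | absent | unresolved
    inserted_length: int = 0
    identity: float | None = None
    note: str = ""


def call_occupancy(
    genome: str,
    genome_id: str,
    locus: IntegrationLocus,
    location: LocusLocation,
    reference_cluster: str,
    junction_tol: int = JUNCTION_TOL,
    min_identity: float = 0.70,
    length_tol: float = 0.25,
) -> LocusCall:
    """Classify one locus as present / absent / unresolved.

    Present: inter-flank distance approximates the reference cluster
    length and the inter-flank sequence aligns to it. Absent: flanks
    directly adjoin (within the junction tolerance). Anything else —
    residual fragments, unexpected inserts — stays unresolved.

    The identity floor is deliberately permissive (0.70): a shared
    cluster whose central region has swapped function still occupies
    the locus, and the length check already rejects residual fragments.
    """
    if location.status != "located":
        return LocusCall(genome_id, locus.id, "unresolved", note=location.status)
    gap_start = location.left.end
    gap_end = location.right.start
    inserted = genome[gap_start:gap_end]
    d = gap_end - gap_start
    if d <= junction_tol:
        return LocusCall(genome_id, locus.id, "absent", inserted_length=d)
    ref_len = len(reference_cluster)
    if abs(d - ref_len) <= length_tol * ref_len:
        anchors = synteny.find_anchors(reference_cluster, inserted)
        blocks = synteny.chain_and_extend(anchors, reference_cluster, inserted)
        if blocks:
            identity, cover = synteny.average_identity(blocks, ref_len)
            if identity >= min_identity and cover >= 0.5:
                return LocusCall(
                    genome_id, locus.id, "present",
                    inserted_length=d, identity=identity,
                )
    # partial-match evidence (e.g. a residual gene from a lost cluster)
    note = "unexpected-insert"
    anchors = synteny.find_anchors(reference_cluster, inserted)
    if anchors:
        covered = sum(a.length for a in anchors)
        if covered >= 100:
            note = f"partial-match:{covered}bp"
    return LocusCall(genome_id, locus.id, "unresolved", inserted_length=d, note=note)


# ---------------------------------------------------------------------------
# crossover profiling


@dataclass
class Segment:
    start: int  # coordinates on sequence A
    end: int
    tier: str  # flank-identical | diverged
    mean_identity: float


@dataclass
class CrossoverProfile:
    windows: pd.DataFrame  # a_pos, identity
    segments: list[Segment]
    breakpoints: list[int]  # a-coordinates of tier transitions
    window: int
    step: int
    col_match: np.ndarray | None = None  # per-alignment-column match flags
    col_apos: np.ndarray | None = None  # per-column position on sequence A

    @property
    def diverged_segments(self) -> list[Segment]:
        return [s for s in self.segments if s.tier == "diverged"]

    def identity_excluding(self, intervals: list[tuple[int, int]]) -> float:
        """Column-level identity outside the given A-coordinate intervals."""
        if self.col_match is None:
            return float("nan")
        mask = np.zeros(len(self.col_match), dtype=bool)
        for s, e in intervals:
            mask |= (self.col_apos >= s) & (self.col_apos < e)
        outside = self.col_match[~mask]
        return float(outside.mean()) if outside.size else 1.0


def crossover_profile(
    cluster_a: str,
    cluster_b: str,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
) -> CrossoverProfile:
    """Sliding-window identity along a global alignment of two clusters.

    Windows are split into two states (near-identical vs diverged) and
    merged into segments; breakpoints sit at state transitions with
    window-level resolution.
    """
    aln = seqs.make_aligner("global").align(cluster_a, cluster_b)[0]
    blocks_a, blocks_b = aln.aligned
    cols_match: list[bool] = []
    cols_apos: list[int] = []
    prev_a = prev_b = 0
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        for _ in range(a0 - prev_a):
            cols_match.append(False)
            cols_apos.append(prev_a)
        for _ in range(b0 - prev_b):
            cols_match.append(False)
            cols_apos.append(a0)
        for i, j in zip(range(a0, a1), range(b0, b1)):
            cols_match.append(cluster_a[i] == cluster_b[j])
            cols_apos.append(i)
        prev_a, prev_b = a1, b1
    for _ in range(len(cluster_a) - prev_a):
        cols_match.append(False)
        cols_apos.append(prev_a)
    match = np.asarray(cols_match, dtype=float)
    apos = np.asarray(cols_apos)

    starts = np.arange(0, max(1, len(match) - window + 1), step)
    win_id = np.array([match[s : s + window].mean() for s in starts])
    win_apos = np.array([apos[min(s + window // 2, len(apos) - 1)] for s in starts])
    windows = pd.DataFrame({"a_pos": win_apos, "identity": win_id})

    threshold = (FLANK_TIER_MIN + LEVEL2_DIVERGED_MAX) / 2  # 0.945
    high = win_id >= threshold
    segments: list[Segment] = []
    breakpoints: list[int] = []
    seg_start = 0
    for i in range(1, len(high) + 1):
        if i == len(high) or high[i] != high[seg_start]:
            ids = win_id[seg_start:i]
            a0 = int(win_apos[seg_start]) if seg_start else 0
            a1 = int(win_apos[i - 1]) if i < len(high) else len(cluster_a)
            tier = "flank-identical" if high[seg_start] else "diverged"
            segments.append(Segment(a0, a1, tier, float(ids.mean())))
            if i < len(high):
                breakpoints.append(int((win_apos[i - 1] + win_apos[i]) // 2))
            seg_start = i
    # stitch segment bounds to partition [0, len(a))
    for prev, nxt in zip(segments, segments[1:]):
        mid = (prev.end + nxt.start) // 2
        prev_end = mid
        prev.end = prev_end
        nxt.start = prev_end
    if segments:
        segments[0].start = 0
        segments[-1].end = len(cluster_a)
    return CrossoverProfile(
        windows, segments, breakpoints, window, step,
        col_match=match.astype(bool), col_apos=apos,
    )


# ---------------------------------------------------------------------------
# core cassette extraction


@dataclass
class CoreCassette:
    start: int  # on the supplied precursor/cluster sequence
    end: int
    dna: str
    peptide: str


def extract_cores(
    precursor_seq: str,
    leader_model: dict,
    max_mismatch: int = 2,
) -> list[CoreCassette]:
    """Cassettes between conserved recognition flanks.

    ``leader_model`` needs ``left`` and ``right`` DNA motifs (in frame)
    and optionally ``max_core`` (default 30 bp). Returns an empty list
    when no leader match is found.
    """
    left = leader_model["left"].upper()
    right = leader_model["right"].upper()
    max_core = int(leader_model.get("max_core", 30))
    cores: list[CoreCassette] = []
    cursor = 0
    while True:
        lhits = _approx_find(precursor_seq[cursor:], left, max_mismatch / len(left))
        if not lhits:
            break
        lpos = cursor + min(h[0] for h in lhits)
        core_start = lpos + len(left)
        search_zone = precursor_seq[core_start : core_start + max_core + len(right)]
        rhits = _approx_find(search_zone, right, max_mismatch / len(right))
        if not rhits:
            cursor = core_start
            continue
        rpos = core_start + min(h[0] for h in rhits)
        dna = precursor_seq[core_start:rpos]
        peptide = seqs.translate_dna(dna) if len(dna) % 3 == 0 else ""
        cores.append(CoreCassette(core_start, rpos, dna, peptide))
        cursor = rpos + len(right)
    return cores


# ---------------------------------------------------------------------------
# three-level classification


@dataclass
class VariationCall:
    cluster_id: str
    genome_a: str
    genome_b: str
    level: int
    evidence: dict = field(default_factory=dict)


def classify_variation(
    cluster_id: str,
    call_a: LocusCall,
    call_b: LocusCall,
    profile: CrossoverProfile | None = None,
    cores_a: list[CoreCassette] | None = None,
    cores_b: list[CoreCassette] | None = None,
    slot_intervals: list[tuple[int, int]] | None = None,
) -> list[VariationCall]:
    """Assign variation levels for one cluster between two genomes.

    Level 1: occupancy differs. Level 2: shared cluster with a diverged
    internal segment (>= 500 bp below 0.90 identity) between
    near-identical (>= 0.99) segments. Level 3: >= 0.99 identity
    everywhere except <= 30 bp cassettes inside precursor slots, and
    the cassettes differ. Levels can co-occur; all are reported.
    """
    a, b = call_a.genome_id, call_b.genome_id
    calls: list[VariationCall] = []
    states = {call_a.state, call_b.state}
    if "unresolved" in states:
        return calls
    if call_a.state != call_b.state:
        calls.append(
            VariationCall(cluster_id, a, b, 1,
                          {"states": (call_a.state, call_b.state)})
        )
        return calls
    if call_a.state == "absent":
        return calls
    # both present
    if profile is not None:
        div = [
            s for s in profile.diverged_segments
            if s.end - s.start >= LEVEL2_MIN_SEGMENT and s.mean_identity < LEVEL2_DIVERGED_MAX
        ]
        flank_ok = any(
            s.tier == "flank-identical" and s.mean_identity >= FLANK_TIER_MIN
            for s in profile.segments
        )
        if div and flank_ok:
            calls.append(
                VariationCall(
                    cluster_id, a, b, 2,
                    {
                        "diverged": [(s.start, s.end, round(s.mean_identity, 3)) for s in div],
                        "breakpoints": profile.breakpoints,
                    },
                )
            )
        elif not div and cores_a and cores_b:
            pairs = list(zip(cores_a, cores_b))
            differing = [
                (ca.dna, cb.dna) for ca, cb in pairs if ca.dna != cb.dna
            ]
            short_enough = all(
                len(ca.dna) <= 30 and len(cb.dna) <= 30 for ca, cb in pairs
            )
            # every diverged stretch must sit on an annotated cassette
            # slot, and the sequences with cassettes excised must be
            # near-identical (>= 0.99)
            slack = profile.window
            slots = slot_intervals or [(c.start, c.end) for c in cores_a]
            dips_on_slots = all(
                any(s.start <= e + slack and s.end >= b - slack for b, e in slots)
                for s in profile.diverged_segments
            )
            backbone_ok = profile.identity_excluding(slots) >= FLANK_TIER_MIN
            if differing and short_enough and dips_on_slots and backbone_ok:
                calls.append(
                    VariationCall(
                        cluster_id, a, b, 3,
                        {"cassettes": differing,
                         "identity": [
                             round(seqs.hamming_identity(x, y), 3)
                             for x, y in differing if len(x) == len(y)
                         ]},
                    )
                )
    return calls


def locus_calls_frame(calls: list[LocusCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                genome=c.genome_id, locus=c.locus_id, state=c.state,
                inserted_length=c.inserted_length,
                identity=(round(c.identity, 4) if c.identity is not None else ""),
                note=c.note,
            )
            for c in calls
        ],
        columns=["genome", "locus", "state", "inserted_length", "identity", "note"],
    )


def variation_calls_frame(calls: list[VariationCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                cluster=c.cluster_id, genome_a=c.genome_a, genome_b=c.genome_b,
                level=c.level, evidence=json.dumps(c.evidence, default=str),
            )
            for c in calls
        ],
        columns=["cluster", "genome_a", "genome_b", "level", "evidence"],
    )
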