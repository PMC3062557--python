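"""Anchor-based pairwise genome comparison.

Seed–chain–extend in the style of whole-genome aligners, at desk scale:
maximal exact k-mer matches are chained co-linearly, inter-anchor gaps
are closed with gapped alignment, and the resulting synteny blocks give
length-weighted average nucleotide identity, synteny-break reports,
contig-to-reference placements and mate-pair order checks.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import seqs

DEFAULT_K = 15
DEFAULT_MAX_GAP = 5000
DEFAULT_REPEAT_MAX = 5


@dataclass(frozen=True)
class Anchor:
    """Maximal exact match. For strand '-', qry_pos indexes the
    reverse-complemented query."""

    ref_pos: int
    qry_pos: int
    length: int
    strand: str = "+"

    @property
    def ref_end(self) -> int:
        return self.ref_pos + self.length

    @property
    def qry_end(self) -> int:
        return self.qry_pos + self.length


@dataclass
class SyntenyBlock:
    ref_start: int
    ref_end: int
    qry_start: int
    qry_end: int
    strand: str
    identity: float
    n_anchors: int
    matches: int = 0
    columns: int = 0

    @property
    def ref_len(self) -> int:
        return self.ref_end - self.ref_start

    @property
    def qry_len(self) -> int:
        return self.qry_end - self.qry_start


def _kmer_index(seq: str, k: int, repeat_max: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        index[seq[i : i + k]].append(i)
    return {km: pos for km, pos in index.items() if len(pos) <= repeat_max}


def _scan(ref: str, qry: str, index: dict, k: int, strand: str) -> list[Anchor]:
    anchors = []
    n = len(qry)
    for q in range(n - k + 1):
        hits = index.get(qry[q : q + k])
        if not hits:
            continue
        for r in hits:
            # skip non-leftmost seeds of the same maximal match
            if q > 0 and r > 0 and ref[r - 1] == qry[q - 1]:
                continue
            length = k
            while r + length < len(ref) and q + length < n and ref[r + length] == qry[q + length]:
                length += 1
            anchors.append(Anchor(r, q, length, strand))
    return anchors


def find_anchors(
    ref: str,
    qry: str,
    k: int = DEFAULT_K,
    both_strands: bool = True,
    repeat_max: int = DEFAULT_REPEAT_MAX,
) -> list[Anchor]:
    """All maximal shared exact matches seeded by k-mers.

    K-mers occurring more than ``repeat_max`` times in the reference are
    masked before seeding (repeat handling).
    """
    if k < 11:
        raise ValueError("seed length k must be >= 11")
    index = _kmer_index(ref, k, repeat_max)
    anchors = _scan(ref, qry, index, k, "+")
    if both_strands:
        anchors += _scan(ref, seqs.revcomp(qry), index, k, "-")
    return anchors


def _chain_dp(
    anchors: list[Anchor],
    max_gap: int,
    lookback: int = 64,
    max_indel: int = 1000,
) -> list[list[Anchor]]:
    """Co-linear chaining (windowed DP); returns chains by descending score.

    Links are forbidden across strongly one-sided gaps (|ref gap − qry
    gap| > ``max_indel``): a clean insertion/deletion must terminate a
    block so it surfaces as a synteny break instead of being absorbed.
    """
    if not anchors:
        return []
    anchors = sorted(anchors, key=lambda a: (a.ref_pos, a.qry_pos))
    n = len(anchors)
    score = [a.length for a in anchors]
    pred = [-1] * n
    for i, a in enumerate(anchors):
        for j in range(max(0, i - lookback), i):
            b = anchors[j]
            if b.ref_end > a.ref_pos or b.qry_end > a.qry_pos:
                continue
            gr = a.ref_pos - b.ref_end
            gq = a.qry_pos - b.qry_end
            if gr > max_gap or gq > max_gap or abs(gr - gq) > max_indel:
                continue
            cand = score[j] + a.length - max(gr, gq) * 0.01
            if cand > score[i]:
                score[i] = cand
                pred[i] = j
    used = [False] * n
    chains = []
    for i in sorted(range(n), key=lambda i: -score[i]):
        if used[i]:
            continue
        chain = []
        j = i
        while j != -1 and not used[j]:
            used[j] = True
            chain.append(anchors[j])
            j = pred[j]
        chain.reverse()
        chains.append(chain)
    return chains


def _block_from_chain(chain: list[Anchor], ref: str, qry_oriented: str, strand: str,
                      qry_len: int, max_gap: int) -> SyntenyBlock:
    matches = 0
    cols = 0
    prev = None
    for a in chain:
        matches += a.length
        cols += a.length
        if prev is not None:
            gr = a.ref_pos - prev.ref_end
            gq = a.qry_pos - prev.qry_end
            if gr or gq:
                if gr <= max_gap and gq <= max_gap:
                    m, c, _ = seqs.alignment_identity(
                        ref[prev.ref_end : a.ref_pos],
                        qry_oriented[prev.qry_end : a.qry_pos],
                    )
                    matches += m
                    cols += c
                else:
                    cols += max(gr, gq)
        prev = a
    q0, q1 = chain[0].qry_pos, chain[-1].qry_end
    if strand == "-":
        q0, q1 = qry_len - q1, qry_len - chain[0].qry_pos
    return SyntenyBlock(
        ref_start=chain[0].ref_pos,
        ref_end=chain[-1].ref_end,
        qry_start=q0,
        qry_end=q1,
        strand=strand,
        identity=matches / cols if cols else 1.0,
        n_anchors=len(chain),
        matches=matches,
        columns=cols,
    )


def chain_and_extend(
    anchors: list[Anchor],
    ref: str,
    qry: str,
    max_gap: int = DEFAULT_MAX_GAP,
    min_block: int = 100,
) -> list[SyntenyBlock]:
    """Chain anchors into synteny blocks with gapped identity.

    Returns blocks sorted by reference start; query intervals are in
    forward-query coordinates regardless of strand.
    """
    blocks = []
    qry_rc = seqs.revcomp(qry)
    for strand in ("+", "-"):
        sub = [a for a in anchors if a.strand == strand]
        for chain in _chain_dp(sub, max_gap):
            qseq = qry if strand == "+" else qry_rc
            block = _block_from_chain(chain, ref, qseq, strand, len(qry), max_gap)
            if block.ref_len >= min_block:
                blocks.append(block)
    blocks.sort(key=lambda b: b.ref_start)
    # drop blocks fully contained in a longer one (repeat shadows)
    kept: list[SyntenyBlock] = []
    for b in blocks:
        if any(
            k.ref_start <= b.ref_start and b.ref_end <= k.ref_end and k is not b
            for k in kept
        ):
            continue
        kept.append(b)
    return kept


def average_identity(blocks: list[SyntenyBlock], ref_len: int) -> tuple[float, float]:
    """Length-weighted mean identity and fraction of reference covered."""
    if not blocks:
        raise ValueError("no synteny blocks")
    total_cols = sum(b.columns for b in blocks)
    total_matches = sum(b.matches for b in blocks)
    covered = sum(b.ref_len for b in blocks)
    return total_matches / total_cols, min(1.0, covered / ref_len)


def compare_genomes(
    ref: str,
    qry: str,
    k: int = DEFAULT_K,
    max_gap: int = DEFAULT_MAX_GAP,
) -> tuple[list[SyntenyBlock], float, float]:
    """Convenience: anchors -> blocks -> (blocks, ANI, ref coverage)."""
    anchors = find_anchors(ref, qry, k=k)
    blocks = chain_and_extend(anchors, ref, qry, max_gap=max_gap)
    ani, cov = average_identity(blocks, len(ref))
    return blocks, ani, cov


# ---------------------------------------------------------------------------
# synteny breaks


@dataclass
class Break:
    ref_gap_start: int
    ref_gap_end: int
    qry_gap_start: int
    qry_gap_end: int
    classification: str  # cassette-candidate | rearrangement-or-misassembly | contig-end

    @property
    def ref_gap(self) -> int:
        return self.ref_gap_end - self.ref_gap_start

    @property
    def qry_gap(self) -> int:
        return self.qry_gap_end - self.qry_gap_start


@dataclass
class BreakReport:
    breaks: list[Break] = field(default_factory=list)

    def of_class(self, cls: str) -> list[Break]:
        return [b for b in self.breaks if b.classification == cls]


def detect_breaks(
    blocks: list[SyntenyBlock],
    cassette_min: int = 2000,
    junction_max: int = 200,
    contig_bounds: list[int] | None = None,
    end_tol: int = 50,
) -> BreakReport:
    """Classify inter-block gaps.

    One-sided gap >= ``cassette_min`` with the other side <=
    ``junction_max`` -> cassette-candidate (clean insertion/absence);
    order inversion or large gaps on both sides ->
    rearrangement-or-misassembly; a gap abutting a contig terminus ->
    contig-end.
    """
    report = BreakReport()
    ordered = sorted(blocks, key=lambda b: b.ref_start)
    for a, b in zip(ordered, ordered[1:]):
        rg0, rg1 = a.ref_end, b.ref_start
        qg0, qg1 = a.qry_end, b.qry_start
        ref_gap = max(0, rg1 - rg0)
        qry_gap = qg1 - qg0  # negative = inversion of order
        if ref_gap <= junction_max and 0 <= qry_gap <= junction_max:
            continue  # contiguous enough, not a break
        if contig_bounds and any(
            abs(edge - p) <= end_tol
            for edge in contig_bounds
            for p in (qg0, qg1)
        ):
            cls = "contig-end"
        elif (ref_gap >= cassette_min and 0 <= qry_gap <= junction_max) or (
            qry_gap >= cassette_min and ref_gap <= junction_max
        ):
            cls = "cassette-candidate"
        else:
            cls = "rearrangement-or-misassembly"
        report.breaks.append(Break(rg0, rg1, qg0, max(qg0, qg1), cls))
    return report


# ---------------------------------------------------------------------------
# contig mapping


@dataclass
class Placement:
    contig: str
    ref_start: int
    ref_end: int
    strand: str
    identity: float
    status: str  # placed | ambiguous | unplaced
    score: float = 0.0


def map_contigs(
    ref: str,
    contigs: dict[str, str],
    k: int = DEFAULT_K,
    min_len: int = 1000,
    min_cover: float = 0.2,
    ambiguity_ratio: float = 0.95,
) -> dict[str, Placement]:
    """Best placement per contig on a reference via chain scoring.

    Contigs whose second-best placement is nearly as good (repeat
    content) are flagged ambiguous; contigs with too little anchor
    cover are unplaced.
    """
    placements: dict[str, Placement] = {}
    for name, cseq in contigs.items():
        if len(cseq) < min_len:
            placements[name] = Placement(name, -1, -1, ".", 0.0, "unplaced")
            continue
        anchors = find_anchors(ref, cseq, k=k)
        blocks = chain_and_extend(anchors, ref, cseq, min_block=min(100, len(cseq) // 2))
        if not blocks:
            placements[name] = Placement(name, -1, -1, ".", 0.0, "unplaced")
            continue
        scored = sorted(blocks, key=lambda b: -(b.matches))
        best = scored[0]
        if best.qry_len < min_cover * len(cseq):
            placements[name] = Placement(name, -1, -1, ".", 0.0, "unplaced")
            continue
        status = "placed"
        if len(scored) > 1:
            second = scored[1]
            overlap = min(best.ref_end, second.ref_end) - max(best.ref_start, second.ref_start)
            if (
                second.matches >= ambiguity_ratio * best.matches
                and overlap < 0.5 * best.ref_len
            ):
                status = "ambiguous"
        # extrapolate placement to full contig extent
        if best.strand == "+":
            start = best.ref_start - best.qry_start
            end = best.ref_end + (len(cseq) - best.qry_end)
        else:
            start = best.ref_start - (len(cseq) - best.qry_end)
            end = best.ref_end + best.qry_start
        placements[name] = Placement(
            name, start, end, best.strand, best.identity, status, score=best.matches
        )
    return placements


# ---------------------------------------------------------------------------
# mate-pair order verification


@dataclass
class MateReport:
    n_links: int
    n_evaluable: int
    n_concordant: int
    discordant: list[str] = field(default_factory=list)

    @property
    def concordant_fraction(self) -> float:
        return self.n_concordant / self.n_evaluable if self.n_evaluable else float("nan")


def verify_order_with_mates(
    placements: dict[str, Placement],
    mate_links: pd.DataFrame,
    insert_mean: float,
    insert_sd: float,
) -> MateReport:
    """Check that placed-contig order/orientation agrees with mate pairs.

    A link is concordant when both ends land on placed contigs, the
    implied reference span is within mean +/- 3 SD and the implied
    orientation is forward->reverse.
    """
    lo = insert_mean - 3 * insert_sd
    hi = insert_mean + 3 * insert_sd
    n_eval = 0
    n_ok = 0
    bad: list[str] = []
    for row in mate_links.itertuples():
        pa = placements.get(row.contig_a)
        pb = placements.get(row.contig_b)
        if not pa or not pb or pa.status != "placed" or pb.status != "placed":
            continue
        n_eval += 1

        def ref_pos(p: Placement, pos: int) -> int:
            return p.ref_start + pos if p.strand == "+" else p.ref_end - pos

        ra = ref_pos(pa, row.pos_a)
        rb = ref_pos(pb, row.pos_b)
        span = rb - ra
        orient_ok = (row.strand_a, row.strand_b) == ("+", "-") and span > 0
        if orient_ok and lo <= span <= hi:
            n_ok += 1
        else:
            bad.append(row.pair)
    return MateReport(len(mate_links), n_eval, n_ok, bad)


# ---------------------------------------------------------------------------
# composition classification (IMM stand-in)


def tetranucleotide_profile(seq: str) -> np.ndarray:
    arr = seqs.seq_to_array(seq)
    code = np.full(arr.shape, -1, dtype=np.int64)
    for i, b in enumerate(b"ACGT"):
        code[arr == b] = i
    valid = code >= 0
    idx = np.zeros(256, dtype=float)
    if len(code) >= 4:
        quad = code[:-3] * 64 + code[1:-2] * 16 + code[2:-1] * 4 + code[3:]
        ok = valid[:-3] & valid[1:-2] & valid[2:-1] & valid[3:]
        counts = np.bincount(quad[ok], minlength=256).astype(float)
        total = counts.sum()
        if total:
            idx = counts / total
    return idx


def classify_contigs_by_composition(
    contigs: dict[str, str],
    reference_sets: dict[str, list[str]],
    min_len: int = 1000,
    min_margin: float = 0.01,
) -> pd.DataFrame:
    """Nearest-centroid label on tetranucleotide frequency (cosine).

    Short contigs or narrow margins between the two best centroids are
    flagged low-confidence.
    """
    centroids = {}
    for label, ref_seqs in reference_sets.items():
        profs = [tetranucleotide_profile(s) for s in ref_seqs]
        centroids[label] = np.mean(profs, axis=0)
    rows = []
    for name, cseq in contigs.items():
        prof = tetranucleotide_profile(cseq)
        sims = {}
        for label, cent in centroids.items():
            denom = np.linalg.norm(prof) * np.linalg.norm(cent)
            sims[label] = float(prof @ cent / denom) if denom else 0.0
        ranked = sorted(sims.items(), key=lambda kv: -kv[1])
        best_label, best_sim = ranked[0]
        margin = best_sim - ranked[1][1] if len(ranked) > 1 else best_sim
        low_conf = len(cseq) < min_len or margin < min_margin
        rows.append(
            dict(
                contig=name, label=best_label, similarity=best_sim,
                margin=margin, low_confidence=low_conf,
            )
        )
    return pd.DataFrame(rows, columns=["contig", "label", "similarity", "margin", "low_confidence"])


def blocks_to_frame(blocks: list[SyntenyBlock]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                ref_start=b.ref_start, ref_end=b.ref_end,
                qry_start=b.qry_start, qry_end=b.qry_end,
                strand=b.strand, identity=b.identity, n_anchors=b.n_anchors,
            )
            for b in blocks
        ],
        columns=["ref_start", "ref_end", "qry_start", "qry_end", "strand", "identity", "n_anchors"],
    )
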