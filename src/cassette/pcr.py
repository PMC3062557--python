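"""Presence/absence primer assays, virtual PCR and genotype matrices.

Each pathway gets a dual assay: a presence reaction internal to the
cluster (amplifies only when the cluster is there) and an absence
reaction spanning the empty integration junction (amplifies only when
it is not — a present cluster pushes the span past the product-size
ceiling). A sample where both reactions fire indicates a design or
sample error and is raised, never silently resolved.

Primer matching is purely sequence-based: length, GC bounds, at most
one mismatch per primer and none in the 3'-terminal three bases.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import seqs

PRIMER_LEN = 20
GC_MIN, GC_MAX = 0.40, 0.60
MAX_MISMATCH = 1
THREE_PRIME_EXACT = 3
MAX_PRODUCT = 5000


class ControlViolationError(RuntimeError):
    """Presence and absence reactions both positive for one sample."""


@dataclass(frozen=True)
class PrimerAssay:
    pathway_id: str
    mode: str  # presence-internal | absence-spanning
    forward: str
    reverse: str
    min_product: int
    max_product: int

    def __post_init__(self):
        for p in (self.forward, self.reverse):
            if not 18 <= len(p) <= 25:
                raise ValueError("primer length must be 18-25 nt")


@dataclass
class AssayPair:
    pathway_id: str
    presence: PrimerAssay | None
    absence: PrimerAssay | None
    presence_flag: str = ""  # design-failure note, empty if ok
    absence_flag: str = ""  # e.g. 'impractical-repeat-flanks'


@dataclass
class Amplicon:
    start: int
    end: int
    length: int
    fwd_mismatches: int
    rev_mismatches: int


@dataclass
class AmpliconResult:
    genome_id: str
    pathway_id: str
    mode: str
    products: list[Amplicon] = field(default_factory=list)

    @property
    def positive(self) -> bool:
        return bool(self.products)


# ---------------------------------------------------------------------------
# primer site search


def primer_sites(
    genome: str,
    primer: str,
    max_mismatch: int = MAX_MISMATCH,
    three_prime_exact: bool = True,
) -> list[tuple[int, str, int]]:
    """All annealing sites of a primer on both strands.

    Returns (plus-strand start, strand, mismatches). By default the 3'
    terminal three bases must match exactly (annealing rule); design
    scans disable this to see degraded near-sites too.
    """
    garr = seqs.seq_to_array(genome)
    sites: list[tuple[int, str, int]] = []
    n, m = len(genome), len(primer)
    if n < m:
        return sites
    windows = np.lib.stride_tricks.sliding_window_view(garr, m)
    for strand, probe in (("+", primer), ("-", seqs.revcomp(primer))):
        parr = seqs.seq_to_array(probe)
        mism = (windows != parr).sum(axis=1)
        cand = np.flatnonzero(mism <= max_mismatch)
        if three_prime_exact:
            # exact 3' end: last bases of window (+) / first bases (-)
            if strand == "+":
                bad3 = (windows[cand, -THREE_PRIME_EXACT:] != parr[-THREE_PRIME_EXACT:]).any(axis=1)
            else:
                bad3 = (windows[cand, :THREE_PRIME_EXACT] != parr[:THREE_PRIME_EXACT]).any(axis=1)
            cand = cand[~bad3]
        for pos in cand:
            sites.append((int(pos), strand, int(mism[pos])))
    return sites


def virtual_pcr(
    genome: str,
    assay: PrimerAssay,
    genome_id: str = "",
    max_mismatch: int = MAX_MISMATCH,
    max_product: int | None = None,
) -> AmpliconResult:
    """All convergent primer-site pairs within the product ceiling."""
    ceiling = assay.max_product if max_product is None else max_product
    result = AmpliconResult(genome_id, assay.pathway_id, assay.mode)
    fwd_sites = primer_sites(genome, assay.forward, max_mismatch)
    rev_sites = primer_sites(genome, assay.reverse, max_mismatch)
    plen_f, plen_r = len(assay.forward), len(assay.reverse)
    for (fp, fs, fm), (rp, rs, rm) in itertools.product(fwd_sites, rev_sites):
        if fs == rs:
            continue  # convergent pairs need opposite strands
        if fs == "+":
            start, end = fp, rp + plen_r
        else:
            start, end = rp, fp + plen_f
        length = end - start
        if 0 < length <= ceiling:
            result.products.append(Amplicon(start, end, length, fm, rm))
    return result


# ---------------------------------------------------------------------------
# assay design


def _primer_ok(p: str) -> bool:
    return GC_MIN <= seqs.gc_fraction(p) <= GC_MAX


def _unique_everywhere(primer: str, genome_set: dict[str, str]) -> bool:
    """Usable in the design set: at most one site per genome, and every
    site — including degraded near-sites that would drop out of a
    reaction — must be a perfect match (conserved across strains)."""
    for g in genome_set.values():
        sites = primer_sites(g, primer, max_mismatch=4, three_prime_exact=False)
        if len(sites) > 1:
            return False
        if sites and sites[0][2] != 0:
            return False
    return True


def _pick_primer(
    region: str,
    genome_set: dict[str, str],
    rc: bool,
    step: int = 7,
    offset: int = 0,
    avoid: list[tuple[int, int]] | None = None,
) -> str | None:
    """First GC-acceptable, genome-set-unique primer window in a region.

    ``avoid`` intervals (in the coordinates ``offset`` maps into) are
    skipped — used to keep primers out of hypervariable stretches.
    """
    for off in range(0, len(region) - PRIMER_LEN, step):
        lo, hi = offset + off, offset + off + PRIMER_LEN
        if avoid and any(lo < e and hi > s for s, e in avoid):
            continue
        window = region[off : off + PRIMER_LEN]
        primer = seqs.revcomp(window) if rc else window
        if _primer_ok(primer) and _unique_everywhere(primer, genome_set):
            return primer
    return None


def design_assays(
    pathway_id: str,
    cluster_seq: str,
    left_flank: str,
    right_flank: str,
    genome_set: dict[str, str],
    max_product: int = MAX_PRODUCT,
    presence_product: tuple[int, int] = (200, 1200),
    avoid: list[tuple[int, int]] | None = None,
) -> AssayPair:
    """Design the presence/absence assay pair for one integration locus.

    The presence pair sits inside the cluster (skipping any ``avoid``
    intervals — hypervariable cassettes or crossover centers); the
    absence pair is anchored in both flanks so its product spans the
    empty junction but exceeds ``max_product`` when the cluster is
    inserted. Repeat-borne flanks defeat the uniqueness requirement and
    flag the absence assay impractical, mirroring real screening
    constraints.
    """
    if len(left_flank) < PRIMER_LEN + 10 or len(right_flank) < PRIMER_LEN + 10:
        return AssayPair(pathway_id, None, None,
                         "design-failure:flank-too-short",
                         "design-failure:flank-too-short")
    lo, hi = presence_product
    presence = None
    presence_flag = "design-failure:no-primer-site"
    fwd = _pick_primer(cluster_seq[: len(cluster_seq) // 2], genome_set,
                       rc=False, avoid=avoid)
    if fwd is not None:
        fpos = cluster_seq.find(fwd)
        tgt_lo, tgt_hi = fpos + lo, min(fpos + hi, len(cluster_seq))
        if tgt_hi - tgt_lo > PRIMER_LEN:
            rev = _pick_primer(cluster_seq[tgt_lo:tgt_hi], genome_set,
                               rc=True, offset=tgt_lo, avoid=avoid)
            if rev is not None:
                rpos = cluster_seq.find(seqs.revcomp(rev))
                presence = PrimerAssay(
                    pathway_id, "presence-internal", fwd, rev,
                    min_product=PRIMER_LEN * 2,
                    max_product=max(hi, rpos + PRIMER_LEN - fpos + 100),
                )
                presence_flag = ""
    absence = None
    absence_flag = ""
    if len(cluster_seq) <= max_product:
        absence_flag = "impractical-cluster-shorter-than-ceiling"
    else:
        afwd = _pick_primer(left_flank[-(PRIMER_LEN + 200):], genome_set, rc=False)
        arev = _pick_primer(right_flank[: PRIMER_LEN + 200], genome_set, rc=True)
        if afwd is None or arev is None:
            absence_flag = "impractical-repeat-flanks"
        else:
            absence = PrimerAssay(
                pathway_id, "absence-spanning", afwd, arev,
                min_product=PRIMER_LEN * 2, max_product=max_product,
            )
    return AssayPair(pathway_id, presence, absence, presence_flag, absence_flag)


# ---------------------------------------------------------------------------
# genotyping


def genotype(
    presence_result: AmpliconResult | None,
    absence_result: AmpliconResult | None,
) -> str:
    """Combine the dual reactions into one matrix cell: P, A or U.

    Both-positive is a hard control violation (never silently resolved);
    both-negative is unresolved, because absence is itself a positive
    junction amplification.
    """
    p = presence_result.positive if presence_result else False
    a = absence_result.positive if absence_result else False
    if p and a:
        raise ControlViolationError(
            f"presence and absence reactions both positive for "
            f"{presence_result.genome_id}/{presence_result.pathway_id}"
        )
    if p:
        return "P"
    if a:
        return "A"
    return "U"


@dataclass
class GenotypeMatrix:
    cells: pd.DataFrame  # samples x pathways, values in {P, A, U}
    provenance: dict = field(default_factory=dict)

    def prevalence(self) -> pd.Series:
        return (self.cells == "P").sum() / (self.cells != "U").sum()

    def recovery(self, truth: pd.DataFrame) -> float:
        """Fraction of resolvable cells matching a boolean truth matrix."""
        resolved = self.cells != "U"
        if not resolved.to_numpy().any():
            return float("nan")
        truth_states = truth.map(lambda v: "P" if v else "A")
        agree = (self.cells == truth_states) & resolved
        return float(agree.to_numpy().sum() / resolved.to_numpy().sum())


def screen_genomes(
    genomes: dict[str, str],
    assays: dict[str, AssayPair],
) -> GenotypeMatrix:
    """Run every assay pair on every genome and assemble the matrix."""
    pathways = list(assays)
    rows = {}
    provenance = {}
    for gid, gseq in genomes.items():
        row = {}
        for pid in pathways:
            pair = assays[pid]
            pres = virtual_pcr(gseq, pair.presence, gid) if pair.presence else None
            absn = virtual_pcr(gseq, pair.absence, gid) if pair.absence else None
            row[pid] = genotype(pres, absn)
            provenance[(gid, pid)] = (pres, absn)
        rows[gid] = row
    cells = pd.DataFrame.from_dict(rows, orient="index")[pathways]
    return GenotypeMatrix(cells, provenance)


# ---------------------------------------------------------------------------
# co-occurrence permutation test


def cooccurrence_test(
    matrix: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Pairwise co-presence association under a fixed-margin null.

    Columns are permuted independently (preserving each pathway's
    prevalence exactly); the observed co-presence count is compared to
    the permutation distribution. ``p_value`` is the two-sided add-one
    p (never anti-conservative, but discrete counts make it markedly
    conservative); ``p_value_mid`` is the centered mid-p variant, which
    is calibrated to the nominal level. Degenerate columns (a single
    state among resolved samples) are skipped with a note.
    """
    if matrix.shape[1] < 2:
        raise ValueError("co-occurrence test needs >= 2 pathways")
    rng = np.random.default_rng(seed)
    cols = list(matrix.columns)
    present = (matrix == "P").to_numpy() if matrix.dtypes.iloc[0] == object else matrix.astype(bool).to_numpy()
    resolved = (matrix != "U").to_numpy() if matrix.dtypes.iloc[0] == object else np.ones_like(present, bool)
    rows = []
    for i, j in itertools.combinations(range(len(cols)), 2):
        ok = resolved[:, i] & resolved[:, j]
        x = present[ok, i]
        y = present[ok, j]
        note = ""
        if x.all() or (~x).all() or y.all() or (~y).all():
            rows.append(dict(pathway_a=cols[i], pathway_b=cols[j],
                             observed=int((x & y).sum()), p_value=np.nan,
                             p_value_mid=np.nan, note="degenerate-column"))
            continue
        obs = int((x & y).sum())
        null = np.empty(n_perm, dtype=int)
        for t in range(n_perm):
            null[t] = int((rng.permutation(x) & rng.permutation(y)).sum())
        p_hi = (1 + int((null >= obs).sum())) / (n_perm + 1)
        p_lo = (1 + int((null <= obs).sum())) / (n_perm + 1)
        p = min(1.0, 2 * min(p_hi, p_lo))
        center = null.mean()
        dist = np.abs(null - center)
        d_obs = abs(obs - center)
        p_mid = (
            0.5 + int((dist > d_obs).sum()) + 0.5 * int((dist == d_obs).sum())
        ) / (n_perm + 1)
        rows.append(dict(pathway_a=cols[i], pathway_b=cols[j],
                         observed=obs, p_value=p, p_value_mid=p_mid, note=note))
    return pd.DataFrame(
        rows,
        columns=["pathway_a", "pathway_b", "observed", "p_value", "p_value_mid", "note"],
    )
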