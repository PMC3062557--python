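"""Cyanobactin product chemistry: formulas, monoisotopic masses, ladders.

Cyanobactins are head-to-tail (N–C) macrocyclic ribosomal peptides. Their
mature products differ from the plain macrocycle by a small set of
post-translational modifications:

- heterocyclization of Cys/Ser/Thr side chains to azolines (net loss of
  H2O), optionally oxidized to azoles (further loss of H2);
- prenylation of Ser/Thr hydroxyls (gain of one isoprene unit, C5H8,
  monoisotopic 68.0626 Da), which produces a characteristic neutral-loss
  ladder in tandem MS.

This module turns a core amino-acid sequence plus a modification spec
into a molecular formula, a singly protonated monoisotopic m/z, a
fragment ladder, and ppm errors against observed peaks. All arithmetic
is exact element-count bookkeeping; masses come from the fixed
monoisotopic table below.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

__all__ = [
    "Formula",
    "ModificationSpec",
    "CyanobactinProduct",
    "FragmentLadder",
    "MatchResult",
    "residue_formula",
    "peptide_formula",
    "apply_spec",
    "monoisotopic_mz",
    "ppm_error",
    "isoprene_ladder",
    "enumerate_candidates",
    "match_observed",
    "make_product",
]

#: Monoisotopic element masses (Da). Fixed so printed literature values
#: are reproduced to <=5e-5 Da.
MONOISOTOPIC_MASS = {
    "C": 12.000000,
    "H": 1.00782503,
    "N": 14.00307401,
    "O": 15.99491462,
    "S": 31.97207069,
}

#: Mass of a proton (Da); all reported m/z here are [M+H]+ unless the
#: charge is explicitly 0.
PROTON_MASS = 1.00727646

SUPPORTED_ELEMENTS = tuple(MONOISOTOPIC_MASS)

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class InvalidResidueError(ValueError):
    """Raised for amino-acid letters outside the 20 standard residues."""


class FormulaError(ValueError):
    """Raised for unsupported elements or negative element counts."""


@dataclass(frozen=True)
class Formula:
    """An element → count map for a neutral molecule (C,H,N,O,S only).

    Supports element-wise ``+``/``-`` and integer ``*``. Subtraction
    below zero raises :class:`FormulaError`: a fragment can never
    contain atoms its parent lacks.
    """

    counts: tuple[tuple[str, int], ...]

    def __init__(self, counts: dict[str, int] | tuple[tuple[str, int], ...] = ()):
        items = dict(counts)
        for el, n in items.items():
            if el not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unsupported element: {el!r}")
            if n < 0:
                raise FormulaError(f"negative count for {el}: {n}")
        clean = tuple((el, items[el]) for el in SUPPORTED_ELEMENTS if items.get(el, 0))
        object.__setattr__(self, "counts", clean)

    @classmethod
    def parse(cls, text: str) -> "Formula":
        """Parse ``"C38H62N6O8S"`` style strings."""
        counts: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_RE.finditer(text):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise FormulaError(f"cannot parse formula {text!r}")
            counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
            pos = m.end()
        if pos != len(text) or not counts:
            raise FormulaError(f"cannot parse formula {text!r}")
        return cls(counts)

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __getitem__(self, el: str) -> int:
        return dict(self.counts).get(el, 0)

    def __add__(self, other: "Formula") -> "Formula":
        a, b = self.as_dict(), other.as_dict()
        return Formula({el: a.get(el, 0) + b.get(el, 0) for el in set(a) | set(b)})

    def __sub__(self, other: "Formula") -> "Formula":
        a, b = self.as_dict(), other.as_dict()
        out = {el: a.get(el, 0) - b.get(el, 0) for el in set(a) | set(b)}
        bad = [el for el, n in out.items() if n < 0]
        if bad:
            raise FormulaError(f"subtraction yields negative counts for {sorted(bad)}")
        return Formula(out)

    def __mul__(self, k: int) -> "Formula":
        if k < 0:
            raise FormulaError("cannot multiply a formula by a negative integer")
        return Formula({el: n * k for el, n in self.counts})

    __rmul__ = __mul__

    def hill(self) -> str:
        """Hill-order string: C, H, then remaining elements alphabetically."""
        d = self.as_dict()
        order = [el for el in ("C", "H") if el in d] + sorted(set(d) - {"C", "H"})
        return "".join(f"{el}{d[el] if d[el] != 1 else ''}" for el in order)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.hill()


WATER = Formula({"H": 2, "O": 1})
H2 = Formula({"H": 2})
ISOPRENE = Formula({"C": 5, "H": 8})

#: Residue formulas (amino-acid monomer minus water), standard 20.
RESIDUE_FORMULAS = {
    "G": Formula({"C": 2, "H": 3, "N": 1, "O": 1}),
    "A": Formula({"C": 3, "H": 5, "N": 1, "O": 1}),
    "S": Formula({"C": 3, "H": 5, "N": 1, "O": 2}),
    "P": Formula({"C": 5, "H": 7, "N": 1, "O": 1}),
    "V": Formula({"C": 5, "H": 9, "N": 1, "O": 1}),
    "T": Formula({"C": 4, "H": 7, "N": 1, "O": 2}),
    "C": Formula({"C": 3, "H": 5, "N": 1, "O": 1, "S": 1}),
    "L": Formula({"C": 6, "H": 11, "N": 1, "O": 1}),
    "I": Formula({"C": 6, "H": 11, "N": 1, "O": 1}),
    "N": Formula({"C": 4, "H": 6, "N": 2, "O": 2}),
    "D": Formula({"C": 4, "H": 5, "N": 1, "O": 3}),
    "Q": Formula({"C": 5, "H": 8, "N": 2, "O": 2}),
    "K": Formula({"C": 6, "H": 12, "N": 2, "O": 1}),
    "E": Formula({"C": 5, "H": 7, "N": 1, "O": 3}),
    "M": Formula({"C": 5, "H": 9, "N": 1, "O": 1, "S": 1}),
    "H": Formula({"C": 6, "H": 7, "N": 3, "O": 1}),
    "F": Formula({"C": 9, "H": 9, "N": 1, "O": 1}),
    "R": Formula({"C": 6, "H": 12, "N": 4, "O": 1}),
    "Y": Formula({"C": 9, "H": 9, "N": 1, "O": 2}),
    "W": Formula({"C": 11, "H": 10, "N": 2, "O": 1}),
}

HETEROCYCLIZABLE = frozenset("CST")
PRENYLATABLE = frozenset("ST")


def residue_formula(aa: str) -> Formula:
    """Formula of one amino-acid residue (monomer minus water)."""
    try:
        return RESIDUE_FORMULAS[aa.upper()]
    except KeyError:
        raise InvalidResidueError(f"not a standard amino acid: {aa!r}") from None


def peptide_formula(seq: str, topology: str = "head_to_tail_cyclic") -> Formula:
    """Neutral formula of an unmodified peptide.

    ``linear`` adds one water to the residue sum; ``head_to_tail_cyclic``
    does not (the macrocyclizing condensation removes it).
    """
    if not seq:
        raise InvalidResidueError("empty peptide sequence")
    if topology not in ("linear", "head_to_tail_cyclic"):
        raise ValueError(f"unknown topology: {topology!r}")
    total = Formula()
    for aa in seq:
        total = total + residue_formula(aa)
    if topology == "linear":
        total = total + WATER
    return total


@dataclass(frozen=True)
class ModificationSpec:
    """Post-translational modification state of one candidate product.

    ``heterocycles`` is a list of ``(position, ring_state)`` with
    ring_state ``azoline`` (−H2O) or ``azole`` (−H2O −H2); positions are
    0-based indexes into the core and must hold Cys/Ser/Thr.
    ``n_prenyl`` isoprene units are added at Ser/Thr; the exact sites
    are frequently undetermined by MS, so ``prenyl_sites`` is optional.
    """

    macrocyclic: bool = True
    heterocycles: tuple[tuple[int, str], ...] = ()
    n_prenyl: int = 0
    prenyl_sites: tuple[int, ...] | None = None

    def __post_init__(self):
        object.__setattr__(self, "heterocycles", tuple(self.heterocycles))
        if self.prenyl_sites is not None:
            object.__setattr__(self, "prenyl_sites", tuple(self.prenyl_sites))
        for _, state in self.heterocycles:
            if state not in ("azoline", "azole"):
                raise ValueError(f"unknown ring state: {state!r}")
        if self.n_prenyl < 0:
            raise ValueError("n_prenyl must be >= 0")

    @property
    def n_modifications(self) -> int:
        return len(self.heterocycles) + self.n_prenyl

    def validate(self, core: str) -> None:
        for pos, _ in self.heterocycles:
            if not 0 <= pos < len(core) or core[pos] not in HETEROCYCLIZABLE:
                raise ValueError(
                    f"heterocycle at position {pos} requires Cys/Ser/Thr in {core!r}"
                )
        n_st = sum(core.count(aa) for aa in PRENYLATABLE)
        if self.n_prenyl > n_st:
            raise ValueError(
                f"{self.n_prenyl} prenyls exceed the {n_st} Ser/Thr in {core!r}"
            )
        if self.prenyl_sites is not None:
            if len(self.prenyl_sites) != self.n_prenyl:
                raise ValueError("prenyl_sites length must equal n_prenyl")
            for pos in self.prenyl_sites:
                if not 0 <= pos < len(core) or core[pos] not in PRENYLATABLE:
                    raise ValueError(
                        f"prenyl site {pos} requires Ser/Thr in {core!r}"
                    )

    def describe(self) -> str:
        het = "+".join(f"{p}:{s}" for p, s in self.heterocycles) or "none"
        return (
            f"{'cyclo' if self.macrocyclic else 'linear'};"
            f"het={het};prenyl={self.n_prenyl}"
        )


def apply_spec(base: Formula, spec: ModificationSpec, core: str) -> Formula:
    """Apply a modification spec to an unmodified peptide formula.

    Each azoline subtracts H2O; each azole subtracts H2O then H2
    (oxidation); each prenyl adds C5H8.
    """
    spec.validate(core)
    out = base
    for _, state in spec.heterocycles:
        out = out - WATER
        if state == "azole":
            out = out - H2
    out = out + spec.n_prenyl * ISOPRENE
    return out


def monoisotopic_mz(formula: Formula, charge: int = 1) -> float:
    """Monoisotopic m/z of ``formula`` carrying ``charge`` extra protons.

    ``charge=0`` gives the neutral monoisotopic mass.
    """
    mass = sum(MONOISOTOPIC_MASS[el] * n for el, n in formula.counts)
    mass += charge * PROTON_MASS
    return mass / charge if charge > 1 else mass


def ppm_error(observed: float, predicted: float) -> float:
    """(observed − predicted) / predicted × 1e6."""
    if predicted <= 0:
        raise ValueError("predicted mass must be positive")
    return (observed - predicted) / predicted * 1e6


@dataclass(frozen=True)
class CyanobactinProduct:
    """One fully specified candidate product and its derived quantities."""

    core: str
    spec: ModificationSpec
    formula: Formula = field(compare=False)
    neutral_mass: float = field(compare=False)
    mz_mh: float = field(compare=False)

    @property
    def n_prenyl(self) -> int:
        return self.spec.n_prenyl


def make_product(core: str, spec: ModificationSpec) -> CyanobactinProduct:
    topology = "head_to_tail_cyclic" if spec.macrocyclic else "linear"
    formula = apply_spec(peptide_formula(core, topology), spec, core)
    return CyanobactinProduct(
        core=core,
        spec=spec,
        formula=formula,
        neutral_mass=monoisotopic_mz(formula, charge=0),
        mz_mh=monoisotopic_mz(formula, charge=1),
    )


@dataclass(frozen=True)
class FragmentLadder:
    """Isoprene neutral-loss ladder: (k lost, formula, [M+H−k·C5H8]+)."""

    steps: tuple[tuple[int, Formula, float], ...]

    def mz_values(self) -> list[float]:
        return [mz for _, _, mz in self.steps]


def isoprene_ladder(product: CyanobactinProduct) -> FragmentLadder:
    """Sequential loss of every prenyl group as neutral isoprene.

    The ladder has ``n_prenyl + 1`` rungs including the intact parent.
    """
    steps = []
    formula = product.formula
    for k in range(product.n_prenyl + 1):
        if k:
            formula = formula - ISOPRENE
        steps.append((k, formula, monoisotopic_mz(formula, charge=1)))
    return FragmentLadder(steps=tuple(steps))


def enumerate_candidates(core: str, pathway_class: str) -> list[CyanobactinProduct]:
    """All distinct-formula modification states for a core sequence.

    ``tru``-class chemistry: the Cys (if any) is heterocyclized to a
    thiazoline, and 0..(#Ser+#Thr) prenyl groups are possible; MS cannot
    distinguish prenyl placement, so candidates are enumerated by count.

    ``pat``-class chemistry: Cys becomes a thiazole (oxidized) and each
    Ser/Thr may or may not carry an azoline; no prenylation. Candidates
    are deduplicated by formula.
    """
    if not core:
        raise InvalidResidueError("empty core sequence")
    if pathway_class not in ("tru", "pat"):
        raise ValueError(f"unknown pathway class: {pathway_class!r}")
    cys = [i for i, aa in enumerate(core) if aa == "C"]
    st = [i for i, aa in enumerate(core) if aa in PRENYLATABLE]
    candidates: list[CyanobactinProduct] = []
    seen: set[tuple[tuple[str, int], ...]] = set()
    if pathway_class == "tru":
        het = tuple((i, "azoline") for i in cys)
        for n_prenyl in range(len(st) + 1):
            prod = make_product(
                core, ModificationSpec(heterocycles=het, n_prenyl=n_prenyl)
            )
            if prod.formula.counts not in seen:
                seen.add(prod.formula.counts)
                candidates.append(prod)
    else:
        het_cys = tuple((i, "azole") for i in cys)
        for n_ring in range(len(st) + 1):
            for sites in itertools.combinations(st, n_ring):
                het = het_cys + tuple((i, "azoline") for i in sites)
                prod = make_product(core, ModificationSpec(heterocycles=het))
                if prod.formula.counts not in seen:
                    seen.add(prod.formula.counts)
                    candidates.append(prod)
    return candidates


@dataclass(frozen=True)
class MatchResult:
    observed_mz: float
    candidate: CyanobactinProduct | None
    ppm: float | None
    matched: bool


def match_observed(
    observed_mz: float,
    candidates: list[CyanobactinProduct],
    tol_ppm: float = 5.0,
) -> MatchResult:
    """Best candidate for an observed [M+H]+ peak.

    Minimizes |ppm error|; ties break toward fewer modifications. If
    every candidate exceeds ``tol_ppm`` the result is flagged unmatched.
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    scored = sorted(
        candidates,
        key=lambda c: (abs(ppm_error(observed_mz, c.mz_mh)), c.spec.n_modifications),
    )
    best = scored[0]
    best_ppm = ppm_error(observed_mz, best.mz_mh)
    if abs(best_ppm) > tol_ppm:
        return MatchResult(observed_mz, None, None, False)
    return MatchResult(observed_mz, best, best_ppm, True)
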