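"""Exact-mass engine for macrocyclic peptide natural products.

Everything in this package that touches a mass goes through this module:
elemental formulas with optional heavy-isotope substitutions, residue and
peptide compositions (linear or head-to-tail cyclic), a modification algebra
(prenyl, geranyl, disulfide, methionine sulfoxide, carbamidomethyl-cysteine),
stable-isotope label shifts, and an exhaustive elemental-formula search for
unexplained mass deltas.

Monoisotopic atomic masses are embedded to 8+ decimals (CODATA/AME values);
only C, H, N, O, S are supported — peptides of the 20 standard amino acids
and their isoprenoid/sulfur chemistry need nothing else.

Nominal masses follow low-resolution ion-trap reporting conventions: the
nominal m/z of an ion is the *truncated* (floored) monoisotopic value, while
the nominal value of a mass *difference* (a label shift, a neutral loss, a
derivatization delta) is the rounded one. The two conventions reproduce the
integer masses low-resolution instruments print for heavy peptide ions,
where the accumulated mass defect pushes the decimal part above 0.5.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from itertools import product as _cartesian
from typing import Iterable, Iterator, Mapping

__all__ = [
    "ElementalFormula",
    "IsotopeLabel",
    "PeptideProduct",
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "ISOTOPE_DELTAS",
    "MODIFICATIONS",
    "RESIDUE_FORMULAS",
    "residue_formula",
    "peptide_formula",
    "monoisotopic_mass",
    "protonated_mz",
    "nominal_mz",
    "nominal_shift",
    "apply_modifications",
    "isotope_shift",
    "infer_atom_count",
    "formula_search",
    "FormulaCandidate",
    "AtomCountResult",
]

# Monoisotopic atomic masses, Da.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
}

PROTON_MASS = 1.00727646688

# Heavy-isotope mass increments over the light (monoisotopic) nuclide, Da.
ISOTOPE_DELTAS: dict[str, tuple[str, float]] = {
    "15N": ("N", 0.9970348941),
    "34S": ("S", 1.9957959000),
    "13C": ("C", 1.0033548378),
    "2H": ("H", 1.0062767458),
    "18O": ("O", 2.0042449924),
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalFormula:
    """An element -> count map, the unit of all mass arithmetic.

    ``isotope_subs`` records how many atoms of an element are replaced by a
    named heavy isotope (e.g. ``{"15N": 11}``); substituted atoms keep their
    entry in ``counts`` and contribute the heavy-isotope mass instead.
    """

    counts: Mapping[str, int] = field(default_factory=dict)
    isotope_subs: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {e: int(n) for e, n in self.counts.items() if n != 0}
        for e, n in clean.items():
            if e not in MONOISOTOPIC_MASS:
                raise ValueError(f"unsupported element {e!r}")
            if n < 0:
                raise ValueError(f"negative count for element {e}: {n}")
        subs = {iso: int(n) for iso, n in self.isotope_subs.items() if n != 0}
        for iso, n in subs.items():
            if iso not in ISOTOPE_DELTAS:
                raise ValueError(f"unknown isotope {iso!r}")
            elem = ISOTOPE_DELTAS[iso][0]
            if n < 0 or n > clean.get(elem, 0):
                raise ValueError(
                    f"isotope substitution {iso} x{n} exceeds {elem} count "
                    f"{clean.get(elem, 0)}"
                )
        object.__setattr__(self, "counts", dict(sorted(clean.items())))
        object.__setattr__(self, "isotope_subs", dict(sorted(subs.items())))

    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        """Parse a plain formula string like ``C5H8O`` or ``H2O``."""
        text = text.strip()
        if not text:
            return cls()
        counts: Counter[str] = Counter()
        pos = 0
        for m in _FORMULA_TOKEN.finditer(text):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {text!r} at {text[pos:]!r}")
            counts[m.group(1)] += int(m.group(2) or 1)
            pos = m.end()
        if pos != len(text):
            raise ValueError(f"cannot parse formula {text!r} at {text[pos:]!r}")
        return cls(counts)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        counts = Counter(self.counts)
        counts.update(other.counts)
        subs = Counter(self.isotope_subs)
        subs.update(other.isotope_subs)
        return ElementalFormula(counts, subs)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        counts = Counter(self.counts)
        counts.subtract(other.counts)
        subs = Counter(self.isotope_subs)
        subs.subtract(other.isotope_subs)
        return ElementalFormula(counts, subs)  # validates non-negativity

    def __mul__(self, k: int) -> "ElementalFormula":
        if not isinstance(k, int) or k < 0:
            raise ValueError("formula multiplier must be a non-negative integer")
        return ElementalFormula(
            {e: n * k for e, n in self.counts.items()},
            {i: n * k for i, n in self.isotope_subs.items()},
        )

    __rmul__ = __mul__

    def with_full_label(self, isotope: str) -> "ElementalFormula":
        """Return a copy with every atom of the isotope's element substituted."""
        elem = ISOTOPE_DELTAS[isotope][0]
        subs = dict(self.isotope_subs)
        subs[isotope] = self.counts.get(elem, 0)
        return ElementalFormula(self.counts, subs)

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __str__(self) -> str:
        # CHNOS order, familiar from peptide chemistry
        order = ["C", "H", "N", "O", "S"]
        parts = [
            f"{e}{self.counts[e] if self.counts[e] != 1 else ''}"
            for e in order
            if e in self.counts
        ]
        return "".join(parts) or "(empty)"


@dataclass(frozen=True)
class IsotopeLabel:
    """A stable-isotope feeding experiment: which element, which heavy
    nuclide, the per-atom mass increment, and the labelling enrichment.

    Culture media in labelling experiments are 90-98 atom% enriched, but
    observed shifts are interpreted as complete labelling, so the default
    enrichment is 1.0.
    """

    element: str
    heavy_isotope: str
    per_atom_delta: float
    enrichment: float = 1.0

    def __post_init__(self) -> None:
        if self.per_atom_delta <= 0:
            raise ValueError("per_atom_delta must be positive")
        if not 0.0 <= self.enrichment <= 1.0:
            raise ValueError("enrichment must lie in [0, 1]")

    @classmethod
    def from_name(cls, isotope: str, enrichment: float = 1.0) -> "IsotopeLabel":
        elem, delta = ISOTOPE_DELTAS[isotope]
        return cls(elem, isotope, delta, enrichment)


def _load_residues() -> dict[str, ElementalFormula]:
    table: dict[str, ElementalFormula] = {}
    text = resources.files("piriminer.data").joinpath("residues.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        code, _name, formula = line.split("\t")
        table[code] = ElementalFormula.parse(formula)
    if len(table) != 20:
        raise RuntimeError("residue table must contain exactly the 20 standard residues")
    return table


def _load_modifications() -> dict[str, tuple[ElementalFormula, ElementalFormula]]:
    table: dict[str, tuple[ElementalFormula, ElementalFormula]] = {}
    text = resources.files("piriminer.data").joinpath("modifications.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, add, remove = line.split("\t")
        table[name] = (
            ElementalFormula.parse("" if add == "-" else add),
            ElementalFormula.parse("" if remove == "-" else remove),
        )
    return table


#: residue (dehydrated monomer) compositions for the 20 standard amino acids
RESIDUE_FORMULAS: dict[str, ElementalFormula] = _load_residues()

#: modification name -> (formula added, formula removed) per instance
MODIFICATIONS: dict[str, tuple[ElementalFormula, ElementalFormula]] = _load_modifications()

WATER = ElementalFormula.parse("H2O")


def residue_formula(aa: str) -> ElementalFormula:
    """Composition of one amino-acid residue (monomer minus water)."""
    try:
        return RESIDUE_FORMULAS[aa]
    except KeyError:
        raise ValueError(
            f"unknown amino-acid code {aa!r}; only the 20 standard one-letter "
            "codes are supported"
        ) from None


def peptide_formula(core: str, topology: str = "cyclic") -> ElementalFormula:
    """Elemental composition of a peptide.

    ``cyclic`` means head-to-tail macrocyclization: the chain condenses onto
    itself, so the composition is the plain sum of residue formulas with no
    terminal water. ``linear`` adds one H2O for the free termini.
    """
    if not core:
        raise ValueError("empty peptide sequence")
    if topology not in ("cyclic", "linear"):
        raise ValueError(f"topology must be 'cyclic' or 'linear', got {topology!r}")
    total = ElementalFormula()
    for aa in core:
        total = total + residue_formula(aa)
    if topology == "linear":
        total = total + WATER
    return total


def monoisotopic_mass(f: ElementalFormula) -> float:
    """Monoisotopic mass in Da, with heavy-isotope substitutions applied."""
    mass = sum(MONOISOTOPIC_MASS[e] * n for e, n in f.counts.items())
    mass += sum(ISOTOPE_DELTAS[iso][1] * n for iso, n in f.isotope_subs.items())
    return mass


def protonated_mz(f: ElementalFormula, z: int = 1) -> float:
    """m/z of the [M + zH]^z+ ion."""
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    return (monoisotopic_mass(f) + z * PROTON_MASS) / z


def nominal_mz(mz: float) -> int:
    """Integer m/z as a low-resolution trap instrument prints an ion.

    Truncation, not rounding: for peptide ions above ~1.2 kDa the accumulated
    mass defect exceeds 0.5 Da, and trap readouts quote the integer part.
    """
    return math.floor(mz)


def nominal_shift(delta: float) -> int:
    """Integer value of a mass difference (shift/loss), round-half-up."""
    return math.floor(abs(delta) + 0.5) * (1 if delta >= 0 else -1)


@dataclass(frozen=True)
class PeptideProduct:
    """A core peptide with topology, a modification multiset, and a charge.

    The modification names are keys of :data:`MODIFICATIONS`. Invariants
    mirror the chemistry: a disulfide needs a free cysteine pair, sulfoxide
    needs a methionine, and a carbamidomethylated cysteine cannot also sit in
    a bridge (derivatization implies prior reduction).
    """

    core: str
    topology: str = "cyclic"
    mods: Mapping[str, int] = field(default_factory=dict)
    charge: int = 1

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        mods = {m: int(n) for m, n in self.mods.items() if n != 0}
        for m, n in mods.items():
            if m not in MODIFICATIONS:
                raise ValueError(f"unknown modification {m!r}")
            if n < 0:
                raise ValueError(f"negative count for modification {m}")
        object.__setattr__(self, "mods", dict(sorted(mods.items())))
        n_cys = self.core.count("C")
        n_met = self.core.count("M")
        ss = mods.get("disulfide", 0)
        cam = mods.get("cam_cys", 0)
        if ss > n_cys // 2:
            raise ValueError(
                f"{ss} disulfide(s) need {2 * ss} cysteines; core has {n_cys}"
            )
        if mods.get("met_sulfoxide", 0) > n_met:
            raise ValueError("more methionine sulfoxides than methionines")
        if cam > n_cys:
            raise ValueError("more carbamidomethyl-cysteines than cysteines")
        if 2 * ss + cam > n_cys:
            raise ValueError(
                "disulfide and carbamidomethyl assignments overlap on a "
                "cysteine pair (derivatization implies prior reduction)"
            )

    def n_isoprenoid_units(self) -> int:
        """Isoprene (C5) unit count: geranyl carries two."""
        return self.mods.get("prenyl", 0) + 2 * self.mods.get("geranyl", 0)

    def n_mod_instances(self) -> int:
        return sum(self.mods.values())

    def formula(self) -> ElementalFormula:
        return apply_modifications(self)

    def mz(self) -> float:
        return protonated_mz(self.formula(), self.charge)

    def label(self) -> str:
        mods = ",".join(
            f"{m}" if n == 1 else f"{n}x{m}" for m, n in sorted(self.mods.items())
        )
        return f"{self.core}[{self.topology}]" + (f"+{mods}" if mods else "")


def apply_modifications(p: PeptideProduct) -> ElementalFormula:
    """Composition of the modified product.

    Per instance: prenyl +C5H8, geranyl +C10H16, disulfide -H2,
    met_sulfoxide +O, cam_cys +C2H3NO on the reduced thiol. Relative to the
    disulfide-bridged form, derivatizing a bridge therefore gains
    2H + 2(C2H3NO) = 116 Da nominal, the diagnostic derivatization shift.
    """
    total = peptide_formula(p.core, p.topology)
    for name, n in p.mods.items():
        add, remove = MODIFICATIONS[name]
        total = total + add * n - remove * n
    return total


def isotope_shift(f: ElementalFormula, label: IsotopeLabel) -> float:
    """Expected mass increase of ``f`` under a full labelling experiment."""
    if label.element not in MONOISOTOPIC_MASS:
        raise ValueError(f"unsupported element {label.element!r}")
    return f[label.element] * label.per_atom_delta * label.enrichment


def nominal_isotope_shift(f: ElementalFormula, label: IsotopeLabel) -> int:
    return nominal_shift(isotope_shift(f, label))


@dataclass(frozen=True)
class AtomCountResult:
    """Labelled-atom count inferred from an observed label shift."""

    n_atoms: int
    residual: float
    consistent: bool


def infer_atom_count(
    observed_shift: float,
    label: IsotopeLabel,
    tolerance_fraction: float = 0.3,
) -> AtomCountResult:
    """How many atoms of the labelled element explain an observed shift.

    Divides by the per-atom increment (scaled by enrichment), rounds to the
    nearest integer, and flags inconsistency when the residual exceeds
    ``tolerance_fraction`` of one per-atom increment.
    """
    if not math.isfinite(observed_shift):
        raise ValueError("observed shift must be finite")
    if observed_shift < 0:
        raise ValueError("observed shift must be >= 0")
    step = label.per_atom_delta * (label.enrichment or 1.0)
    n = round(observed_shift / step)
    residual = observed_shift - n * step
    return AtomCountResult(n, residual, abs(residual) <= tolerance_fraction * step)


@dataclass(frozen=True)
class FormulaCandidate:
    """One elemental composition matching a target mass."""

    formula: ElementalFormula
    mass: float
    delta_mda: float  # signed, target - candidate
    rdbe: float


def _rdbe(f: ElementalFormula) -> float:
    """Ring-plus-double-bond equivalents for CHNOS (S and O are divalent)."""
    return f["C"] + 1 + (f["N"] - f["H"]) / 2


def formula_search(
    target: float,
    tol_mda: float,
    elements: Iterable[str],
    bounds: Mapping[str, int] | int = 20,
    min_rdbe: float = -0.5,
) -> list[FormulaCandidate]:
    """Exhaustively enumerate elemental compositions near a target mass.

    All integer compositions over ``elements`` within per-element ``bounds``
    are generated; those within ``tol_mda`` of ``target`` and passing a
    chemical-plausibility filter (RDBE >= ``min_rdbe`` and integral or
    half-integral, H <= 2C + 2 + N) are returned sorted by |delta|, then by
    formula string for determinism. Delta is signed as target - candidate.
    """
    elements = sorted(set(elements))
    if not elements:
        raise ValueError("element set must be non-empty")
    for e in elements:
        if e not in MONOISOTOPIC_MASS:
            raise ValueError(f"unsupported element {e!r}")
    if tol_mda <= 0:
        raise ValueError("tolerance must be positive")
    if isinstance(bounds, int):
        bounds = {e: bounds for e in elements}
    tol = tol_mda / 1000.0

    out: list[FormulaCandidate] = []
    ranges = [range(bounds[e] + 1) for e in elements]
    for combo in _cartesian(*ranges):
        if not any(combo):
            continue
        mass = sum(MONOISOTOPIC_MASS[e] * n for e, n in zip(elements, combo))
        if abs(mass - target) > tol:
            continue
        f = ElementalFormula(dict(zip(elements, combo)))
        rdbe = _rdbe(f)
        if rdbe < min_rdbe or (2 * rdbe) % 1 != 0:
            continue
        if f["H"] > 2 * f["C"] + 2 + f["N"]:
            continue
        out.append(FormulaCandidate(f, mass, (target - mass) * 1000.0, rdbe))
    out.sort(key=lambda c: (abs(c.delta_mda), str(c.formula)))
    return out


def iter_formulas(candidates: list[FormulaCandidate]) -> Iterator[str]:
    for c in candidates:
        yield str(c.formula)
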