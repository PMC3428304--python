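"""Variant enumeration and MS peak assignment for cyclic peptide products.

Given a mined core peptide, enumerate the plausible modified macrocycles
(prenyl/geranyl isoprenoids, disulfide bridges, methionine sulfoxide),
assign observed MS1 peaks within a mass tolerance, and annotate matches
with MS2 neutral-loss evidence (68/136 Da isoprenoid losses, the 91 Da
carbamidomethyl-cysteine fragment, the 64 Da methionine-sulfoxide loss)
and stable-isotope label consistency.

Geranyl and two prenyls are isobaric at MS1; a +2-isoprenoid-unit match is
therefore a modification *class*, and both readings are kept. Diagnostic
evidence never creates a match on its own: it only annotates mass matches.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import product as _cartesian
from typing import Sequence

from .chem import (
    IsotopeLabel,
    PeptideProduct,
    infer_atom_count,
    isotope_shift,
    monoisotopic_mass,
    protonated_mz,
)

__all__ = [
    "PeakList",
    "MatchResult",
    "VariantConfig",
    "NEUTRAL_LOSSES",
    "enumerate_variants",
    "match_peaks",
    "detect_neutral_losses",
    "verify_labels",
    "LabelCheck",
]

# Diagnostic neutral losses, Da (monoisotopic).
NEUTRAL_LOSSES: dict[str, float] = {
    "isoprenoid_loss_68": 68.0626,   # C5H8
    "isoprenoid_loss_136": 136.1252,  # C10H16
    "cam_cys_loss_91": 91.0092,      # H2NC(=O)CH2SH
    "metox_loss_64": 63.9983,        # CH3SOH
}


@dataclass(frozen=True)
class PeakList:
    """An m/z-sorted peak list with provenance.

    ``level`` is ``MS1`` or ``MS2``; MS2 lists carry the precursor m/z.
    """

    peaks: tuple[tuple[float, float], ...]
    level: str = "MS1"
    precursor_mz: float | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.level not in ("MS1", "MS2"):
            raise ValueError("level must be 'MS1' or 'MS2'")
        for mz, inten in self.peaks:
            if mz <= 0:
                raise ValueError(f"non-positive m/z {mz}")
            if inten < 0:
                raise ValueError(f"negative intensity {inten}")
        object.__setattr__(
            self, "peaks", tuple(sorted((float(m), float(i)) for m, i in self.peaks))
        )

    def mzs(self) -> list[float]:
        return [m for m, _ in self.peaks]


@dataclass(frozen=True)
class VariantConfig:
    """Caps on the modification search space per core.

    ``max_isoprenoid_units`` counts C5 units with geranyl as two; the
    default of 2 covers every assignment pattern seen in practice
    (unmodified, prenyl, geranyl, double prenyl). Carbamidomethylation is
    derivatization chemistry, not biosynthesis, so it is off by default.
    ``allow_disulfide_with_isoprenoid`` can be switched off to encode the
    hypothesis that a bridge blocks prenylation.
    """

    max_prenyl: int = 2
    max_geranyl: int = 1
    max_isoprenoid_units: int = 2
    include_met_sulfoxide: bool = True
    include_cam_cys: bool = False
    allow_disulfide_with_isoprenoid: bool = True
    charges: tuple[int, ...] = (1,)


@dataclass(frozen=True)
class MatchResult:
    """A (product variant, observed peak) assignment."""

    core: str
    variant: PeptideProduct
    theoretical_mz: float
    observed_mz: float
    delta_mda: float  # signed, observed - theoretical
    evidence: frozenset[str] = frozenset()
    rank: int = 0
    isobaric_readings: tuple[str, ...] = ()


def enumerate_variants(
    core: str, config: VariantConfig = VariantConfig()
) -> list[PeptideProduct]:
    """All modified cyclic products of a core under the configured caps.

    The Cartesian product of per-modification ranges, filtered by the
    combined isoprenoid cap and the chemistry invariants. Deterministic,
    duplicate-free, sorted by (total modifications, label).
    """
    n_cys = core.count("C")
    n_met = core.count("M")
    ranges = [
        range(config.max_prenyl + 1),
        range(config.max_geranyl + 1),
        range(n_cys // 2 + 1),
        range((n_met if config.include_met_sulfoxide else 0) + 1),
        range((n_cys if config.include_cam_cys else 0) + 1),
    ]
    out: list[PeptideProduct] = []
    for pr, ge, ss, ox, cam in _cartesian(*ranges):
        if pr + 2 * ge > config.max_isoprenoid_units:
            continue
        if 2 * ss + cam > n_cys:
            continue
        if not config.allow_disulfide_with_isoprenoid and ss and (pr or ge):
            continue
        mods = {
            "prenyl": pr,
            "geranyl": ge,
            "disulfide": ss,
            "met_sulfoxide": ox,
            "cam_cys": cam,
        }
        for z in config.charges:
            out.append(PeptideProduct(core, "cyclic", mods, charge=z))
    out.sort(key=lambda p: (p.n_mod_instances(), p.charge, p.label()))
    return out


def _isobaric_readings(variant: PeptideProduct) -> tuple[str, ...]:
    """Alternative readings of the isoprenoid load at MS1 resolution."""
    units = variant.n_isoprenoid_units()
    if units < 2:
        return ()
    readings = []
    if variant.mods.get("geranyl", 0):
        readings.append("geranyl")
        readings.append("2x prenyl")
    elif variant.mods.get("prenyl", 0) >= 2:
        readings.append("2x prenyl")
        readings.append("geranyl")
    return tuple(readings)


def match_peaks(
    variants: Sequence[PeptideProduct],
    peaks: PeakList,
    tol_mda: float = 300.0,
) -> list[MatchResult]:
    """Assign MS1 peaks to theoretical variants within a tolerance.

    Every (variant, peak) pair within ``tol_mda`` is reported. Per observed
    peak, matches are ranked by |delta| and ties broken by parsimony (fewer
    modification instances), then by variant label; ranks start at 1. The
    result order is (observed m/z, rank), independent of input order.
    """
    if tol_mda <= 0:
        raise ValueError("tolerance must be positive")
    if peaks.level != "MS1":
        raise ValueError("match_peaks expects an MS1 peak list")
    tol = tol_mda / 1000.0
    theoretical = sorted(
        ((v.mz(), v) for v in variants), key=lambda t: (t[0], t[1].label())
    )
    by_peak: dict[float, list[MatchResult]] = {}
    for obs_mz, _inten in peaks.peaks:
        hits = []
        for theo_mz, v in theoretical:
            if abs(obs_mz - theo_mz) <= tol:
                hits.append(
                    MatchResult(
                        core=v.core,
                        variant=v,
                        theoretical_mz=theo_mz,
                        observed_mz=obs_mz,
                        delta_mda=(obs_mz - theo_mz) * 1000.0,
                        isobaric_readings=_isobaric_readings(v),
                    )
                )
        hits.sort(
            key=lambda m: (
                abs(m.delta_mda),
                m.variant.n_mod_instances(),
                m.variant.label(),
            )
        )
        if hits:
            by_peak[obs_mz] = [replace(m, rank=i + 1) for i, m in enumerate(hits)]
    out: list[MatchResult] = []
    for obs_mz in sorted(by_peak):
        out.extend(by_peak[obs_mz])
    return out


def detect_neutral_losses(
    ms2: PeakList,
    tol: float = 0.3,
    min_rel_intensity: float = 0.05,
) -> frozenset[str]:
    """Diagnostic neutral-loss flags from an MS2 spectrum.

    A loss L is flagged when a fragment sits at ``precursor_mz - L`` within
    ``tol`` (Da; trap-instrument scale) and its intensity is at least
    ``min_rel_intensity`` of the base peak.
    """
    if ms2.precursor_mz is None:
        raise ValueError("MS2 peak list must carry a precursor m/z")
    if not ms2.peaks:
        return frozenset()
    base = max(i for _, i in ms2.peaks) or 1.0
    flags = set()
    for name, loss in NEUTRAL_LOSSES.items():
        expected = ms2.precursor_mz - loss
        for mz, inten in ms2.peaks:
            if abs(mz - expected) <= tol and inten / base >= min_rel_intensity:
                flags.add(name)
                break
    return frozenset(flags)


@dataclass(frozen=True)
class LabelCheck:
    """Consistency of an observed isotope-label shift with a match."""

    predicted_labeled_mz: float
    observed_labeled_mz: float
    shift_error: float  # observed - predicted labelled m/z
    n_atoms_inferred: int
    n_atoms_expected: int
    consistent: bool


def verify_labels(
    match: MatchResult,
    labeled_observed_mz: float,
    label: IsotopeLabel,
    tol: float = 0.3,
) -> LabelCheck:
    """Check a match against a stable-isotope labelling experiment.

    The labelled ion is predicted by adding the full-label shift of the
    variant's formula to its theoretical m/z (singly charged shifts divide
    by charge). The observed shift also yields an independent atom count of
    the labelled element.
    """
    f = match.variant.formula()
    z = match.variant.charge
    shift = isotope_shift(f, label) / z
    predicted = match.theoretical_mz + shift
    observed_shift = max(0.0, (labeled_observed_mz - match.theoretical_mz) * z)
    atoms = infer_atom_count(observed_shift, label)
    expected_atoms = f[label.element]
    consistent = abs(labeled_observed_mz - predicted) <= tol
    return LabelCheck(
        predicted_labeled_mz=predicted,
        observed_labeled_mz=labeled_observed_mz,
        shift_error=labeled_observed_mz - predicted,
        n_atoms_inferred=atoms.n_atoms,
        n_atoms_expected=expected_atoms,
        consistent=consistent and atoms.n_atoms == expected_atoms,
    )
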