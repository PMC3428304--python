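"""Forward model: synthetic precursor genes, clone libraries, and spectra.

Every stage of the discovery pipeline is testable against planted ground
truth generated here. The generator emulates the biological shape of real
cyanobactin data: precursor proteins of roughly 40-55 aa carrying the
conserved leader motif, a hypervariable core of 7-22 residues that
typically ends in proline, and the C-terminal recognition region; clone
libraries with a few dominant cores and a long tail of singletons; and
MS1 peak lists with Gaussian m/z error plus uniform decoy noise inside the
instrument scan range of m/z 300-2200, with MS2 spectra carrying the
diagnostic neutral losses implied by each planted modification.

All generation is a pure function of (seed, config): the same inputs
produce byte-identical FASTA, peak lists and truth tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .chem import PeptideProduct, protonated_mz
from .matching import PeakList
from .mining import LEADER_MOTIF, RECOGNITION_MOTIF, scan_leader_motif

__all__ = ["SimConfig", "TruthRow", "TruthTable", "gen_core",
           "gen_precursor_gene", "gen_clone_library", "gen_peaklists"]

SCAN_RANGE = (300.0, 2200.0)

# aa -> codons, from the standard genetic code
_CODONS: dict[str, list[str]] = {}
for codon, aa in standard_dna_table.forward_table.items():
    _CODONS.setdefault(aa, []).append(codon)
for codons in _CODONS.values():
    codons.sort()

# core alphabet: cysteine and methionine are planted separately so their
# frequency is controlled by the disulfide/methionine fractions
_CORE_ALPHABET = [a for a in sorted(_CODONS) if a not in ("C", "M")]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic generator.

    Defaults follow the observed shape of natural piricyclamide libraries:
    cores of 7-22 aa ending in proline, roughly one core in ten carrying the
    double-cysteine pattern, a Zipf-like clone abundance law, and an
    instrument m/z error of a few mDa (high-accuracy mode).
    """

    seed: int
    n_precursors: int = 20
    n_clones: int = 122
    core_length_range: tuple[int, int] = (7, 22)
    frac_disulfide: float = 0.1
    frac_met: float = 0.15
    end_in_proline: bool = True
    clone_zipf_exponent: float = 1.0
    mz_error_sd_mda: float = 5.0
    n_noise_peaks: int = 20
    # probability that a planted product is prenylated / geranylated
    # (mutually exclusive; the remainder stays unmodified); sulfoxide
    # probability applies per methionine-containing core
    mod_assignment_probs: Mapping[str, float] = field(
        default_factory=lambda: {"prenyl": 0.2, "geranyl": 0.2,
                                 "met_sulfoxide": 0.3}
    )

    def __post_init__(self) -> None:
        lo, hi = self.core_length_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid core length range")
        for name in ("frac_disulfide", "frac_met"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_precursors < 1 or self.n_clones < self.n_precursors:
            raise ValueError(
                "need at least one clone per unique precursor "
                f"({self.n_precursors} precursors, {self.n_clones} clones)"
            )


@dataclass(frozen=True)
class TruthRow:
    """Ground truth for one planted precursor/product."""

    record_id: str
    core: str
    dna: str
    strand: str
    gene_span: tuple[int, int]  # precursor ORF on the forward strand
    mods: Mapping[str, int]
    theoretical_mz: float
    clone_count: int

    def product(self) -> PeptideProduct:
        return PeptideProduct(self.core, "cyclic", dict(self.mods))


@dataclass(frozen=True)
class TruthTable:
    rows: tuple[TruthRow, ...]

    @property
    def total_clones(self) -> int:
        return sum(r.clone_count for r in self.rows)

    def __len__(self) -> int:
        return len(self.rows)


def gen_core(rng: np.random.Generator, cfg: SimConfig) -> str:
    """Sample one core sequence under the configured composition rules.

    A mature core cannot itself contain the recognition site (the protease
    would cleave it), so draws resembling it within one mismatch are
    rejected and resampled.
    """
    lo, hi = cfg.core_length_range
    while True:
        length = int(rng.integers(lo, hi + 1))
        aa = list(rng.choice(_CORE_ALPHABET, size=length))
        if cfg.end_in_proline:
            aa[-1] = "P"
        interior = max(1, length - 1)
        if rng.random() < cfg.frac_disulfide and interior >= 2:
            i, j = rng.choice(interior, size=2, replace=False)
            aa[int(i)], aa[int(j)] = "C", "C"
        if rng.random() < cfg.frac_met:
            free = [k for k in range(interior) if aa[k] != "C"]
            if free:
                aa[int(rng.choice(free))] = "M"
        core = "".join(aa)
        if not scan_leader_motif(core, RECOGNITION_MOTIF, 1):
            return core


def _sample_codons(rng: np.random.Generator, protein: str) -> str:
    return "".join(
        _CODONS[aa][int(rng.integers(len(_CODONS[aa])))] for aa in protein
    )


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _instantiate_motif(rng: np.random.Generator, motif: str) -> str:
    return "".join(
        a if a != "x" else str(rng.choice(_CORE_ALPHABET)) for a in motif
    )


def _revcomp(dna: str) -> str:
    return dna.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def gen_precursor_gene(
    seed_or_rng: int | np.random.Generator, core: str
) -> tuple[str, dict]:
    """Codon-sample one precursor gene for a core and embed it in flanks.

    The protein is prefix + leader motif + core + recognition motif +
    tail, stop-free by construction, placed on a random strand inside
    random flanking DNA; the leader motif abuts the core directly, as the
    interstitial-core extraction convention expects. Returns the DNA and a
    truth dict with the gene span (forward-strand, 0-based half-open) and
    strand.
    """
    for aa in core:
        if aa not in _CODONS:
            raise ValueError(f"invalid core residue {aa!r}")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    prefix = "M" + "".join(rng.choice(_CORE_ALPHABET, size=int(rng.integers(9, 15))))
    tail = "".join(rng.choice(_CORE_ALPHABET, size=int(rng.integers(3, 7))))
    protein = (
        prefix + _instantiate_motif(rng, LEADER_MOTIF)
        + core + RECOGNITION_MOTIF + tail
    )
    gene = _sample_codons(rng, protein)
    left = _random_dna(rng, int(rng.integers(10, 41)))
    right = _random_dna(rng, int(rng.integers(10, 41)))
    forward = left + gene + right
    strand = "+" if rng.random() < 0.5 else "-"
    dna = forward if strand == "+" else _revcomp(forward)
    start = len(left) if strand == "+" else len(right)
    truth = {
        "core": core,
        "protein": protein,
        "strand": strand,
        "gene_span": (start, start + len(gene)),
    }
    return dna, truth


def _assign_mods(rng: np.random.Generator, core: str, cfg: SimConfig) -> dict[str, int]:
    probs = cfg.mod_assignment_probs
    mods = {"prenyl": 0, "geranyl": 0, "disulfide": 0, "met_sulfoxide": 0}
    u = rng.random()
    if u < probs.get("prenyl", 0.0):
        mods["prenyl"] = 1
    elif u < probs.get("prenyl", 0.0) + probs.get("geranyl", 0.0):
        mods["geranyl"] = 1
    if core.count("C") >= 2:
        mods["disulfide"] = 1
    if "M" in core and rng.random() < probs.get("met_sulfoxide", 0.0):
        mods["met_sulfoxide"] = 1
    return {m: n for m, n in mods.items() if n}


def gen_clone_library(cfg: SimConfig) -> tuple[list[tuple[str, str]], TruthTable]:
    """Generate a clone library FASTA and its ground-truth table.

    ``n_precursors`` unique cores receive clone counts from a Zipf-like
    abundance law (every core keeps at least one clone); the FASTA carries
    one record per clone, all clones of a core sharing the same template
    gene as in a real amplicon library.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.core_length_range
    if cfg.n_precursors > len(_CORE_ALPHABET) ** max(1, lo - 1):
        raise ValueError("more unique cores requested than the length space holds")
    cores: list[str] = []
    seen = set()
    while len(cores) < cfg.n_precursors:
        c = gen_core(rng, cfg)
        if c not in seen:
            seen.add(c)
            cores.append(c)
    # Zipf-like clone counts: one guaranteed clone per core, remainder multinomial
    ranks = np.arange(1, cfg.n_precursors + 1, dtype=float)
    w = ranks ** (-cfg.clone_zipf_exponent)
    w /= w.sum()
    extra = rng.multinomial(cfg.n_clones - cfg.n_precursors, w)
    counts = extra + 1

    fasta: list[tuple[str, str]] = []
    rows: list[TruthRow] = []
    for i, (core, count) in enumerate(zip(cores, counts)):
        dna, truth = gen_precursor_gene(rng, core)
        mods = _assign_mods(rng, core, cfg)
        product = PeptideProduct(core, "cyclic", mods)
        rec_id = f"p{i:03d}"
        for j in range(count):
            fasta.append((f"{rec_id}_clone{j:03d}", dna))
        rows.append(
            TruthRow(
                record_id=rec_id,
                core=core,
                dna=dna,
                strand=truth["strand"],
                gene_span=truth["gene_span"],
                mods=mods,
                theoretical_mz=protonated_mz(product.formula(), 1),
                clone_count=int(count),
            )
        )
    return fasta, TruthTable(tuple(rows))


def gen_peaklists(
    truth: TruthTable, cfg: SimConfig
) -> tuple[PeakList, dict[str, PeakList]]:
    """Simulate the MS1 survey and per-product MS2 spectra.

    Each planted product contributes one MS1 peak at its theoretical m/z
    plus Gaussian error (sd ``mz_error_sd_mda``), with intensity scaled by
    clone count; ``n_noise_peaks`` uniform decoys are added inside the
    scan range. Each MS2 spectrum holds the precursor and the diagnostic
    neutral-loss fragments implied by the planted modifications.
    """
    if not len(truth):
        raise ValueError("truth table is empty")
    rng = np.random.default_rng(cfg.seed + 1)  # spectra stream, distinct from genes
    ms1_peaks: list[tuple[float, float]] = []
    ms2: dict[str, PeakList] = {}
    for row in truth.rows:
        err = rng.normal(0.0, cfg.mz_error_sd_mda / 1000.0)
        obs = row.theoretical_mz + err
        ms1_peaks.append((obs, 100.0 * row.clone_count))
        frags: list[tuple[float, float]] = [(obs, 100.0)]
        units = row.product().n_isoprenoid_units()
        if units >= 1:
            frags.append((obs - 68.0626, 60.0))
        if units >= 2:
            frags.append((obs - 136.1252, 45.0))
        if row.mods.get("cam_cys", 0):
            frags.append((obs - 91.0092, 40.0))
        if row.mods.get("met_sulfoxide", 0):
            frags.append((obs - 63.9983, 40.0))
        n_extra = int(rng.integers(2, 6))
        lo = max(SCAN_RANGE[0], obs - 800.0)
        for mz in rng.uniform(lo, obs - 150.0, size=n_extra):
            frags.append((float(mz), float(rng.uniform(1.0, 20.0))))
        ms2[row.record_id] = PeakList(
            tuple(frags), level="MS2", precursor_mz=obs,
            source_id=f"sim_ms2_{row.record_id}",
        )
    for mz in rng.uniform(*SCAN_RANGE, size=cfg.n_noise_peaks):
        ms1_peaks.append((float(mz), float(rng.uniform(1.0, 50.0))))
    ms1 = PeakList(tuple(ms1_peaks), level="MS1", source_id="sim_ms1")
    return ms1, ms2
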