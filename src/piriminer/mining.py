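"""Mining cyanobactin precursor genes from DNA.

Cyanobactin precursor proteins are short (~50 aa) and share a conserved
N-terminal leader motif (here ``KKNxxPxxxxPVxR``) and a C-terminal
recognition region (here ``FAGD``) flanking the hypervariable core peptide
that becomes the macrocyclic product. This module translates DNA in all six
frames, scans for the leader motif with a mismatch budget, extracts the core
as the segment strictly between the leader-motif end and the first
downstream recognition-motif hit, and aggregates cores from clone libraries
into a deduplicated catalog with diversity statistics.

ORFs are modelled as segments between stop codons with no start-codon
requirement, because mined sequences are often amplicon fragments.
Coordinates are 0-based half-open on the forward strand throughout; minus
strand features carry a strand flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from Bio.Seq import Seq

__all__ = [
    "OrfSegment",
    "PrecursorRecord",
    "CoreCatalog",
    "MiningConfig",
    "translate_six_frames",
    "scan_leader_motif",
    "extract_core",
    "classify_core",
    "dedupe_cores",
    "mine_precursors",
]

DNA_ALPHABET = set("ACGTN")

LEADER_MOTIF = "KKNxxPxxxxPVxR"
RECOGNITION_MOTIF = "FAGD"


@dataclass(frozen=True)
class MiningConfig:
    """Motif patterns, mismatch budgets, and length filters for mining.

    Mismatch defaults mirror the degeneracy a PCR screen with conserved
    primers tolerates: 2 for the 14-position leader, 1 for the 4-position
    recognition site.
    """

    leader_motif: str = LEADER_MOTIF
    leader_max_mismatch: int = 2
    recognition_motif: str = RECOGNITION_MOTIF
    recognition_max_mismatch: int = 1
    min_orf_aa: int = 30
    core_min_len: int = 5
    core_max_len: int = 30


@dataclass(frozen=True)
class OrfSegment:
    """A stop-free translated segment with forward-strand coordinates."""

    source_id: str
    strand: str  # '+' or '-'
    frame: int  # 0..2 on the translated strand
    aa: str
    nt_start: int  # forward-strand, 0-based half-open
    nt_end: int


@dataclass(frozen=True)
class PrecursorRecord:
    """A mined precursor ORF with leader/core/recognition spans.

    Spans index into ``orf_aa`` and are ordered leader < core < recognition
    without overlap; ``core`` always equals the slice of ``orf_aa`` by
    ``core_span``.
    """

    source_id: str
    strand: str
    frame: int
    orf_aa: str
    nt_span: tuple[int, int]
    leader_span: tuple[int, int]
    core_span: tuple[int, int]
    recognition_span: tuple[int, int]
    core: str

    def __post_init__(self) -> None:
        l, c, r = self.leader_span, self.core_span, self.recognition_span
        if not (l[0] <= l[1] <= c[0] <= c[1] <= r[0] <= r[1] <= len(self.orf_aa)):
            raise ValueError("spans must be ordered leader <= core <= recognition")
        if self.core != self.orf_aa[c[0] : c[1]]:
            raise ValueError("core does not match its span")
        if not self.core:
            raise ValueError("core must be non-empty")


@dataclass(frozen=True)
class CoreEntry:
    core: str
    count: int
    source_ids: tuple[str, ...]
    flags: frozenset[str]
    length: int


@dataclass(frozen=True)
class CoreCatalog:
    """Unique cores with clone counts and diversity statistics."""

    entries: tuple[CoreEntry, ...]

    @property
    def total_clones(self) -> int:
        return sum(e.count for e in self.entries)

    @property
    def n_unique(self) -> int:
        return len(self.entries)

    def length_range(self, disulfide: bool | None = None) -> tuple[int, int] | None:
        lens = [
            e.length
            for e in self.entries
            if disulfide is None or (("disulfide_pattern" in e.flags) == disulfide)
        ]
        return (min(lens), max(lens)) if lens else None

    def summary(self) -> dict:
        return {
            "total_clones": self.total_clones,
            "unique_cores": self.n_unique,
            "length_range": self.length_range(),
            "length_range_disulfide": self.length_range(disulfide=True),
            "length_range_no_disulfide": self.length_range(disulfide=False),
        }


def _check_dna(dna: str) -> str:
    dna = dna.upper()
    bad = set(dna) - DNA_ALPHABET
    if bad:
        raise ValueError(f"invalid DNA characters: {sorted(bad)}")
    return dna


def translate_six_frames(
    dna: str, source_id: str = "seq", min_len: int = 30
) -> list[OrfSegment]:
    """Translate both strands in all three frames, split at stop codons.

    Codons containing N translate to X (and X never satisfies a motif
    position). Segments shorter than ``min_len`` amino acids are dropped.
    Minus-strand segment coordinates are reported on the forward strand.
    """
    dna = _check_dna(dna)
    n = len(dna)
    out: list[OrfSegment] = []
    for strand in "+-":
        seq = dna if strand == "+" else str(Seq(dna).reverse_complement())
        for frame in range(3):
            usable = (n - frame) // 3 * 3
            if usable <= 0:
                continue
            aa = str(Seq(seq[frame : frame + usable]).translate())
            start = 0
            for segment in aa.split("*"):
                end = start + len(segment)
                if len(segment) >= min_len:
                    s_nt = frame + 3 * start
                    e_nt = frame + 3 * end
                    if strand == "-":
                        s_nt, e_nt = n - e_nt, n - s_nt
                    out.append(
                        OrfSegment(source_id, strand, frame, segment, s_nt, e_nt)
                    )
                start = end + 1  # skip the stop codon
    return out


def _motif_matches_at(aa: str, pos: int, pattern: str, max_mismatch: int) -> bool:
    mismatches = 0
    for i, p in enumerate(pattern):
        c = aa[pos + i]
        if c == "X":
            return False  # ambiguous translation never matches, wildcards included
        if p in ("x", "X"):
            continue
        if c != p:
            mismatches += 1
            if mismatches > max_mismatch:
                return False
    return True


def scan_leader_motif(
    aa: str, pattern: str = LEADER_MOTIF, max_mismatch: int = 0
) -> list[int]:
    """All positions where ``pattern`` matches with <= ``max_mismatch``
    substitutions at non-wildcard positions (``x`` is the wildcard).
    Overlapping matches are all reported; a pattern longer than the sequence
    yields an empty list.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    return [
        i
        for i in range(len(aa) - len(pattern) + 1)
        if _motif_matches_at(aa, i, pattern, max_mismatch)
    ]


@dataclass(frozen=True)
class Rejection:
    source_id: str
    reason: str  # 'no_recognition' | 'length'
    detail: str


def extract_core(
    orf: OrfSegment,
    leader_pos: int,
    config: MiningConfig = MiningConfig(),
) -> PrecursorRecord | Rejection:
    """Cut the core out of an ORF given a leader-motif match position.

    The core is the segment strictly between the leader-motif end and the
    first recognition-motif occurrence after it. Cores outside the
    configured length window are rejected with reason ``length``; a missing
    downstream recognition motif rejects with ``no_recognition``.
    """
    aa = orf.aa
    leader_end = leader_pos + len(config.leader_motif)
    rec_hits = [
        leader_end + p
        for p in scan_leader_motif(
            aa[leader_end:], config.recognition_motif, config.recognition_max_mismatch
        )
    ]
    if not rec_hits:
        return Rejection(orf.source_id, "no_recognition", f"leader at {leader_pos}")
    rec_start = rec_hits[0]
    core = aa[leader_end:rec_start]
    if not (config.core_min_len <= len(core) <= config.core_max_len):
        return Rejection(
            orf.source_id, "length", f"core {core!r} length {len(core)}"
        )
    return PrecursorRecord(
        source_id=orf.source_id,
        strand=orf.strand,
        frame=orf.frame,
        orf_aa=aa,
        nt_span=(orf.nt_start, orf.nt_end),
        leader_span=(leader_pos, leader_end),
        core_span=(leader_end, rec_start),
        recognition_span=(rec_start, rec_start + len(config.recognition_motif)),
        core=core,
    )


def classify_core(core: str) -> frozenset[str]:
    """Structural flags read directly from the core sequence.

    ``disulfide_pattern``: >= 2 cysteines, so an intramolecular bridge is
    possible; ``has_met``: methionine present (sulfoxide-prone);
    ``prenylation_candidate``: a heteroatom-bearing residue (S/T/Y/W) that
    could accept an isoprenoid.
    """
    flags = set()
    if core.count("C") >= 2:
        flags.add("disulfide_pattern")
    if "M" in core:
        flags.add("has_met")
    if any(r in core for r in "STYW"):
        flags.add("prenylation_candidate")
    return frozenset(flags)


def dedupe_cores(
    records: Iterable[PrecursorRecord | tuple[str, str]],
) -> CoreCatalog:
    """Collapse clone records to unique cores with counts.

    Accepts PrecursorRecords or plain ``(core, source_id)`` pairs. Entries
    are sorted by count descending, then lexicographically, which makes the
    catalog deterministic. Clones are conserved: the counts sum to the
    number of input records.
    """
    groups: dict[str, list[str]] = {}
    for rec in records:
        if isinstance(rec, PrecursorRecord):
            core, src = rec.core, rec.source_id
        else:
            core, src = rec
        groups.setdefault(core, []).append(src)
    entries = [
        CoreEntry(core, len(srcs), tuple(srcs), classify_core(core), len(core))
        for core, srcs in groups.items()
    ]
    entries.sort(key=lambda e: (-e.count, e.core))
    return CoreCatalog(tuple(entries))


def mine_precursors(
    sequences: Iterable[tuple[str, str]],
    config: MiningConfig = MiningConfig(),
) -> tuple[list[PrecursorRecord], list[Rejection]]:
    """Full mining pass over (id, dna) pairs.

    Every six-frame ORF is scanned for the leader motif; each leader hit is
    extended to a core extraction. Output order follows input order, then
    strand/frame/position, so identical inputs give identical results.
    """
    records: list[PrecursorRecord] = []
    rejections: list[Rejection] = []
    for seq_id, dna in sequences:
        for orf in translate_six_frames(dna, seq_id, config.min_orf_aa):
            for pos in scan_leader_motif(
                orf.aa, config.leader_motif, config.leader_max_mismatch
            ):
                result = extract_core(orf, pos, config)
                if isinstance(result, PrecursorRecord):
                    records.append(result)
                else:
                    rejections.append(result)
    return records, rejections
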