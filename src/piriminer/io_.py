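"""File I/O and run configuration.

FASTA reading/writing goes through Biopython; peak lists are plain
tab-separated m/z-intensity columns with ``#key=value`` header lines for
metadata (MS2 files carry ``#precursor_mz=``). Run configuration is a flat
dataclass readable from YAML or simple ``key=value`` text; unknown keys
are rejected so typos fail loudly instead of silently using a default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .matching import PeakList

__all__ = [
    "ConfigError",
    "DataError",
    "RunConfig",
    "read_fasta",
    "write_fasta",
    "read_peaks",
    "write_peaks",
]


class ConfigError(ValueError):
    """Invalid or unknown configuration."""


class DataError(ValueError):
    """Malformed or missing input data."""


@dataclass(frozen=True)
class RunConfig:
    """All pipeline knobs in one place, each with a documented default.

    Tolerances are in mDa; ``match_tol_mda`` defaults to ion-trap scale
    (300 mDa = 0.3 Da), with 20 mDa the usual high-accuracy setting.
    """

    leader_motif: str = "KKNxxPxxxxPVxR"
    leader_max_mismatch: int = 2
    recognition_motif: str = "FAGD"
    recognition_max_mismatch: int = 1
    min_orf_aa: int = 30
    core_min_len: int = 5
    core_max_len: int = 30
    match_tol_mda: float = 300.0
    ms2_tol_da: float = 0.3
    ms2_min_rel_intensity: float = 0.05
    max_prenyl: int = 2
    max_geranyl: int = 1
    max_isoprenoid_units: int = 2
    include_met_sulfoxide: bool = True
    include_cam_cys: bool = False
    allow_disulfide_with_isoprenoid: bool = True
    max_charge: int = 1
    seed: int = 0
    verbosity: int = 1

    @classmethod
    def from_mapping(cls, data: dict) -> "RunConfig":
        known = {f.name: f.type for f in dataclasses.fields(cls)}
        unknown = set(data) - set(known)
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        try:
            return cls(**data)
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Read YAML (nested sections are flattened) or ``key=value`` lines."""
        text = Path(path).read_text()
        data: dict = {}
        try:
            loaded = yaml.safe_load(text)
        except yaml.YAMLError:
            loaded = None
        if isinstance(loaded, dict):
            flat: dict = {}
            for k, v in loaded.items():
                if isinstance(v, dict):
                    flat.update(v)
                else:
                    flat[k] = v
            data = flat
        else:  # key=value lines
            for line in text.splitlines():
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ConfigError(f"cannot parse config line {line!r}")
                k, v = (s.strip() for s in line.split("=", 1))
                data[k] = yaml.safe_load(v)
        return cls.from_mapping(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA into (id, uppercase sequence) pairs, order preserved."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    records: list[tuple[str, str]] = []
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            seq = str(rec.seq).upper()
            if not seq:
                raise DataError(f"empty sequence for record {rec.id!r}")
            records.append((rec.id, seq))
    except ValueError as exc:
        raise DataError(f"malformed FASTA {path}: {exc}") from exc
    if not records:
        raise DataError(f"no FASTA records in {path}")
    return records


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records),
        str(path),
        "fasta",
    )


def read_peaks(path: str | Path) -> PeakList:
    """Read a tab-separated peak list (m/z, intensity).

    ``#key=value`` lines set metadata (``precursor_mz``, ``level``,
    ``source_id``); a non-numeric first row is treated as a column header.
    Output peaks are sorted by m/z.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    meta: dict[str, str] = {}
    peaks: list[tuple[float, float]] = []
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "=" in line:
                k, v = line[1:].split("=", 1)
                meta[k.strip()] = v.strip()
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise DataError(f"{path}:{ln}: expected two tab-separated columns")
        try:
            mz, inten = float(fields[0]), float(fields[1])
        except ValueError:
            if ln == 1 or (not peaks and not meta.get("_saw_data")):
                continue  # header row
            raise DataError(f"{path}:{ln}: non-numeric peak fields {fields[:2]}")
        meta["_saw_data"] = "1"
        if mz <= 0:
            raise DataError(f"{path}:{ln}: non-positive m/z {mz}")
        if inten < 0:
            raise DataError(f"{path}:{ln}: negative intensity {inten}")
        peaks.append((mz, inten))
    level = meta.get("level", "MS2" if "precursor_mz" in meta else "MS1")
    precursor = float(meta["precursor_mz"]) if "precursor_mz" in meta else None
    try:
        return PeakList(
            tuple(peaks),
            level=level,
            precursor_mz=precursor,
            source_id=meta.get("source_id", path.stem),
        )
    except ValueError as exc:
        raise DataError(str(exc)) from exc


def write_peaks(peaks: PeakList, path: str | Path) -> None:
    lines = []
    if peaks.source_id:
        lines.append(f"#source_id={peaks.source_id}")
    lines.append(f"#level={peaks.level}")
    if peaks.precursor_mz is not None:
        lines.append(f"#precursor_mz={peaks.precursor_mz:.4f}")
    lines.append("mz\tintensity")
    lines.extend(f"{mz:.4f}\t{inten:.2f}" for mz, inten in peaks.peaks)
    Path(path).write_text("\n".join(lines) + "\n")
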