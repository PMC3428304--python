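"""End-to-end discovery pipeline: DNA in, ranked product matches out.

Stages: mine precursors from FASTA, deduplicate cores into a catalog,
enumerate modified product variants with theoretical masses, optionally
match an MS1 peak list and annotate with MS2 neutral-loss evidence. Each
stage writes one tab-separated report; ``summary.json`` records counts,
parameters, the package version and a config hash so a run is fully
reproducible from its outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .io_ import DataError, RunConfig, read_fasta, read_peaks
from .matching import (
    PeakList,
    VariantConfig,
    detect_neutral_losses,
    enumerate_variants,
    match_peaks,
)
from .mining import MiningConfig, dedupe_cores, mine_precursors

__all__ = ["run_pipeline"]

log = logging.getLogger("piriminer")

MASS_FMT = "%.4f"


def _mining_config(cfg: RunConfig) -> MiningConfig:
    return MiningConfig(
        leader_motif=cfg.leader_motif,
        leader_max_mismatch=cfg.leader_max_mismatch,
        recognition_motif=cfg.recognition_motif,
        recognition_max_mismatch=cfg.recognition_max_mismatch,
        min_orf_aa=cfg.min_orf_aa,
        core_min_len=cfg.core_min_len,
        core_max_len=cfg.core_max_len,
    )


def _variant_config(cfg: RunConfig) -> VariantConfig:
    return VariantConfig(
        max_prenyl=cfg.max_prenyl,
        max_geranyl=cfg.max_geranyl,
        max_isoprenoid_units=cfg.max_isoprenoid_units,
        include_met_sulfoxide=cfg.include_met_sulfoxide,
        include_cam_cys=cfg.include_cam_cys,
        allow_disulfide_with_isoprenoid=cfg.allow_disulfide_with_isoprenoid,
        charges=tuple(range(1, cfg.max_charge + 1)),
    )


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=MASS_FMT)


def run_pipeline(
    fasta: str | Path,
    outdir: str | Path,
    config: RunConfig = RunConfig(),
    peaks: str | Path | None = None,
    ms2_dir: str | Path | None = None,
    cores: list[str] | None = None,
) -> dict:
    """Run mining -> catalog -> variants -> (optional) matching.

    ``cores`` bypasses mining for amino-acid input (e.g. a printed core
    list); otherwise ``fasta`` is mined for precursor genes. Returns the
    summary dictionary that is also written to ``summary.json``.
    """
    t0 = time.time()
    outdir = Path(outdir)
    mcfg = _mining_config(config)
    vcfg = _variant_config(config)

    if cores is not None:
        records, rejections = [], []
        catalog = dedupe_cores((c, f"input_{i}") for i, c in enumerate(cores))
    else:
        sequences = read_fasta(fasta)
        records, rejections = mine_precursors(sequences, mcfg)
        if not records:
            raise DataError("no precursor genes found in input")
        catalog = dedupe_cores(records)
    log.info("mining: %d records, %d rejections, %d unique cores",
             len(records), len(rejections), catalog.n_unique)

    outdir.mkdir(parents=True, exist_ok=True)
    _write_tsv(
        pd.DataFrame(
            [
                {
                    "source_id": r.source_id,
                    "strand": r.strand,
                    "frame": r.frame,
                    "nt_start": r.nt_span[0] + 1,  # 1-based inclusive in reports
                    "nt_end": r.nt_span[1],
                    "core": r.core,
                    "orf_aa": r.orf_aa,
                }
                for r in records
            ]
        ),
        outdir / "precursors.tsv",
    )
    _write_tsv(
        pd.DataFrame(
            [
                {
                    "core": e.core,
                    "clones": e.count,
                    "length": e.length,
                    "flags": ",".join(sorted(e.flags)) or "-",
                }
                for e in catalog.entries
            ]
        ),
        outdir / "catalog.tsv",
    )

    variant_rows = []
    variants_by_core = {}
    for entry in catalog.entries:
        vs = enumerate_variants(entry.core, vcfg)
        variants_by_core[entry.core] = vs
        for v in vs:
            variant_rows.append(
                {
                    "core": v.core,
                    "variant": v.label(),
                    "charge": v.charge,
                    "formula": str(v.formula()),
                    "mz": v.mz(),
                }
            )
    _write_tsv(pd.DataFrame(variant_rows), outdir / "variants.tsv")
    log.info("variants: %d over %d cores", len(variant_rows), catalog.n_unique)

    match_rows = []
    n_matches = 0
    if peaks is not None:
        peaklist = read_peaks(peaks)
        ms2_lists = []
        if ms2_dir is not None:
            ms2_lists = [
                read_peaks(p) for p in sorted(Path(ms2_dir).glob("*.tsv"))
            ]
        all_variants = [v for vs in variants_by_core.values() for v in vs]
        matches = match_peaks(all_variants, peaklist, config.match_tol_mda)
        n_matches = len(matches)
        for m in matches:
            evidence: frozenset[str] = frozenset()
            for ms2 in ms2_lists:
                if ms2.precursor_mz is None:
                    continue
                if abs(ms2.precursor_mz - m.observed_mz) <= config.ms2_tol_da:
                    evidence = evidence | detect_neutral_losses(
                        ms2, config.ms2_tol_da, config.ms2_min_rel_intensity
                    )
            match_rows.append(
                {
                    "observed_mz": m.observed_mz,
                    "rank": m.rank,
                    "core": m.core,
                    "variant": m.variant.label(),
                    "theoretical_mz": m.theoretical_mz,
                    "delta_mda": m.delta_mda,
                    "isobaric_readings": ";".join(m.isobaric_readings) or "-",
                    "evidence": ",".join(sorted(evidence)) or "-",
                }
            )
        log.info("matching: %d matches over %d peaks",
                 n_matches, len(peaklist.peaks))
    _write_tsv(pd.DataFrame(match_rows), outdir / "matches.tsv")

    summary = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "parameters": config.to_dict(),
        "n_input_records": len(records) if cores is None else len(cores),
        "n_precursor_records": len(records),
        "n_rejections": len(rejections),
        "n_unique_cores": catalog.n_unique,
        "total_clones": catalog.total_clones,
        "n_variants": len(variant_rows),
        "n_matches": n_matches,
        "catalog_summary": catalog.summary(),
    }
    # runtime is logged, not written: reports stay byte-stable across runs
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    log.info("pipeline finished in %.2f s", time.time() - t0)
    return summary
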