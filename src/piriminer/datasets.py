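"""Bundled reference core-peptide lists.

Two small plain-text tables ship with the package: the core peptides
detected in cultured *Microcystis* strains (with their LC-MS-assigned
modifications), and the 122-clone lake-bloom metagenome catalog of 19
unique cores. They serve as worked-example inputs and as fixtures for the
diversity statistics.
"""

from __future__ import annotations

from importlib import resources

__all__ = ["load_strain_cores", "load_bloom_catalog", "expand_bloom_clones"]


def _rows(name: str) -> list[list[str]]:
    text = resources.files("piriminer.data").joinpath(name).read_text()
    return [
        line.split("\t")
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]


def load_strain_cores() -> list[tuple[str, str]]:
    """(core, modification codes) pairs from the cultured-strain survey."""
    return [(core, mods) for core, mods in _rows("strain_cores.tsv")]


def load_bloom_catalog() -> list[tuple[int, str]]:
    """(clone count, core) pairs from the bloom metagenome library."""
    return [(int(n), core) for n, core in _rows("bloom_catalog.tsv")]


def expand_bloom_clones() -> list[tuple[str, str]]:
    """One (core, clone_id) record per clone, as dedupe_cores consumes."""
    out = []
    for count, core in load_bloom_catalog():
        out.extend((core, f"{core}_{i}") for i in range(count))
    return out
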