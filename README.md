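# piriminer

Genome mining and mass-spectrometric dereplication of cyanobactins —
ribosomally synthesized, head-to-tail macrocyclized peptides of
cyanobacteria such as the piricyclamides of *Microcystis*.

Cyanobactin precursor proteins are short (~50 aa) and modular: a conserved
N-terminal leader carrying the `KKNxxPxxxxPVxR` motif, a hypervariable core
peptide of 7–22 residues (typically ending in Pro), and a C-terminal
recognition region starting with `FAGD`. Maturation excises the core and
macrocyclizes it head-to-tail; products may additionally carry a prenyl
(+C₅H₈) or geranyl (+C₁₀H₁₆) group on a heteroatom, an intramolecular
disulfide bridge (−H₂), or a methionine sulfoxide (+O, a sample-prep
artifact). `piriminer` turns these rules into a testable in-silico
discovery pipeline for microbiologists and natural-product chemists:

- **`piriminer.chem`** — exact-mass engine: elemental formulas, residue
  compositions, macrocycle masses (cyclic = Σ residues, no terminal water;
  MH⁺ = M + 1.00728), a modification algebra, stable-isotope (¹⁵N/³⁴S)
  label shifts, and an exhaustive elemental-formula search with an RDBE
  plausibility filter.
- **`piriminer.mining`** — six-frame translation, wildcard motif scanning
  with mismatch budgets, core extraction between the leader and recognition
  motifs, and clone-library deduplication with diversity statistics.
- **`piriminer.matching`** — enumeration of modified product variants and
  assignment of MS1 peaks with parsimony-ranked matches, MS² neutral-loss
  diagnostics (−68/−136 isoprenoid, −91 carbamidomethyl-Cys, −64 Met-SO),
  and isotope-label consistency checks.
- **`piriminer.simulate`** — a seeded forward model (precursor genes, clone
  libraries, peak lists) with full ground truth, so every stage is testable
  without instrument data.
- **`piriminer` CLI** — `mine`, `mass`, `variants`, `match`, `simulate`,
  `pipeline`.

## Worked example

The exact mass of a cyclic core, straight from the residue compositions:

```bash
$ piriminer mass GTHLYTITP
core            GTHLYTITP
topology        cyclic
formula         C46H69N11O13
monoisotopic_mass  983.5076
mz_z1           984.5149
nominal_mz      984
```

984.5149 is the theoretical MH⁺ of the cyclic nonapeptide GTHLYTITP — the
m/z an electrospray or MALDI instrument should report for the unmodified
macrocycle. A disulfide-bridged peptide shows the ion-trap readout before
and after reduction + iodoacetamide derivatization (+116 Da total):

```bash
$ piriminer mass TLGCMNGTERCLGLP --mods disulfide=1   # nominal_mz  1544
$ piriminer mass TLGCMNGTERCLGLP --mods cam_cys=2     # nominal_mz  1660
```

An unexplained mass delta can be searched for plausible CHO compositions;
for 84.0311 Da (a modified-tyrosine adduct) within 50 mDa:

```python
>>> from piriminer import formula_search
>>> [(str(c.formula), round(c.delta_mda, 1))
...  for c in formula_search(84.0311, 50, {"C", "H", "O"}, 20)][:2]
[('C4H4O2', 10.0), ('C5H8O', -26.4)]
```

A fully synthetic end-to-end run, with ground truth for every clone:

```bash
$ piriminer simulate --seed 7 --n-precursors 6 --n-clones 20 -o sim
6 precursors, 20 clones -> sim
$ piriminer pipeline sim/clones.fasta --peaks sim/ms1.tsv --ms2-dir sim/ms2 -o out
cores=6 variants=32 matches=8 -> out
$ head -5 out/matches.tsv
observed_mz  rank  core             variant                           theoretical_mz  delta_mda  isobaric_readings  evidence
1299.6392    1     LNPNNYTTRQP      LNPNNYTTRQP[cyclic]               1299.6440       -4.8245    -                  -
1554.7979    1     KPLQCRYEPKICP    KPLQCRYEPKICP[cyclic]+disulfide   1554.7920       5.9483     -                  -
1833.9832    1     RIQPDDQIPHGEITP  RIQPDDQIPHGEITP[cyclic]+geranyl   1833.9858       -2.5597    geranyl;2x prenyl  isoprenoid_loss_136,isoprenoid_loss_68
1833.9832    2     RIQPDDQIPHGEITP  RIQPDDQIPHGEITP[cyclic]+2xprenyl  1833.9858       -2.5597    2x prenyl;geranyl  isoprenoid_loss_136,isoprenoid_loss_68
```

(Columns are tab-separated in the actual file.) Each planted product comes
back as a rank-1 match within a few mDa; geranyl and 2×prenyl are isobaric
at MS1, so both readings are listed, and the MS² evidence column shows the
diagnostic isoprenoid neutral losses. The bundled reference core lists are
available via `piriminer.datasets`.

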