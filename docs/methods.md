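# Methods

## The model

Cyanobactins are ribosomal peptides: a short precursor protein encodes, in
order, an N-terminal leader, one core peptide, and a C-terminal recognition
region. Two proteases excise the core and join its termini head-to-tail,
so the mature macrocycle's elemental composition is the plain sum of its
residue compositions with **no terminal water**; the linear form adds one
H₂O. Tailoring chemistry is expressed as a modification algebra on the
composition, per modification instance:

| modification    | composition change | nominal delta |
|-----------------|--------------------|---------------|
| prenyl          | +C₅H₈              | +68           |
| geranyl         | +C₁₀H₁₆            | +136          |
| disulfide       | −H₂                | −2            |
| met_sulfoxide   | +O                 | +16           |
| cam_cys         | +C₂H₃NO            | +57 per Cys   |

Carbamidomethylation (`cam_cys`) models the disulfide diagnostic: the
bridge is reduced and each freed thiol alkylated with iodoacetamide, so
going from the bridged form (`disulfide=1`) to the fully derivatized form
(`cam_cys=2`) gains 2 H + 2×C₂H₃NO = 116 Da nominal. Per-cysteine
bookkeeping keeps partial derivatization expressible; the invariant
`2·n_disulfide + n_cam ≤ n_Cys` forbids assigning both to one cysteine
pair. Methionine sulfoxide is treated as a sample-preparation artifact of
the intact product, never as an encoded modification.

Monoisotopic atomic masses (C 12, H 1.00782503, N 14.00307400,
O 15.99491462, S 31.97207100; proton 1.00727647) and heavy-isotope
increments (¹⁵N−¹⁴N = 0.99703489, ³⁴S−³²S = 1.99579590 Da) are embedded to
8 decimals. MH⁺ = (M + z·1.00727647)/z. Two *nominal* conventions coexist,
both matching how low-resolution ion traps report numbers:

- the nominal m/z of an **ion** is the truncated (floored) monoisotopic
  value — above ~1.2 kDa the accumulated mass defect exceeds 0.5 Da and
  trap readouts quote the integer part (e.g. 1544.70 → 1544);
- the nominal value of a mass **difference** (label shift, neutral loss,
  derivatization delta) is round-half-up (3.99 → 4, 116.06 → 116).

Isotope-label enrichment defaults to 1.0 (complete labelling) even though
feeding media are typically 90–98 atom%; observed shifts are interpreted
against the full-label prediction, and enrichment is a configurable field
for when partial labelling matters. `isotope_shift` counts **every** atom
of the labelled element in the composition — including, for ³⁴S, the
methionine sulfur, not only cysteines. `infer_atom_count` inverts an
observed shift to the nearest atom count and flags residuals above 30% of
one per-atom increment.

## Formula search

`formula_search` enumerates all integer compositions over the requested
elements within per-element bounds, keeps those within the tolerance of the
target mass, and filters for chemical plausibility: ring-plus-double-bond
equivalents RDBE = C + 1 + (N − H)/2 ≥ −0.5 (integral or half-integral by
construction) and H ≤ 2C + 2 + N. Candidates are sorted by |Δ| with the
signed deviation reported as target − candidate, in mDa. The default
bounds (≤20 per element) cover small substituent masses; the enumeration
is exhaustive, so it agrees with a brute-force nested loop by design and
by test.

## Mining

ORFs are modelled as stop-free translated segments (standard code, both
strands, all three frames) with **no start-codon requirement**, because
clone-library inserts are amplicon fragments; the default minimum segment
length is 30 aa, comfortably below the ~48–53 aa of full precursors.
Ambiguous bases (N) translate to X, and X never satisfies a motif
position — wildcards included — so ambiguity cannot fake a hit.

Motifs are one-letter patterns with `x` as wildcard; a window matches when
non-wildcard mismatches stay within the budget. Defaults:
leader `KKNxxPxxxxPVxR` with ≤2 mismatches, recognition `FAGD` with ≤1 —
roughly the degeneracy a PCR screen with conserved primers tolerates. The
core is the segment **strictly between** the leader-motif end and the first
downstream recognition hit; a 5–30 aa window rejects absurd extractions
(`length`), and a missing downstream motif rejects with `no_recognition`.
Coordinates are 0-based half-open on the forward strand internally and
1-based inclusive in reports.

Clone libraries deduplicate to unique cores sorted by count descending,
then lexicographically; statistics cover total clones, unique cores, and
length ranges overall and within the double-cysteine (disulfide-capable)
class.

## Variant enumeration and matching

Per core the variant space is the Cartesian product of prenyl 0–2,
geranyl 0–1, disulfide 0–⌊n_Cys/2⌋ and Met-sulfoxide 0–n_Met, pruned by a
combined isoprenoid cap of 2 C₅ units (geranyl counts as two) — the
assignment patterns actually observed (unmodified, prenyl, geranyl, double
prenyl). Carbamidomethyl variants are off by default since derivatization
is an experiment, not biosynthesis. Only singly protonated ions are
enumerated by default; charge states to 3 are a config key.

Matching reports every (variant, peak) pair within tolerance and ranks per
peak by |Δ|, breaking ties by parsimony (fewer modification instances) and
then label, which makes results independent of input order. Geranyl and
2×prenyl are isobaric at MS1, so such matches carry both readings
explicitly. Default tolerances: 300 mDa (ion-trap MS1) for matching and
0.3 Da for MS² fragments, with 20 mDa the usual high-accuracy setting —
config keys, not constants. MS² evidence (−68.0626/−136.1252 isoprenoid,
−91.0092 carbamidomethyl-Cys, −63.9983 Met-sulfoxide neutral losses, at a
≥5% relative-intensity floor) only annotates mass matches; it never
creates one.

## Synthetic data

The generator is a pure function of (seed, config) built on
`numpy.random.default_rng`. Defaults encode the natural library shape:
cores 7–22 aa ending in Pro; ~10% of cores carry a planted double-cysteine
pattern (which is then modelled as bridged) and ~15% a methionine;
isoprenoid assignment probabilities 0.2 prenyl / 0.2 geranyl (mutually
exclusive, remainder unmodified) with Met-sulfoxide probability 0.3 per
Met-containing core; clone counts follow a Zipf-like law (exponent 1.0,
every core keeping ≥1 clone) over a 122-clone library. Codon choice is
uniform over synonymous codons with no GC model — mining is
codon-agnostic. Genes embed prefix + leader motif + core + recognition
motif + tail in random flanks on a random strand; sampled cores may not
contain a ≤1-mismatch copy of the recognition motif (a real core
resembling the protease site would be cleaved), which also guarantees the
miner's first-downstream-hit rule recovers the planted core exactly.

MS1 peaks sit at theoretical m/z plus Gaussian error (default sd 5 mDa)
with decoy noise uniform in the instrument scan range m/z 300–2200; MS²
spectra contain only the precursor, the diagnostic losses implied by the
planted modifications, and a little noise — a deliberate
diagnostic-loss-only model, sufficient to exercise evidence detection.
What passing tests therefore show: the pipeline inverts its own forward
model at realistic error scales. What they do not show: robustness to
chimeric reads, sequencing error, co-eluting isobars, full b/y
fragmentation, adducts other than MH⁺, or isotope-envelope effects at
partial enrichment.

## Problem sizes and numerical choices

The test suite runs simulations of 10–30 precursors and ≤122 clones, 50
planted MS1 peaks, and formula searches with bounds ≤20 per element —
sizes at which every stage is exact or statistically stable, and the whole
suite completes in well under a minute. Tie-breaks are lexicographic
everywhere a total order is needed, so all reports are byte-stable for
identical inputs/config/seed; `summary.json` embeds a config hash. Mass
comparisons in tests use absolute tolerances at least an order of
magnitude tighter than any instrument scale asserted (5×10⁻⁵ Da for
4-decimal values).

## Known limitations

- Supported elements are CHNOS; selenopeptides or metal adducts are out.
- Only protonation is modelled; no Na⁺/K⁺ adducts, no average masses, no
  isotope-pattern envelopes.
- The double-cysteine flag assumes at most pairwise bridging; interchain
  disulfides and >1 bridge per 4 cysteines are expressible in the algebra
  but never auto-assigned.
- The ³⁴S full-label prediction counts methionine sulfur; an observed
  shift consistent with fewer sulfur atoms than the composition holds is
  reported as inconsistent rather than silently excused.
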