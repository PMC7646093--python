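# Methods

This note documents the models, algorithms and numerical choices behind
`dialibkit`, the assumptions they rest on, and what the synthetic-data tests
do and do not demonstrate about real data.

## Peptide chemistry

All masses are monoisotopic; the target instruments are high-resolution
Orbitraps, for which average masses are irrelevant.  The residue table and
the water (18.010565 Da) and proton (1.007276 Da) constants are the
standard published values, bundled in `chem.RESIDUE_MASSES`; a unit test
cross-checks them against pyteomics' independent mass table.

Modified sequences use UniMod bracket notation (`C[UniMod:4]AR`, leading
tag = N-terminal).  Numeric mass-delta tags (`C[+57.0215]`) are accepted on
input and normalised to the nearest bundled UniMod entry within ±0.01 Da.
The bundled subset covers the modifications of a standard tryptic search
(carbamidomethyl-C, oxidised M, N-terminal acetyl, plus carbamyl,
deamidation, phospho); anything else raises an unsupported-modification
error rather than guessing.

Fragments are b/y only, charges 1–2 by default: the convention of DIA assay
libraries.  Neutral-loss and a/c/x/z ions are out of scope.  The b/y
complementarity identity `mz(b_i) + mz(y_{n−i}) = M + 2·proton` (singly
charged) is enforced by a property test over random sequences — it caught
an ordinal-labelling bug during development, which is exactly what it is
for.

Peak–ion matching uses a ±0.03 Th window by default, the same tolerance
used for DIA chromatogram extraction on this instrument class, so library
construction and downstream extraction agree about what "the same mass"
means.  Matching is globally greedy by distance; a peak satisfies at most
one ion, ties resolved b-before-y, then lower ordinal, then lower charge —
arbitrary but deterministic.

## PSM ingest

Internal retention time is always seconds; dialects convert on read
(MaxQuant `peptides.txt` prints minutes).  PSM-level FDR is assumed
controlled by the upstream search engine; `filter_psms` offers an optional
score gate (off by default), a charge gate, and a tryptic-junction check
(cleave after K/R, not before P) that is a no-op when the table carries no
sequence-context columns.  Semi-tryptic peptides are deliberately retained
by default — they are part of library completeness, not noise.

## Retention-time calibration

The RT→iRT model is affine per run.  `fit_irt_map` runs ordinary least
squares followed by iterated outlier rejection: residuals beyond
3 robust sigmas (1.4826 × MAD, the consistent Gaussian scale estimate) of
the survivor median are dropped and the line refit, to a fixpoint or five
rounds.  The 1.4826 factor matters: a raw 3×MAD cut sits at ≈2 Gaussian
sigmas and the monotone iteration then cascades, rejecting good points.
Degenerate inputs fail loudly: fewer than three pairs or three survivors,
or zero RT variance, raise typed errors.  r² is reported on survivors.

Under the simulated conditions (20 landmarks, σ = 5 s Gaussian RT noise on
a 3600 s gradient) the fitted slope is within 2 % and the intercept within
2 iRT units of truth in ≥ 95 % of 200 seeded replicates — the regression
suite asserts exactly this.

### CiRT landmark selection

Candidates must be proteotypic, unmodified, at charge 2 or 3, and have
precursor intensity strictly above the configured quantile (default 0.75,
type-7 linear-interpolation quantile) of **all** quantified precursors —
the pool is not restricted to candidates, so the cut means "top quartile of
the experiment".  PSMs are first collapsed to precursors: RT = median,
intensity = max, score = max across observations; the max keeps a
landmark's abundance evidence even when some identifications caught the
chromatographic tail.

The observed candidate RT span (not the nominal gradient length — robust to
dead volume) is cut into 20 equal-width bins and the most intense candidate
is taken from each non-empty bin, ties broken by higher score then
lexicographically smaller sequence (intensity is the only abundance signal
the criteria reference, hence the within-bin rule).  Empty bins yield fewer
landmarks rather than borrowing from neighbours; more than 25 % empty bins
attaches a warning.  Landmarks then need reference iRT values: pushed
through a SiRT-anchored fit when one exists, otherwise min–max scaled onto
[0, 100], the conventional iRT span.  Both anchoring strategies are
provided because sample sets with and without spike-ins both occur; the
library records which was used.  SiRT reference values are user-supplied
via a landmark TSV — the commercial 11-peptide kit's values are proprietary
and not bundled.

## Consensus spectra

Precursor-region peaks (±1.5 Th of the precursor m/z) are removed first —
standard library hygiene.  Peaks are pooled across replicates and clustered
greedily, seeding each cluster from the most intense unclustered peak with
a ±tol window (default 0.03 Th).  A cluster survives if it appears in
≥ 60 % of replicates; with fewer than three replicates the rule degenerates
and all peaks are kept, because "60 % of 2" cannot distinguish signal from
noise.  Consensus m/z is the intensity-weighted cluster mean; consensus
intensity is the median across members (robust to one aberrant replicate);
iRT is the median of the members' calibrated RTs, each through its own
run's fit.  Members are ordered canonically (run id, scan id) before
clustering so the result is invariant to input order.

On synthetic replicates (fixed 10-peak fragment profile + uniform noise,
5 replicates) the 60 % rule recovers ≥ 95 % of true peaks and accepts < 5 %
of noise peaks across 100 seeds — asserted in the suite.

## Assay generation

Transition candidates are consensus peaks matched to allowed b/y ions,
restricted to 300–1800 Th (common assay-library practice, configurable) and
outside ±9 Th of the precursor (half a typical DIA isolation window;
products inside it would co-extract with the precursor).  Ranking is
library intensity descending with lower-m/z tie-break for determinism; the
top 6 survive.  Entries with zero usable products are rejected with a
reason and counted, not silently dropped.

Decoys are pseudo-reversed: residues 1..n−1 reversed, C-terminal residue
fixed, modifications travelling with their residues.  This preserves amino
acid composition (hence precursor m/z) and the tryptic y1 ion while
scrambling internal fragment masses.  Product m/z is recomputed for the
same (series, ordinal, charge) labels; intensities and iRT are kept, so
target and decoy score distributions differ only through mass placement.
Palindromic prefixes fall back to a seeded shuffle (≤ 10 tries); a target
with no distinct permutation (e.g. AAK) is skipped and counted.  Decoy
entries carry their target's group id, so subset and merge operations keep
the pairing exact rather than inferring it from sequences.

## Protein inference

The protein-group definition is parsimony at the peptide-set level:
accessions with identical peptide sets merge; an accession whose set is a
strict subset of another's is absorbed into the superset's group, computed
to closure.  When a set fits under two incomparable supersets, the larger
peptide set wins, ties by lexicographically smallest representative — an
arbitrary but deterministic rule.  The implementation (sort by set size,
absorb downward) is verified against a brute-force subset-closure oracle on
100 random maps in the suite.

A peptide is proteotypic iff it maps to exactly one accession; a protein
counts as proteotypic iff it is Swiss-Prot canonical (``sp|`` header,
accession without isoform suffix — one curated sequence per gene) and owns
at least one proteotypic peptide.  Library statistics count distinct
precursors, distinct modified sequences (stripped-sequence count reported
alongside, since either convention is found in the wild), protein groups,
and proteotypic canonical proteins, always excluding decoys.

Protein abundance rollup for DIA output is the median over all detected
fragment intensities of all precursors assigned to the group; missing
fragments are omitted, never zero-filled, and even-count medians are the
mean of the central pair.

## Serialization

The OpenSWATH transition TSV is the canonical on-disk form (one row per
transition, the standard column set: PrecursorMz, ProductMz,
Tr_recalibrated, transition_name, LibraryIntensity, decoy, PeptideSequence,
FullUniModPeptideName, PrecursorCharge, ProteinName, FragmentType,
FragmentCharge, FragmentSeriesNumber).  `Tr_recalibrated` holds iRT.  A few
extra columns (replicate count, sample type, best score, decoy pairing)
make write→read the identity; unknown extra columns are accepted on read.
Floats are written with `repr`, so round trips are bit-exact.

TraML output follows the PSI 1.0.0 structure (cvList, CompoundList/Peptide
with normalized-RT cvParams, TransitionList with Precursor/Product m/z and
target/decoy cvParams).  Offline validation uses a hand-written structural
XSD subset bundled at `data/traml_subset_synthetic.xsd` — it checks the
hierarchy, required attributes and cvParam structure this package emits; it
is not the full official schema.  Tests additionally reparse the XML with a
parser sharing no code with the writer and require m/z agreement to 1e-4.

PRM inclusion lists use minutes (instrument convention): per precursor, a
window of predicted RT (inverse of a supplied calibration fit) ± 5 min by
default; a warning fires when more than 100 windows overlap at any time
point, the scheduling capacity of a typical targeted method.  Requested
peptides absent from the library are returned in a miss list.

Binary SpectraST library formats (`.splib`/`.pepidx`/`.spidx`) are not
emitted; TSV and TraML carry the library.

## Synthetic data

The generator emulates the DDA inputs of a library build: random proteomes
(Swiss-Prot-style accessions, seed-specific blocks so merged simulations do
not collide), in-silico tryptic digestion (after K/R, not before P,
configurable missed cleavages and semi-tryptic fraction), hidden iRT
uniform on [0, 100], per-run affine iRT→RT transforms spanning roughly the
middle 80 % of the gradient with Gaussian jitter (default σ = 5 s),
log-normal precursor intensities (the heavy-tailed abundance that makes a
third-quartile cut meaningful), charges drawn 1:2:3:4 =
0.05:0.60:0.30:0.05, and spectra composed of a per-precursor true b/y
subset with jittered intensities plus Poisson-count uniform noise peaks.
`dense_cirt_run` produces the landmark-selection stress case: 1000 distinct
proteotypic precursors uniformly covering a 3600 s gradient, so no bin is
empty.

What the generator does **not** model: chimeric spectra, realistic
fragmentation intensity patterns, charge-state coexistence per peptide,
isotope envelopes, peak-width/saturation effects, or shared peptides
between unrelated proteins beyond what random digestion produces.  Passing
tests therefore demonstrate the pipeline's logic (selection rules,
calibration recovery, traceability of every transition to its generating
ion), not identification performance on real chromatography.  Default test
problem sizes (hundreds of PSMs, 2–3 runs, 200 calibration replicates, 100
grouping instances) are chosen so the full suite runs in seconds while
estimator variance stays well inside the asserted tolerances.

## Pipeline and interfaces

`run_build` chains the stages and aborts on a stage's hard error, reporting
per-stage counts (input = kept + removed everywhere) plus calibration r²
and bin occupancy in a QC dict.  Builds are single-process and
deterministic: one seed drives decoy generation and any shuffles, and the
CLI's `build` writes byte-identical TSVs for identical inputs and seed.
The library-first API is the primary interface; the `dialibkit` click CLI
is a thin wrapper (simulate, import, cirt, calibrate, build, merge, subset,
stats, export-prm) with a YAML config mirroring the config dataclasses.

## Known limitations

- Only affine RT calibration; no lowess/spline alignment or cross-run RT
  transfer beyond the landmark mechanism.
- The bundled UniMod subset is small by design; extending it is a
  one-line table edit but deliberately explicit.
- Protein grouping is set-theoretic parsimony, not probabilistic inference;
  no PSM-level error propagation.
- The structural TraML schema validates what this package writes, not
  arbitrary third-party TraML.
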