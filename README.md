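# dialibkit

Build calibrated, decoy-appended spectral libraries for DIA and PRM
proteomics from DDA search results.

## The problem

Data-independent acquisition (DIA/SWATH) quantifies peptides by matching
multiplexed fragment spectra against a *spectral library*: for every peptide
precursor (modified sequence + charge), a set of transitions — (precursor
m/z, product m/z) pairs with reference intensities — plus a
gradient-independent retention time (iRT).  Parallel reaction monitoring
(PRM) validates shortlisted biomarkers with scheduled targeted MS/MS built
from the same assays.  `dialibkit` implements the library-construction
workflow between a search engine's peptide-spectrum matches (PSMs) and a
ready-to-use assay library:

1. **PSM ingest** — generic / pFind-style / MaxQuant `peptides.txt` TSV
   dialects, MGF/mzML/mzXML spectra (via pyteomics), normalised to one
   internal schema (seconds, UniMod bracket notation).
2. **Retention-time calibration** — a robust affine map `iRT = a·RT + b`
   per run, fit by least squares with iterated MAD-based outlier rejection.
   Landmarks are either spiked-in synthetic iRT standards (SiRT, reference
   values supplied by the user) or **CiRT** landmarks discovered from the
   data itself: proteotypic, unmodified peptides at charge 2–3 with
   intensity above the third quartile of all quantified precursors, one per
   gradient bin (20 equal-width bins ⇒ up to 20 landmarks per sample type).
3. **Consensus spectra** — one representative MS2 spectrum per precursor,
   clustering peaks across replicate identifications and keeping those seen
   in ≥ 60 % of replicates.
4. **Assay generation** — the top 6 annotated b/y product ions per
   precursor (intensity-ranked, precursor-region and out-of-range products
   excluded) and one pseudo-reverse decoy per target (C-terminal residue
   fixed, so precursor m/z and tryptic y1 behaviour are preserved).
5. **Protein inference** — parsimony protein groups (identical or subset
   peptide sets merge), proteotypic-peptide and Swiss-Prot-canonical
   accounting, and a median-of-fragment-intensities protein abundance
   rollup for downstream DIA quantification.
6. **Serialization** — OpenSWATH transition TSV (canonical form), TraML 1.0
   XML, MSP/MGF consensus export, scheduled PRM inclusion lists
   (± 5 min windows), library merge/subset with decoy pairing preserved.

A seeded synthetic-data module (`dialibkit.simulate`) generates proteomes,
PSM runs and spectra with known ground truth, so the whole pipeline is
testable without any raw data.

## Worked example

```sh
python examples/03_build_library.py
```

```text
simulated 1200 PSMs over 3 runs, 255 peptides in truth

replicate groups      253
consensus spectra     253
target assays         253
decoy assays          253
library stats: LibraryStats(n_transition_groups=253, n_peptides=253,
               n_stripped_peptides=253, n_protein_groups=20,
               n_proteotypic_proteins=20)
calibration run0: r^2 = 0.9978 over 14 landmarks
calibration run1: r^2 = 0.9965 over 16 landmarks
calibration run2: r^2 = 0.9973 over 14 landmarks
library iRT vs hidden iRT: r^2 = 1.0000

wrote library.tsv (OpenSWATH transition list) and library.traml
```

253 of the 255 simulated peptides end up as target assays, each paired 1:1
with a pseudo-reverse decoy.  The per-run calibration r² is the quality of
the CiRT-based affine RT→iRT fit; the final line shows that library iRT
values recover the generator's hidden iRT scale.  The other example scripts
cover peptide chemistry (`01`), landmark discovery and calibration (`02`),
PRM scheduling (`04`) and merge/subset/overlap statistics (`05`).

The same pipeline is scriptable from the shell:

```sh
dialibkit simulate --seed 1 --out sim/
dialibkit build --psm sim/psms.tsv --spectra sim/spectra.mgf --seed 1 \
    --out library.tsv --qc-out qc.json
dialibkit stats --lib library.tsv
```

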