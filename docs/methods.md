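# Methods

This note documents the models implemented in `chromdomain`, the
parameters that matter, the numerical conventions, and what the synthetic
data do and do not establish.

## iTRAQ enrichment model

Each peptide row carries reporter intensities for a domain channel and a
control channel; the peptide-level ratio is domain/control.  The protein
ratio per replicate is the **median** of its peptide ratios — robust to a
single aberrant peptide; the arithmetic mean is selectable
(`aggregation="mean"`).  Peptides with zero control intensity are dropped;
a protein with no usable peptide in a replicate is excluded from that
replicate with a warning.

Housekeeping and ribosomal proteins contaminate domain and control
purifications alike, so their mean raw ratio in a replicate estimates that
replicate's global labeling/loading bias.  Every protein's ratio is
divided by this background factor.  Two algebraic consequences are tested
to 1e-9: recomputing the factor on corrected data gives exactly 1
(idempotence), and scaling one replicate's domain channel by any constant
leaves all corrected ratios unchanged (scale invariance).

Corrected ratios are averaged **arithmetically** over the replicates in
which the protein was identified (a geometric option exists; "average" is
read literally), and peptide counts are summed over the same replicates.
Proteins absent from every replicate are not emitted.  Tier boundaries are
deliberately asymmetric: ≥ for the 1.5 threshold, strictly > for the 1.0
relaxed threshold, and tiering is monotone in both ratio and peptide count
(property-tested).

Complex-level summaries count, over the *annotated* subunits, those whose
tier reaches RELAXED_B or better (configurable); ratio and peptide
averages run over *identified* subunits only, since there is no principled
imputation for unidentified ones.  A complex is depicted at coverage
≥ 0.5.

## Histone-PTM quantification

Propionylation chemistry fixes the digest and the mass arithmetic:

* free K and me1-K gain a propionyl (+56.026215 Da); me2/me3/acetyl-K do
  not; every peptide N-terminus is propionylated;
* trypsin therefore cleaves after R only (Arg-C-like), never before P.

The lysine-state alphabet is {prop, ac, me1+prop, me2, me3} with
monoisotopic deltas 56.026215, 42.010565, 70.041865, 28.031300,
42.046950 Da.  Residue masses come from pyteomics; [M+H]+ = Σ residues +
18.010565 + 1.007276 + deltas.  Because positional isomers are
mass-degenerate at MS1, forms are enumerated as multisets over the
peptide's lysines and grouped into mass bins (4-decimal rounding).  A
notable degeneracy: acetyl + methyl equals propionyl in mass
(42.010565 + 14.015650 = 56.026215), so the full 5-state alphabet on the
four H4 lysines collapses from C(8,4) = 70 multisets to 35 mass bins —
verified against an exhaustive per-site oracle.

Recalibration fits observed → theoretical m/z on unmodified anchor
peptides of the same histone (H4 46–55 and 79–92; H3 64–69 and 27–40,
fully propionylated): a linear map with ≥ 2 anchors, offset-only with 1,
skipped with a warning at 0.  Both models are provided because the
original processing is ambiguous between them; linear is the default.

Peak assignment takes the nearest peak within ±0.15 Da (half the 0.3 Da
parent-selection window used upstream; configurable).  Bins closer than
2× tolerance — e.g. acetyl vs trimethyl, Δ 0.036 Da — are merged into an
ambiguity group and quantified jointly; resolving them requires MS/MS,
which is out of scope.  Proportions are intensity over summed intensity
per peptide; a peptide with all-zero assignments is "not detected" rather
than given proportions.  Replica averaging is the unweighted mean over
detected replicas, renormalized.

Built-in sequences are the mature yeast H3 and H4 (initiator Met removed,
1-based conventional numbering); arbitrary histones load from FASTA.

## EM footprint analysis

Calibration multiplies nm by 3.0 bp/nm (150 bp ≈ 50 nm) and rounds
half-up to integer bp.  Coordinates are 0-based half-open; on circular
molecules a bubble with start > end wraps through the origin and interval
arithmetic is modulo ring length.  Linearization maps x → (x − cut) mod L;
a bubble containing the cut site is physically impossible (restriction
enzymes cannot cut single-stranded DNA), so such molecules are flagged
unanalyzable and excluded, with their ids reported.

Size bins: sub (<130), mono [130, 180), intermediate [180, 260), gap
[260, 280), di [280, 360], supra (>360) bp.  Boundaries are
lower-inclusive except the di upper bound, which is inclusive so that the
stated 280–360 range is honored on both ends; 260–280 bp is kept as an
explicit gap bin rather than silently folded into a neighbor.

Molecule classes are **emergent**, not a fixed ontology: the key is
(bubble count, sorted multiset of (size bin, feature relation) pairs),
with relation ∈ {overlaps_feature, upstream, downstream} of the single
configured feature.  Keys are invariant to bubble listing order and to
coordinate shifts that cross no boundary.  `fraction_crosslinked_over_feature`
counts molecules with no bubble overlapping the feature by ≥ 1 bp
(min_overlap configurable, since EM boundary precision is limited).

## Recovery accounting

Recovery = 100 × elution/extract, reported both unrounded and as a
round-half-up integer matching the conventional presentation; the package
reproduces the published 13/7/13/2/11% IgG-step and 3% calmodulin-step
recoveries from the published fmole amounts.  Fold-excess is a plain
quotient against the PDC1 reference amount.  Recombination efficiency
defaults to 100 × rec/(rec+nonrec) because published efficiencies (55–74%)
are bounded by 100, which the literal quotient rec/nonrec need not be; the
literal mode is available and flagged in output.  Mass-balance QC flags
|(P+SUP) − CE|/CE > 0.25 — advisory only, reflecting blot-quantification
noise.  Accessibility titrations are normalized to the highest-enzyme
point (= 100%); ChIP retention is 100 × IP/(input × dilution).

## Synthetic data

A single root seed expands into fixed per-generator substreams
(`numpy.random.SeedSequence.spawn`), so outputs are bit-for-bit
reproducible and adding a generator never perturbs existing fixtures.
All noise is multiplicative log-normal parameterized by CV with unit
median; CV = 0 yields exactly 1, which gives every generator/analyzer
pair an exact noise-free closure (tested).

* **iTRAQ** defaults: 200 background proteins at true corrected ratio 1,
  20 spiked at 3.0, three replicates, peptide counts 1 + Poisson(2),
  ratio CV 0.25, and a per-replicate global bias factor (log-normal,
  σ = 0.2, or fixed values) that the background correction must remove.
  Intensities are generated at peptide level so the ratio-aggregation
  choice is genuinely exercised.  Under these conditions strict calls
  reach sensitivity ≥ 0.85 and specificity ≥ 0.95.
* **MALDI**: peaks at theoretical m/z under a linear calibration drift
  (slope, offset) shared by all spots, intensity = total × proportion ×
  log-normal noise (default CV 0.1), anchors included, optional uniform
  background peaks, three spots.
* **Molecules**: configurations are drawn from a catalog of (nucleosome
  start positions, probability).  Each nucleosome protects 147 bp;
  footprints with linkers below the merge threshold (default 30 bp — no
  EM resolution figure is available, so this is an explicit, configurable
  assumption) coalesce into one bubble; boundaries get Gaussian jitter;
  a bubble that drifts over the cut site is nudged off it so the
  population stays analyzable.  Output in bp or nm.
* **Amounts**: deterministic closure fixtures with configurable true
  recovery, extraction loss, fold-excess and efficiency.

What the simulations do **not** model: sequence-dependent psoralen
preferences, incomplete crosslinking of naked DNA (the likely source of
real intermediate-size bubbles), isotope impurities and peptide-level
identification errors in iTRAQ, and MALDI profile shapes or isotope
envelopes.  Passing parameter-recovery tests therefore demonstrates the
correctness of the estimators under the stated noise model, not
instrument-level realism.

## Problem sizes

Default test and acceptance runs use 220 proteins × 3 replicates for
iTRAQ, 100 seeded repeats of 3-spot MALDI simulations, and 500–1000
molecules for EM — sizes at which binomial error bands (3 SE) are tight
enough to be informative while the whole suite runs in seconds.

## Known limitations

* Enrichment calling applies no multiple-testing control, matching the
  thresholding approach it implements.
* Histone-PTM quantification is MS1-only; ambiguity groups (ac vs me3)
  are inherent at this level.
* The 12-class structure of a real molecule population is data-driven;
  the classifier reproduces whatever classes the data contain, and class
  counts depend on the configured feature and bins.
* `recovery` treats input amounts as exact; uncertainty propagation from
  blot/qPCR quantification is not modeled.
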