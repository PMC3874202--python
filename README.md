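# chromdomain

Quantitative analyses for **native chromatin-domain purifications** from
budding yeast.  When a chromosomal region (an rDNA subdomain, a single-copy
gene) is excised as a chromatin ring by site-specific recombination and
affinity-purified via a LexA-TAP bait, four kinds of measurements describe
what came out.  This package implements the downstream numerics for all
four, each exercisable on synthetic data with known ground truth or on
published summary tables:

1. **iTRAQ enrichment calling** (`chromdomain.itraq`).  Peptides from a
   domain purification and a mock control are labeled with two iTRAQ
   reporters; the per-protein reporter ratio measures specific
   co-purification.  Per replicate, each protein ratio is divided by the
   mean ratio of housekeeping and ribosomal proteins (the background
   factor), corrected ratios are averaged over replicates, and enrichment
   is tiered:

   - STRICT: mean corrected ratio ≥ 1.5 with ≥ 2 peptides
   - RELAXED_A: ratio ≥ 1.5 with 1 peptide
   - RELAXED_B: ratio > 1.0 with ≥ 2 peptides

   A protein complex is depicted when ≥ 50% of its annotated subunits pass.

2. **Histone-PTM quantification** (`chromdomain.histone_ptm`).
   Propionylation converts free and monomethyl lysines (and peptide
   N-termini) to propionylated forms (+56.02621 Da), so trypsin cleaves
   after arginine only.  For a peptide such as H4 4–17 (GKGGKGLGKGGAKR,
   lysines K5/K8/K12/K16) all mass-distinct modification forms are
   enumerated; after recalibration against unmodified anchor peptides,
   each form's relative proportion is its peak intensity divided by the
   summed intensity over all forms of the peptide, averaged over MALDI
   spot replicas.

3. **Psoralen-EM nucleosome footprints** (`chromdomain.em`).  Psoralen
   crosslinks protein-free DNA; each nucleosome leaves ~147 bp
   uncrosslinked, visible after denaturation as a single-stranded bubble.
   Contours are calibrated (150 bp ≈ 50 nm), circular molecules are
   linearized at the restriction cut site, bubbles are binned
   (mono-nucleosome 130–180 bp, di-nucleosome 280–360 bp, intermediate
   180–260 bp), molecules are classified by bubble number/size/position
   relative to a feature, and the fraction of molecules whose feature is
   fully crosslinked (nucleosome-free) is computed.

4. **Recovery accounting** (`chromdomain.recovery`).  Recovery
   (elution/extract), fold-excess over the unrelated PDC1 reference locus,
   recombination efficiency, mass-balance QC, restriction-accessibility
   normalization, and ChIP percent-of-input.  `chromdomain.datasets`
   carries the published fmole amounts per purification fraction for the
   five domains as ready-made inputs.

`chromdomain.simulate` generates all four input kinds with ground truth
(spiked enrichment ratios, true modification proportions, nucleosome
configuration catalogs, true recoveries) so that every stage's parameter
recovery is testable offline.

## Worked example

Simulate an iTRAQ experiment (200 background proteins with true corrected
ratio 1, 20 spiked at ratio 3, three replicates, 25% ratio CV) and call
enrichment:

```sh
$ chromdomain simulate itraq --seed 7 --out sim
wrote itraq simulation to sim
$ chromdomain itraq --quant sim/quant.tsv --annot sim/annotation.tsv \
    --domain-channel 115 --control-channel 114 --out res
220 proteins, 20 strictly enriched
$ head -4 res/proteins.tsv
protein_id  avg_ratio     total_peptides  tier       functional_class
BG0000      1.083082497   9               RELAXED_B  housekeeping
BG0001      0.8974050784  9               NONE       ribosomal protein
BG0002      1.097072852   10              RELAXED_B  housekeeping
```

All 20 spiked proteins are called STRICT; background proteins scatter
around a corrected ratio of 1 and at most reach RELAXED_B (ratio barely
above 1), never the strict criterion.

The recovery arithmetic on the published amounts of the 5S rRNA gene
domain (cellular extract 3521 fmol, IgG elution 248 fmol):

```pycon
>>> from chromdomain import datasets, recovery
>>> rep = recovery.report(datasets.domain_amounts("5S"))
>>> rep.recovery_pct, rep.qc_flags
({'E_igg': 7}, [])
```

i.e. 7% of the 5S domains present in the extract were recovered in the
elution, and pellet + supernatant account for the extract within the QC
tolerance.

Other subcommands: `chromdomain histone-ptm`, `chromdomain em`,
`chromdomain recovery`, `chromdomain simulate maldi|em|amounts`; see
`--help` for the input dialects, and `docs/methods.md` for the models and
their assumptions.

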