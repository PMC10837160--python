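# pavprot

Variant-aware peptide libraries and MS-PAV / MS-pQTL association mapping for
bottom-up, peptide-centric DIA proteomics.

## The problem

Bottom-up mass-spectrometry proteomics quantifies a protein from the
intensities of its tryptic peptides. A protein-altering variant (PAV) — here
restricted to single-nucleotide missense substitutions at minor allele
frequency (MAF) > 10% — changes the amino-acid sequence of the peptides
covering it. A standard (reference) spectral library only contains the
reference-allele peptide, so that peptide goes undetected in homozygous
alternate-allele carriers and halves in heterozygotes. Rolling such peptides
into protein quantification produces genotype-dependent protein estimates
and hence spurious pQTLs: the mass-spectrometric equivalent of the *epitope
effect* that plagues affinity-based proteomics.

`pavprot` implements the countermeasure end to end:

1. **Gene model** (`gene_model`): align a protein FASTA with a BED12
   annotation track and a genome; resolve ambiguous protein-to-placement
   mappings (translation-exact first, then Met-start/in-frame, then
   canonical/alphanumeric, then input order); map genomic SNVs to missense
   consequences.
2. **Libraries** (`library_builder`): inject each MAF-filtered PAV
   independently into its reference protein; digest in silico (cleave after
   K/R with no proline exception, ≤ 1 missed cleavage, 7–30 aa, N-terminal
   Met excision); match reference and alternate digests position-wise; emit
   the *reference*, *PAV-inclusive* (reference ∪ alternate simple matches,
   plus `{protein}_{rsID}` isoform entries) and *PAV-exclusive* (reference
   minus every variant-overlapping peptide) libraries.
3. **MS-PAV calling** (`detection_association`): per detection *signal* —
   a unique (variant peptide, allele, nanoparticle, precursor charge,
   missed-cleavage) combination — test peptide detection against allele
   carriage (≥ 1 copy) with a two-sided Fisher's exact test on the 2×2
   table, for both the major (`p_maj`) and the minor (`p_min`) allele;
   control the family with Bonferroni, significant iff
   `min(p_maj, p_min) < α / n_signals`.
4. **MS-pQTL mapping** (`quantitative_association`): roll peptides up to
   protein × nanoparticle quantities per library, inverse-normal transform
   (Blom offset `(r − 3/8)/(n + 1/4)`), and fit
   `INT(protein) ~ g + age + sex + BMI + diabetes + PC1..3` where `g` is
   the minor-allele dosage (0/1/2). MS-pQTLs require `p < 5×10⁻⁸` on the
   PAV-exclusive quantities. Comparing reference vs PAV-exclusive models
   classifies each variant as a robust pQTL, an epitope effect, or
   underpowered.
5. **QC** (`qc_validation`): detection-fraction filters, cross-nanoparticle
   Spearman correlations of doubly-charged precursors (technical
   replicates), and genotype-concordance flags for spectral-confusion
   false positives.
6. **External overlap** (`overlap_annotation`): classify variants against
   affinity-platform summary statistics as cis (`p < 0.05/n_variants` on
   the variant's own protein), trans-only
   (`p < 0.05/n_variants/n_assayed_proteins` on another protein),
   not assayed, or no overlap.
7. **Synthetic cohorts** (`synthetic_data`): toy genomes/gene models,
   Hardy–Weinberg genotypes, covariates, and per-nanoparticle DIA-style
   report tables with allele-dosage-scaled variant-peptide intensities and
   detection calibrated to a 0.58 carrier sensitivity / 0.05 false-positive
   rate, with ground truth, under three scenarios: `epitope`, `true_pqtl`,
   `null`.

## Worked example

```bash
pavprot simulate --scenario epitope --seed 1 --out-dir study/
pavprot build-model --bed study/model.bed --proteins study/proteins.fa \
    --genome study/genome.fa --out study/model.tsv
pavprot detect-mspav --model study/model.tsv --genome study/genome.fa \
    --vcf study/genotypes.vcf --dosage study/dosage.tsv \
    $(printf -- '--report %s ' study/report_NP*.tsv) --out study/mspav.tsv
pavprot pqtl --model study/model.tsv --genome study/genome.fa \
    --vcf study/genotypes.vcf --dosage study/dosage.tsv \
    --covariates study/covariates.tsv \
    $(printf -- '--report %s ' study/report_NP*.tsv) --out study/pqtl.tsv
```

Equivalently in Python (this is what `scripts/acceptance.py` runs; output
below is from `--seed 1`):

```text
signals tested: 81; significant: 81; unique variants: 3
chr1:122:T:G  PROT000  epitope_effect  p_ref=6.26e-11  p_excl=0.378
chr2:118:G:T  PROT001  epitope_effect  p_ref=5.07e-17  p_excl=0.976
chr1:386:G:C  PROT002  epitope_effect  p_ref=2.66e-23  p_excl=0.268
```

Reading: all 81 variant-peptide signals track donor genotype (Fisher,
Bonferroni over the 81-signal family), so all three simulated variants are
MS-PAVs. At the protein level each variant is strongly "associated" when the
protein is quantified with the standard reference library (`p_ref`), but the
association vanishes with the PAV-exclusive library (`p_excl`) — the
signature of an epitope effect, which is exactly what the `epitope`
scenario encodes (no true abundance effect).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full pipeline on a freshly simulated epitope-scenario cohort
(simulation → libraries → detection matrices → Fisher MS-PAV calls →
roll-ups → covariate-adjusted pQTL models → regimen classification), prints
the run's summary, and writes the JSON result mapping to `--out`.
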