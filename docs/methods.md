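# Methods

## Statistical model

### Detection-level test (MS-PAV)

For one detection signal — a unique (variant peptide, allele, nanoparticle,
precursor charge, missed-cleavage form) — let `d_i ∈ {0, 1}` be detection
(strictly positive reported quantity) in sample `i` and `g_i ∈ {0, 1, 2}`
the minor-allele dosage. Samples without genotypes are dropped per test.
Two 2×2 tables are formed, detection × carriage, where carriage of an
allele means at least one copy (minor carriers `g ≥ 1`, major carriers
`g ≤ 1`), and each is tested with a two-sided Fisher's exact test. The
reported `p_best = min(p_maj, p_min)`; a tie reports the minor allele
(deterministic output; ties are measure-zero in practice). Sidedness is
configurable; two-sided is the default of the reference analysis
environment (`fisher.test`). Family-wise control is Bonferroni over the
number of tested signals, with strict inequality.

The Fisher p-value is computed by direct enumeration of the hypergeometric
support with fixed margins: `p = Σ { P(k) : P(k) ≤ P(k_obs) · (1 + 1e-7) }`.
The `1e-7` relative tie gap is the convention of the reference
implementation; a table with a zero margin carries no information and
returns `p = 1` with a degeneracy flag.

### Protein-level model (MS-pQTL)

Peptide intensities are rolled up per (protein, nanoparticle) from the
peptides of a chosen library; only library members contribute. Protein
values are transformed by the rank-based inverse-normal transform with
average ranks for ties and the Blom offset `Φ⁻¹((r − 3/8)/(n + 1/4))`
(tie handling unstated upstream; Blom is the common choice), missing
values excluded — in contrast to the peptide-level model `pX`, where
missing intensities are set to zero because non-detection is itself the
allele-dosage signal. The pQTL model is ordinary least squares

    INT(protein) = β·g + age + sex + BMI + diabetes + PC1 + PC2 + PC3 + ε

with `β` per minor-allele copy in inverse-normal units. MS-pQTLs are calls
at `p < 5×10⁻⁸` (strict) on PAV-exclusive quantities. Nanoparticles are
analyzed separately; because which nanoparticle measures a protein best is
not knowable a priori, the comparison pipeline reports all and classifies
on the nanoparticle with the smallest reference-library p (flagged).

### Regimen classification

With `S_ref` / `S_excl` denoting significance with the reference /
PAV-exclusive library at a common threshold: `S_ref ∧ S_excl` → robust
pQTL; `S_ref ∧ ¬S_excl` → epitope effect; neither → underpowered. The
fourth configuration (`¬S_ref ∧ S_excl`) is not an enumerated regimen; it
is classed robust with a discordance flag rather than inventing a class.

## Roll-up choice: median vs sum

The default roll-up is the median of log2 intensities of the library's
detected peptides — robust for general quantification, and a documented
stand-in for search-engine protein inference (MaxLFQ-like), which this
package does not reproduce; its only contract is sensitivity to library
membership. For the epitope demonstration the median has a structural blind
spot: in alternate homozygotes the reference-allele peptide is *undetected*
and simply leaves the median, so the protein estimate returns to baseline
and the artifact becomes non-monotone in dosage. The `sum` roll-up (raw
intensities, missing treated as absent) is depressed exactly by the missing
variant peptide — which is the artifact under study — so the scenario
pipeline and CLI `pqtl` command use `method="sum"` explicitly.

## Synthetic cohorts

The generator emits everything the pipeline consumes, with ground truth.

* **Gene models.** Proteins are built from explicit tryptic segments
  (6–11 non-K/R residues plus K or R), back-translated codon-randomly,
  given a stop codon, split into 1–3 CDS blocks with random introns, and
  placed on two chromosomes on both strands; every entry passes the
  translation round-trip by construction. PAV sites avoid K/R and Met so
  injected variants produce simple reference-to-alternate matches.
* **Genotypes.** Hardy–Weinberg: `g ~ Binomial(2, MAF)`, MAF uniform in
  [0.10, 0.50]. Covariates: age ~ U(18, 80) (the cohort's stated range),
  sex and diabetes ~ Bernoulli(0.5) (cohort design in equal proportions),
  BMI ~ N(28, 4.5) kg/m², three standard-normal genotype PCs.
* **Intensities.** Protein log2 abundance = baseline + small covariate
  effects + N(0, 0.5); peptide log2 intensity adds a per-peptide ionization
  factor N(0, 0.8), a per-nanoparticle offset N(0, 0.3) with per-pair
  jitter, technical noise N(0, 0.25), and — for allele-specific peptides —
  `log2(copies/2)`: the reference-allele peptide halves in heterozygotes
  and vanishes in alternate homozygotes. The noise scales are plausible for
  engine-normalized plasma DIA data; they are stated once here and not
  revisited.
* **Detection.** Variant peptides: per signal, the threshold is the
  empirical (1 − sensitivity) quantile of carrier intensities, so the
  carrier detection rate matches the configured default 0.58 with
  false-positive detections at 0.05 in non-carriers — both calibrated to
  the GIP worked example (130/223 carriers, 5/102 non-carriers). Invariant
  peptides are subject to 10% random missingness only.
* **Scenarios.** `epitope`: allele-specific peptides, no true abundance
  effect. `true_pqtl`: protein abundance additionally shifted by 0.5 log2
  per alternate-allele copy (an inverse-normal effect on the scale of the
  published MS-pQTL betas, 0.42–1.0). `null`: variant peptides present in
  the library but detected independently of genotype — the false-positive
  control.
* **Preset calibration.** In non-null scenarios allele-specific peptides
  draw their response factor from N(2.0, 0.4) log2 rather than N(0, 0.8):
  an MS-PAV is by selection a well-ionizing, well-detected peptide
  (otherwise it would never pass the Fisher stage), and in the published
  demonstration the variant peptide dominates its protein's quantification.
  The value 2.0 was fixed by the documented replicate calibration (epitope
  regimen recovery 88%/96%/100% at response means 1.0/1.5/2.0) and frozen.
  The epitope preset also uses short proteins (40–70 aa) so variant
  peptides are a material share of the tryptic map.

### What a green simulation test does and does not establish

The simulator reproduces the statistical structure the analysis assumes —
dosage-scaled allele-specific intensities, calibrated detection, HWE
genotypes, nanoparticle replication — but not real spectra: no retention
time, fragmentation, interference, LD between variants, match-between-runs
artefacts, or protein-inference ambiguity. A green end-to-end test
establishes that the pipeline recovers the intended regimen when the
mechanism is as modeled, not that it would do so on any real cohort.

## Numerical and design notes

* Coordinates: BED 0-based half-open; VCF and protein positions 1-based;
  CDS blocks stored in transcription order.
* A single trailing stop codon is trimmed silently; internal stops and
  frame violations invalidate an entry. Standard codon table only.
* Stop-gain/stop-loss variants are excluded from injection (the library
  builder's contract is single-residue substitution); synonymous and
  non-coding SNVs map to no consequence.
* MAF filter is strictly `> 0.10`; Bonferroni and the 5×10⁻⁸ call are
  strict inequalities; the detection-fraction filter is strictly `>`.
* Digestion: cleavage after every K/R with no proline exception (matching
  the `--cut K*,R*` search convention); Met excision applies only to
  protein-N-terminal peptides; the 7–30 aa window is applied after
  missed-cleavage enumeration.
* Peptides shared between proteins are retained in each protein's entries;
  protein-group inference is delegated to the report producer.
* Multiple PAVs per protein are injected independently, one isoform per
  variant; multiple substitutions within one peptide are not combined.
* The parameter-recovery simulation generates its outcome directly on the
  inverse-normal scale with unit marginal variance (residual variance
  `1 − β²·2·MAF·(1 − MAF) − Σγ²`); effect sizes in pQTL studies are
  reported in these units, and any other scale would make the INT rescale
  the slope by construction.
* Rank-deficient designs raise with the collinear columns named; constant
  genotypes and all-identical intensity vectors are errors, not silent
  NaNs.

## Known limitations

* Protein quantification is a peptide roll-up, not MaxLFQ; absolute
  protein values are not comparable to engine output.
* External-overlap classification matches exact variant identifiers; no
  LD expansion of the query variants.
* The genotype-concordance flag (> 90% detection in the discordant
  genotype group for both alleles) is an operationalization of a narrative
  criterion, with a configurable threshold.
* Search-engine behaviour (FDR, match-between-runs, spectral confusion) is
  outside the model; the `null` scenario and the concordance flags probe
  its consequences only schematically.
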