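"""Synthetic cohorts: toy genomes, gene models, genotypes, DIA-style reports.

The generator emits every input the analysis consumes — genome FASTA, BED12
gene model, protein FASTA, genotype VCF/dosage table, covariates, and one
quantification report per nanoparticle — together with a ground-truth table
that joins losslessly to each file, so every pipeline stage is testable
without external downloads.

The statistical world is the one the analysis assumes: genotypes in
Hardy-Weinberg proportions at MAF 0.10-0.50; log-normal peptide
intensities proportional to a protein abundance with covariate effects;
allele-specific peptide intensity additionally proportional to the number
of copies of that allele (so the reference-allele peptide halves in
heterozygotes and vanishes in alternate homozygotes — the epitope
mechanism); detection of variant peptides calibrated to a carrier
sensitivity of 0.58 with a 0.05 false-positive rate in non-carriers
(the GIP worked example: 130/223 and 5/102); and five nanoparticle
fractions acting as partially overlapping technical replicates.

Scenarios: ``epitope`` (allele-specific peptides, no true abundance
effect), ``true_pqtl`` (protein abundance shifted per alternate-allele
copy), ``null`` (variant peptides detected independently of genotype).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .gene_model import (
    GeneModelEntry,
    GenomicVariant,
    PavRecord,
    codon_genomic_positions,
    cds_sequence,
    translate_cds,
    _COMPLEMENT,
)
from .library_builder import (
    LibrarySet,
    ORIGIN_ALT,
    ORIGIN_INVARIANT,
    ORIGIN_REF,
    build_libraries,
    filter_pavs_by_maf,
)

logger = logging.getLogger(__name__)

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODONS_BY_AA: dict[str, list[str]] = {}
for codon, aa in sorted(_TABLE.forward_table.items()):
    _CODONS_BY_AA.setdefault(aa, []).append(codon)
_STOP_CODONS = sorted(_TABLE.stop_codons)

# residues used inside tryptic segments (no K/R so cleavage sites are explicit,
# no M so Met excision applies only at the protein N-terminus)
_SEGMENT_AA = "ACDEFGHILNPQSTVWY"

SCENARIOS = ("epitope", "true_pqtl", "null")


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Generator configuration; defaults are the study's stated conditions."""

    seed: int = 0
    scenario: str = "null"
    n_samples: int = 325
    n_proteins: int = 12
    protein_length_range: tuple[int, int] = (60, 120)
    n_pavs: int = 6
    maf_range: tuple[float, float] = (0.10, 0.50)
    detection_sensitivity: float = 0.58
    detection_fpr: float = 0.05
    log2_intensity_mean: float = 20.0
    protein_sd: float = 0.5
    ionization_sd: float = 0.8
    noise_sd: float = 0.25
    missingness: float = 0.10
    pqtl_beta: float = 0.5
    variant_ion_mean: float = 2.0
    variant_ion_sd: float = 0.4
    beta_age: float = 0.005
    beta_sex: float = 0.2
    beta_bmi: float = 0.01
    beta_diabetes: float = 0.15
    n_nanoparticles: int = 5

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise SimulationError(f"unknown scenario {self.scenario!r}")
        for rate in (self.detection_sensitivity, self.detection_fpr, self.missingness):
            if not (0.0 <= rate <= 1.0):
                raise SimulationError(f"rate {rate} outside [0, 1]")
        lo, hi = self.maf_range
        if not (0.0 <= lo <= hi <= 0.5):
            raise SimulationError(f"maf_range {self.maf_range} invalid")
        if self.protein_length_range[0] < 25:
            raise SimulationError(
                "proteins shorter than 25 aa cannot yield three peptides of length 7-30"
            )


def scenario_config(scenario: str, seed: int = 0, **overrides) -> SimConfig:
    """Preset configurations for the three simulation scenarios.

    The epitope preset uses short proteins (40-70 aa) so variant peptides
    are a material share of the tryptic map, mirroring the small-protein
    demonstrations where the artifact is strongest.
    """
    presets = {
        "epitope": dict(n_proteins=6, n_pavs=3, protein_length_range=(40, 70)),
        "true_pqtl": dict(n_proteins=6, n_pavs=3),
        "null": dict(),
    }
    kwargs = dict(scenario=scenario, seed=seed)
    kwargs.update(presets[scenario])
    kwargs.update(overrides)
    return SimConfig(**kwargs)


@dataclass
class SimGeneModel:
    genome: dict[str, str]
    entries: list[GeneModelEntry]
    protein_seqs: dict[str, str]
    variants: list[GenomicVariant]
    pavs: list[PavRecord]
    bed_text: str
    genome_fasta_text: str
    protein_fasta_text: str


@dataclass
class SimTruth:
    variants: pd.DataFrame
    peptides: pd.DataFrame
    config: SimConfig


@dataclass
class SimStudy:
    model: SimGeneModel
    libraries: LibrarySet
    dosage: pd.DataFrame  # samples x variant_id, minor-allele copies
    covariates: pd.DataFrame
    vcf_text: str
    reports: dict[str, pd.DataFrame]
    truth: SimTruth
    config: SimConfig


# ---------------------------------------------------------------------------
# Gene model


def _random_protein(rng: np.random.Generator, length_range: tuple[int, int]) -> str:
    """Protein with explicit tryptic segments of 7-13 aa, starting with Met."""
    target = int(rng.integers(length_range[0], length_range[1] + 1))
    seq = ["M"]
    while len(seq) < target - 8:
        seg_len = int(rng.integers(6, 12))
        seq.extend(rng.choice(list(_SEGMENT_AA), size=seg_len))
        seq.append(str(rng.choice(["K", "R"])))
    # C-terminal segment without a trailing cleavage site
    seq.extend(rng.choice(list(_SEGMENT_AA), size=max(0, target - len(seq))))
    return "".join(seq)


def _back_translate(rng: np.random.Generator, protein: str) -> str:
    codons = [str(rng.choice(_CODONS_BY_AA[aa])) for aa in protein]
    codons.append(str(rng.choice(_STOP_CODONS)))
    return "".join(codons)


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def simulate_gene_model(config: SimConfig) -> SimGeneModel:
    """Toy genome FASTA + BED12 + protein FASTA with embedded missense PAVs.

    CDSs have a valid start and stop, no internal stops, 1-3 blocks, both
    strands; every emitted entry passes the translation round-trip by
    construction (asserted). PAV sites are chosen away from K/R so they
    produce simple reference-to-alternate peptide matches.
    """
    rng = np.random.default_rng([config.seed, 11])
    chrom_parts: dict[str, list[str]] = {"chr1": [], "chr2": []}
    cursors = {"chr1": 0, "chr2": 0}
    entries: list[GeneModelEntry] = []
    protein_seqs: dict[str, str] = {}
    bed_lines: list[str] = []

    for i in range(config.n_proteins):
        pid = f"PROT{i:03d}"
        protein = _random_protein(rng, config.protein_length_range)
        cds = _back_translate(rng, protein)
        chrom = "chr1" if i % 2 == 0 else "chr2"
        strand = "+" if rng.random() < 0.5 else "-"
        n_blocks = int(rng.integers(1, 4))
        # split the CDS into contiguous chunks
        if n_blocks > 1:
            cuts = sorted(rng.choice(np.arange(3, len(cds) - 3), size=n_blocks - 1, replace=False))
        else:
            cuts = []
        bounds = [0] + [int(c) for c in cuts] + [len(cds)]
        chunks = [cds[a:b] for a, b in zip(bounds, bounds[1:])]

        spacer = _random_bases(rng, int(rng.integers(20, 51)))
        chrom_parts[chrom].append(spacer)
        cursors[chrom] += len(spacer)
        gene_start = cursors[chrom]

        introns = [_random_bases(rng, int(rng.integers(10, 31))) for _ in range(n_blocks - 1)]
        genomic_chunks = chunks if strand == "+" else [
            c.translate(_COMPLEMENT)[::-1] for c in reversed(chunks)
        ]
        blocks_asc: list[tuple[int, int]] = []
        pos = gene_start
        for j, piece in enumerate(genomic_chunks):
            blocks_asc.append((pos, pos + len(piece)))
            chrom_parts[chrom].append(piece)
            pos += len(piece)
            if j < len(introns):
                chrom_parts[chrom].append(introns[j])
                pos += len(introns[j])
        cursors[chrom] = pos
        gene_end = blocks_asc[-1][1]

        tx_blocks = tuple(blocks_asc if strand == "+" else list(reversed(blocks_asc)))
        entry = GeneModelEntry(
            protein_id=pid,
            chrom=chrom,
            strand=strand,
            cds_blocks=tx_blocks,
            protein_seq=protein,
            bed_index=i,
        )
        entries.append(entry)
        protein_seqs[pid] = protein

        sizes = ",".join(str(e - s) for s, e in blocks_asc)
        starts = ",".join(str(s - gene_start) for s, _ in blocks_asc)
        bed_lines.append(
            "\t".join(
                [
                    chrom,
                    str(gene_start),
                    str(gene_end),
                    pid,
                    "0",
                    strand,
                    str(gene_start),
                    str(gene_end),
                    "0",
                    str(len(blocks_asc)),
                    sizes + ",",
                    starts + ",",
                ]
            )
        )

    for chrom in chrom_parts:
        chrom_parts[chrom].append(_random_bases(rng, 30))
    genome = {chrom: "".join(parts) for chrom, parts in chrom_parts.items()}

    for entry in entries:  # construction invariant
        assert translate_cds(entry, genome) == entry.protein_seq

    variants: list[GenomicVariant] = []
    pavs: list[PavRecord] = []
    for k in range(config.n_pavs):
        entry = entries[k % len(entries)]
        protein = entry.protein_seq
        cds = cds_sequence(entry, genome)
        placed = False
        for _ in range(200):
            p = int(rng.integers(3, len(protein) - 1))
            ref_aa = protein[p - 1]
            if ref_aa in "KRM":
                continue
            if any(v.protein_id == entry.protein_id and v.protein_pos == p for v in pavs):
                continue
            codon = cds[(p - 1) * 3 : p * 3]
            options = [(o, b) for o in range(3) for b in "ACGT" if b != codon[o]]
            rng.shuffle(options)
            for offset, base in options:
                alt_codon = codon[:offset] + base + codon[offset + 1 :]
                alt_aa = _TABLE.forward_table.get(alt_codon)
                if alt_aa is None or alt_aa in "KR" or alt_aa == ref_aa:
                    continue
                gpos = codon_genomic_positions(entry, p)[offset]
                ref_base = genome[entry.chrom][gpos - 1]
                alt_base = base if entry.strand == "+" else base.translate(_COMPLEMENT)
                maf = float(rng.uniform(*config.maf_range))
                rsid = f"rs{100000 + k}"
                variant = GenomicVariant(
                    chrom=entry.chrom, pos=gpos, ref=ref_base, alt=alt_base, rsid=rsid, maf=maf
                )
                variants.append(variant)
                pavs.append(
                    PavRecord(
                        variant_id=f"{entry.chrom}:{gpos}:{ref_base}:{alt_base}",
                        protein_id=entry.protein_id,
                        protein_pos=p,
                        ref_aa=ref_aa,
                        alt_aa=alt_aa,
                        maf=maf,
                        rsid=rsid,
                    )
                )
                placed = True
                break
            if placed:
                break
        if not placed:
            raise SimulationError(f"could not place a PAV on {entry.protein_id}")

    genome_fasta = "".join(f">{c}\n{seq}\n" for c, seq in genome.items())
    protein_fasta = "".join(f">{pid}\n{seq}\n" for pid, seq in protein_seqs.items())
    return SimGeneModel(
        genome=genome,
        entries=entries,
        protein_seqs=protein_seqs,
        variants=variants,
        pavs=pavs,
        bed_text="\n".join(bed_lines) + "\n",
        genome_fasta_text=genome_fasta,
        protein_fasta_text=protein_fasta,
    )


# ---------------------------------------------------------------------------
# Genotypes & covariates


def simulate_genotypes(
    config: SimConfig, pavs: list[PavRecord]
) -> tuple[pd.DataFrame, pd.DataFrame, str]:
    """Hardy-Weinberg genotypes, covariates, and a VCF rendering.

    Genotypes are Binomial(2, MAF) alternate-allele counts per sample;
    covariates are age ~ U(18, 80), sex and diabetes ~ Bernoulli(0.5),
    BMI ~ N(28, 4.5) and three standard-normal genotype PCs. Returns
    (dosage samples x variants, covariates, VCF text).
    """
    rng = np.random.default_rng([config.seed, 23])
    samples = [f"S{i:03d}" for i in range(config.n_samples)]
    dosage = pd.DataFrame(index=pd.Index(samples, name="sample"))
    for pav in pavs:
        dosage[pav.variant_id] = rng.binomial(2, pav.maf, size=config.n_samples)

    covariates = pd.DataFrame(
        {
            "age": rng.uniform(18, 80, size=config.n_samples),
            "sex": rng.integers(0, 2, size=config.n_samples).astype(float),
            "bmi": rng.normal(28.0, 4.5, size=config.n_samples),
            "diabetes": rng.integers(0, 2, size=config.n_samples).astype(float),
            "pc1": rng.normal(size=config.n_samples),
            "pc2": rng.normal(size=config.n_samples),
            "pc3": rng.normal(size=config.n_samples),
        },
        index=dosage.index,
    )

    buf = io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    buf.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">\n')
    chroms = sorted({p.variant_id.split(":")[0] for p in pavs})
    for c in chroms:
        buf.write(f"##contig=<ID={c}>\n")
    buf.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
    gt_code = {0: "0/0", 1: "0/1", 2: "1/1"}
    ordered = sorted(pavs, key=lambda p: (p.variant_id.split(":")[0], int(p.variant_id.split(":")[1])))
    for pav in ordered:
        chrom, pos, ref, alt = pav.variant_id.split(":")
        g = dosage[pav.variant_id]
        af = float(g.mean() / 2.0)
        gts = "\t".join(gt_code[int(x)] for x in g)
        buf.write(
            f"{chrom}\t{pos}\t{pav.rsid or '.'}\t{ref}\t{alt}\t.\tPASS\tAF={af:.6f}\tGT\t{gts}\n"
        )
    return dosage, covariates, buf.getvalue()


# ---------------------------------------------------------------------------
# Quantification reports


def _dedup_entries(libraries: LibrarySet):
    seen = set()
    out = []
    for p in libraries.pav_inclusive:
        key = (p.sequence, p.protein_id, p.origin, p.variant_id, p.missed_cleavages, p.met_excised)
        if key not in seen:
            seen.add(key)
            out.append(p)
    return out


def simulate_report(
    config: SimConfig,
    model: SimGeneModel,
    libraries: LibrarySet,
    dosage: pd.DataFrame,
    covariates: pd.DataFrame,
) -> tuple[dict[str, pd.DataFrame], SimTruth]:
    """Per-nanoparticle DIA-style report tables plus ground truth.

    Per sample, protein log2 abundance carries covariate effects and — in
    the ``true_pqtl`` scenario — a ``pqtl_beta`` shift per alternate-allele
    copy. Peptide intensity is abundance times a peptide ionization factor
    and a nanoparticle offset; allele-specific peptides scale with allele
    copy number. Variant-peptide detection thresholds are set at the
    empirical (1 - sensitivity) carrier quantile, with Bernoulli(fpr)
    false-positive detections in non-carriers; invariant peptides are
    subject to random missingness only.
    """
    if not libraries.pav_inclusive:
        raise SimulationError("empty library; was it built from this gene model?")
    lib_proteins = {p.protein_id for p in libraries.pav_inclusive}
    if not lib_proteins.issubset(set(model.protein_seqs)):
        raise SimulationError("library does not match the simulated gene model")

    rng = np.random.default_rng([config.seed, 37])
    samples = list(dosage.index)
    n = len(samples)
    variant_protein = {p.variant_id: p.protein_id for p in model.pavs}
    isoform_label = {p.variant_id: f"{p.protein_id}_{p.label}" for p in model.pavs}

    cov_effect = (
        config.beta_age * (covariates["age"].to_numpy() - 49.0)
        + config.beta_sex * (covariates["sex"].to_numpy() - 0.5)
        + config.beta_bmi * (covariates["bmi"].to_numpy() - 28.0)
        + config.beta_diabetes * (covariates["diabetes"].to_numpy() - 0.5)
    )

    true_beta: dict[str, float] = {}
    abundance: dict[str, np.ndarray] = {}
    for pid in model.protein_seqs:
        mu = config.log2_intensity_mean + rng.normal(0.0, 1.0)
        a = mu + cov_effect + rng.normal(0.0, config.protein_sd, size=n)
        abundance[pid] = a
    for pav in model.pavs:
        beta = config.pqtl_beta if config.scenario == "true_pqtl" else 0.0
        true_beta[pav.variant_id] = beta
        if beta:
            abundance[pav.protein_id] = (
                abundance[pav.protein_id] + beta * dosage[pav.variant_id].to_numpy()
            )

    np_labels = [f"NP{i + 1}" for i in range(config.n_nanoparticles)]
    np_offsets = {lab: rng.normal(0.0, 0.3) for lab in np_labels}

    entries = _dedup_entries(libraries)
    report_rows: dict[str, list[pd.DataFrame]] = {lab: [] for lab in np_labels}
    sample_arr = np.array(samples)
    peptide_truth_rows = []

    for entry in entries:
        k = int(rng.integers(1, config.n_nanoparticles + 1))
        entry_nps = list(rng.choice(np_labels, size=k, replace=False))
        charges = [2] + ([3] if rng.random() < 0.3 else [])
        if entry.origin == ORIGIN_INVARIANT or config.scenario == "null":
            ion = rng.normal(0.0, config.ionization_sd)
        else:
            # allele-specific peptides are detection-conditioned: a variant
            # peptide only ever enters an MS-PAV analysis because it ionizes
            # and detects well, so its response factor is drawn high
            ion = rng.normal(config.variant_ion_mean, config.variant_ion_sd)

        if entry.origin == ORIGIN_INVARIANT or config.scenario == "null":
            factor_log2 = np.zeros(n)
            carriers = np.ones(n, dtype=bool)
        else:
            d = dosage[entry.variant_id].to_numpy(dtype=float)
            copies = d if entry.origin == ORIGIN_ALT else 2.0 - d
            with np.errstate(divide="ignore"):
                factor_log2 = np.log2(copies / 2.0)
            carriers = copies > 0

        pg = entry.protein_id
        if entry.origin == ORIGIN_ALT:
            pg = isoform_label[entry.variant_id]

        base = abundance[entry.protein_id] + ion + factor_log2
        peptide_truth_rows.append(
            {
                "sequence": entry.sequence,
                "protein_id": entry.protein_id,
                "protein_group": pg,
                "origin": entry.origin,
                "variant_id": entry.variant_id,
                "missed_cleavages": entry.missed_cleavages,
                "nanoparticles": ",".join(sorted(entry_nps)),
                "charges": ",".join(map(str, charges)),
                "ionization_log2": ion,
            }
        )

        for lab in entry_nps:
            jitter = rng.normal(0.0, 0.2)
            for charge in charges:
                level = (
                    base
                    + np_offsets[lab]
                    + jitter
                    + rng.normal(0.0, config.noise_sd, size=n)
                )
                if entry.origin == ORIGIN_INVARIANT:
                    detected = rng.random(n) > config.missingness
                elif config.scenario == "null":
                    detected = rng.random(n) < config.detection_sensitivity
                else:
                    detected = np.zeros(n, dtype=bool)
                    if carriers.sum() >= 2:
                        thr = np.quantile(level[carriers], 1.0 - config.detection_sensitivity)
                        detected[carriers] = level[carriers] > thr
                    else:  # degenerate cohort; detect all carriers
                        thr = np.nanmin(level[carriers]) - 1.0 if carriers.any() else 0.0
                        detected[carriers] = True
                    fp = rng.random(n) < config.detection_fpr
                    fp_idx = (~carriers) & fp
                    level = level.copy()
                    level[fp_idx] = thr + np.abs(rng.normal(0.0, 0.3, size=int(fp_idx.sum())))
                    detected |= fp_idx
                if not detected.any():
                    continue
                report_rows[lab].append(
                    pd.DataFrame(
                        {
                            "Run": sample_arr[detected],
                            "Protein.Group": pg,
                            "Stripped.Sequence": entry.sequence,
                            "Precursor.Charge": charge,
                            "Precursor.Quantity": np.exp2(level[detected]),
                        }
                    )
                )

    reports = {
        lab: (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(
                columns=[
                    "Run",
                    "Protein.Group",
                    "Stripped.Sequence",
                    "Precursor.Charge",
                    "Precursor.Quantity",
                ]
            )
        )
        for lab, frames in report_rows.items()
    }

    variants_truth = pd.DataFrame(
        [
            {
                "variant_id": pav.variant_id,
                "rsid": pav.rsid,
                "protein_id": pav.protein_id,
                "protein_pos": pav.protein_pos,
                "ref_aa": pav.ref_aa,
                "alt_aa": pav.alt_aa,
                "scenario_class": config.scenario,
                "true_beta": true_beta[pav.variant_id],
                "maf": pav.maf,
                "maf_observed": float(
                    min(dosage[pav.variant_id].mean() / 2, 1 - dosage[pav.variant_id].mean() / 2)
                ),
            }
            for pav in model.pavs
        ]
    )
    truth = SimTruth(
        variants=variants_truth,
        peptides=pd.DataFrame(peptide_truth_rows),
        config=config,
    )
    return reports, truth


# ---------------------------------------------------------------------------
# Convenience bundles


def simulate_study(config: SimConfig) -> SimStudy:
    """End-to-end: gene model -> libraries -> genotypes -> reports."""
    model = simulate_gene_model(config)
    pavs = filter_pavs_by_maf(model.pavs, threshold=0.0)  # range validation only
    libraries = build_libraries(model.protein_seqs, pavs)
    dosage, covariates, vcf_text = simulate_genotypes(config, pavs)
    reports, truth = simulate_report(config, model, libraries, dosage, covariates)
    return SimStudy(
        model=model,
        libraries=libraries,
        dosage=dosage,
        covariates=covariates,
        vcf_text=vcf_text,
        reports=reports,
        truth=truth,
        config=config,
    )


def write_study(study: SimStudy, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "genome.fa").write_text(study.model.genome_fasta_text)
    (out / "model.bed").write_text(study.model.bed_text)
    (out / "proteins.fa").write_text(study.model.protein_fasta_text)
    (out / "genotypes.vcf").write_text(study.vcf_text)
    study.dosage.to_csv(out / "dosage.tsv", sep="\t")
    study.covariates.to_csv(out / "covariates.tsv", sep="\t")
    for lab, df in study.reports.items():
        df.to_csv(out / f"report_{lab}.tsv", sep="\t", index=False)
    study.truth.variants.to_csv(out / "truth_variants.tsv", sep="\t", index=False)
    study.truth.peptides.to_csv(out / "truth_peptides.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# Model-level parameter-recovery dataset (inverse-normal scale)


def simulate_pqtl_dataset(
    beta: float,
    maf: float,
    n: int,
    seed: int,
    covariate_beta: float = 0.1,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Protein, genotype and covariates for slope-recovery simulations.

    The outcome is generated directly on the inverse-normal scale with unit
    marginal variance (effect sizes in pQTL studies are reported in these
    units): y = beta*g + covariate effects + residual, with the residual
    variance set to 1 minus the explained variance.
    """
    rng = np.random.default_rng(seed)
    g = rng.binomial(2, maf, size=n).astype(float)
    cov = pd.DataFrame(
        {
            "age": rng.uniform(18, 80, size=n),
            "sex": rng.integers(0, 2, size=n).astype(float),
            "bmi": rng.normal(28.0, 4.5, size=n),
            "diabetes": rng.integers(0, 2, size=n).astype(float),
            "pc1": rng.normal(size=n),
            "pc2": rng.normal(size=n),
            "pc3": rng.normal(size=n),
        }
    )
    cov_std = (cov - cov.mean()) / cov.std(ddof=0)
    explained = beta**2 * 2 * maf * (1 - maf) + covariate_beta**2 * cov.shape[1]
    if explained >= 1.0:
        raise SimulationError(f"explained variance {explained:.3f} >= 1; reduce effect sizes")
    resid_sd = float(np.sqrt(1.0 - explained))
    y = (
        beta * g
        + covariate_beta * cov_std.sum(axis=1).to_numpy()
        + rng.normal(0.0, resid_sd, size=n)
    )
    return y, g, cov
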