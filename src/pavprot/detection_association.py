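"""Detection matrices and the Fisher's-exact MS-PAV framework.

A *signal* is one unique (variant peptide, allele, nanoparticle, precursor
charge, missed-cleavage) combination; per signal the quantification reports
yield a boolean detection vector across samples. Each signal is tested for
association with donor genotype in two 2x2 tables — detection versus
carriage (>= 1 copy) of the major allele, and versus carriage of the minor
allele — with a two-sided Fisher's exact test; the stronger of the two
(p_maj / p_min) is reported, and significance is Bonferroni-controlled over
the full signal family.

The Fisher p-value is computed by direct hypergeometric enumeration with
the conventional relative tie tolerance of 1e-7 (the behaviour of R's
``fisher.test``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

SIGNAL_LEVELS = [
    "peptide_sequence",
    "variant_id",
    "allele",
    "nanoparticle",
    "precursor_charge",
    "missed_cleavages",
]


class AssociationError(ValueError):
    pass


@dataclass(frozen=True)
class DetectionSignal:
    peptide_sequence: str
    variant_id: str
    allele: str  # "ref" | "alt"
    nanoparticle: str
    precursor_charge: int
    missed_cleavages: int


@dataclass
class FisherResult:
    signal: Optional[DetectionSignal]
    table_major: np.ndarray
    table_minor: np.ndarray
    p_maj: float
    p_min: float
    n_detected: int
    n: int
    degenerate: bool = False

    @property
    def p_best(self) -> float:
        return min(self.p_maj, self.p_min)

    @property
    def allele_best(self) -> str:
        # tie broken toward the minor allele for deterministic output
        return "minor" if self.p_min <= self.p_maj else "major"


@dataclass
class PeptideLmResult:
    signal: Optional[DetectionSignal]
    beta: float
    p_x: float
    n: int


# ---------------------------------------------------------------------------
# Fisher's exact test


def fisher_exact_2x2(table, relative_gap: float = 1e-7) -> float:
    """Two-sided Fisher's exact p-value for a 2x2 table of counts.

    Enumerates the full hypergeometric support with fixed margins and sums
    the probabilities of every table no more probable than the observed one,
    allowing a relative gap of ``relative_gap`` when comparing tied
    probabilities. A table with a zero margin is degenerate and returns 1.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise AssociationError(f"not a non-negative 2x2 count table: {table!r}")
    a = int(t[0, 0])
    n_total = int(t.sum())
    r = int(t[0].sum())  # row-1 margin
    c = int(t[:, 0].sum())  # col-1 margin
    if r == 0 or c == 0 or r == n_total or c == n_total:
        return 1.0
    k_lo = max(0, r + c - n_total)
    k_hi = min(r, c)
    ks = np.arange(k_lo, k_hi + 1)
    pmf = hypergeom.pmf(ks, n_total, r, c)
    p_obs = pmf[a - k_lo]
    p = float(pmf[pmf <= p_obs * (1.0 + relative_gap)].sum())
    return min(p, 1.0)


def fisher_detection_test(
    detections, genotypes, signal: Optional[DetectionSignal] = None
) -> FisherResult:
    """Fisher's exact test of peptide detection against allele carriage.

    ``genotypes`` are minor(alternate)-allele dosages in {0, 1, 2} with NaN
    (or negative) for missing; missing-genotype samples are excluded.
    Carriage means at least one copy of the allele: minor carriers have
    dosage >= 1, major carriers have dosage <= 1. Both 2x2 tables
    (rows: detected / not detected, columns: carrier / non-carrier) are
    tested two-sided.
    """
    d = np.asarray(detections, dtype=float)
    g = np.asarray(genotypes, dtype=float)
    if d.shape != g.shape:
        raise AssociationError("detections and genotypes are not aligned")
    keep = np.isfinite(g) & (g >= 0)
    if not keep.any():
        raise AssociationError("all genotypes missing")
    d = d[keep].astype(bool)
    g = g[keep]

    def table(carrier: np.ndarray) -> np.ndarray:
        return np.array(
            [
                [int((d & carrier).sum()), int((d & ~carrier).sum())],
                [int((~d & carrier).sum()), int((~d & ~carrier).sum())],
            ]
        )

    t_min = table(g >= 1)
    t_maj = table(g <= 1)
    degenerate = any(
        m == 0 or m == t.sum()
        for t in (t_min, t_maj)
        for m in (t[0].sum(), t[:, 0].sum())
    )
    return FisherResult(
        signal=signal,
        table_major=t_maj,
        table_minor=t_min,
        p_maj=fisher_exact_2x2(t_maj),
        p_min=fisher_exact_2x2(t_min),
        n_detected=int(d.sum()),
        n=int(keep.sum()),
        degenerate=degenerate,
    )


def bonferroni_threshold(alpha: float = 0.05, n_signals: int = 1) -> float:
    """Family-wise threshold alpha / n_signals."""
    if n_signals < 1:
        raise AssociationError(f"n_signals must be >= 1, got {n_signals}")
    return alpha / n_signals


# ---------------------------------------------------------------------------
# Report -> detection matrix


def _normalize_reports(
    reports: Union[pd.DataFrame, Mapping[str, pd.DataFrame]]
) -> pd.DataFrame:
    """Stack per-nanoparticle DIA report tables into one long frame."""
    rename = {
        "Run": "sample",
        "Stripped.Sequence": "sequence",
        "Precursor.Charge": "precursor_charge",
        "Precursor.Quantity": "quantity",
        "Protein.Group": "protein_group",
    }
    if isinstance(reports, Mapping):
        frames = []
        for label, df in reports.items():
            df = df.rename(columns=rename).copy()
            df["nanoparticle"] = label
            frames.append(df)
        long = pd.concat(frames, ignore_index=True)
    else:
        long = reports.rename(columns=rename).copy()
        if "nanoparticle" not in long.columns:
            long["nanoparticle"] = "NP1"
    required = {"sample", "sequence", "precursor_charge", "quantity", "nanoparticle"}
    missing = required - set(long.columns)
    if missing:
        raise AssociationError(f"report missing columns: {sorted(missing)}")
    return long


def detections_from_report(
    reports: Union[pd.DataFrame, Mapping[str, pd.DataFrame]],
    libraries,
    samples: Optional[Sequence[str]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Detection (boolean) and intensity matrices over variant-peptide signals.

    Signals are enumerated only for peptides annotated ``ref_allele`` or
    ``alt_allele`` in the PAV-inclusive library. Detection is a strictly
    positive quantity for that precursor in that sample. Report peptides
    absent from the library are counted and ignored; duplicate
    (sample, precursor) rows keep the maximum quantity with a warning.
    Rows are indexed by the signal tuple, columns by sample.
    """
    long = _normalize_reports(reports)
    annot = libraries.annotation_frame()
    lib_sequences = set(annot["sequence"])
    unknown = ~long["sequence"].isin(lib_sequences)
    if unknown.any():
        logger.info(
            "%d report rows (%d sequences) absent from library, ignored",
            int(unknown.sum()),
            long.loc[unknown, "sequence"].nunique(),
        )
        long = long[~unknown]

    key = ["nanoparticle", "sample", "sequence", "precursor_charge"]
    dup = long.duplicated(key, keep=False)
    if dup.any():
        logger.warning(
            "%d duplicate (sample, precursor) report rows; keeping maximum quantity",
            int(dup.sum()),
        )
        long = long.groupby(key, as_index=False)["quantity"].max()

    variant_annot = annot[annot["origin"].isin(["ref_allele", "alt_allele"])].copy()
    variant_annot["allele"] = variant_annot["origin"].map(
        {"ref_allele": "ref", "alt_allele": "alt"}
    )
    variant_annot = variant_annot[
        ["sequence", "variant_id", "allele", "missed_cleavages"]
    ].drop_duplicates()

    merged = long.merge(variant_annot, on="sequence", how="inner")
    merged = merged[merged["quantity"] > 0]

    if samples is None:
        samples = sorted(long["sample"].unique())
    samples = list(samples)

    index_cols = [
        "sequence",
        "variant_id",
        "allele",
        "nanoparticle",
        "precursor_charge",
        "missed_cleavages",
    ]
    if merged.empty:
        empty_idx = pd.MultiIndex.from_arrays([[] for _ in SIGNAL_LEVELS], names=SIGNAL_LEVELS)
        empty = pd.DataFrame(index=empty_idx, columns=samples, dtype=float)
        return empty.astype(bool), empty

    intens = merged.pivot_table(
        index=index_cols, columns="sample", values="quantity", aggfunc="max"
    )
    intens.index.names = SIGNAL_LEVELS
    intens = intens.reindex(columns=samples)
    detect = intens.notna() & (intens > 0)
    return detect, intens


# ---------------------------------------------------------------------------
# MS-PAV calling


def scan_signals(
    detections: pd.DataFrame, dosage: pd.DataFrame
) -> list[FisherResult]:
    """Run the Fisher detection test for every signal row.

    ``dosage`` is samples x variant_id with minor-allele copies; samples
    missing from the genotype table are dropped per test.
    """
    shared = [s for s in detections.columns if s in dosage.index]
    if not shared:
        raise AssociationError("no samples shared between detections and genotypes")
    if len(shared) < len(detections.columns):
        logger.info(
            "%d proteomics samples lack genotypes and are dropped",
            len(detections.columns) - len(shared),
        )
    results = []
    for idx, row in detections.iterrows():
        sig = DetectionSignal(
            peptide_sequence=idx[0],
            variant_id=idx[1],
            allele=idx[2],
            nanoparticle=str(idx[3]),
            precursor_charge=int(idx[4]),
            missed_cleavages=int(idx[5]),
        )
        if sig.variant_id not in dosage.columns:
            logger.warning("variant %s absent from genotype table; signal skipped", sig.variant_id)
            continue
        g = dosage.loc[shared, sig.variant_id].to_numpy(dtype=float)
        d = row[shared].to_numpy(dtype=bool)
        results.append(fisher_detection_test(d, g, signal=sig))
    return results


def call_mspavs(
    results: Sequence[FisherResult],
    alpha: float = 0.05,
    variant_to_protein: Optional[Mapping[str, str]] = None,
) -> tuple[pd.DataFrame, dict]:
    """Bonferroni-corrected MS-PAV calls plus a de-duplicated summary.

    The family size is the number of tested signals; a signal is significant
    iff p_best < alpha / n_signals (strict). The summary de-duplicates
    significant signals to unique peptides, variants and (when a mapping is
    given) genes/proteins.
    """
    if not results:
        return pd.DataFrame(), {
            "n_signals": 0,
            "n_significant": 0,
            "threshold": None,
            "n_unique_peptides": 0,
            "n_unique_variants": 0,
            "n_unique_genes": 0,
        }
    threshold = bonferroni_threshold(alpha, len(results))
    rows = []
    for r in results:
        sig = r.signal
        rows.append(
            {
                "peptide_sequence": sig.peptide_sequence if sig else None,
                "variant_id": sig.variant_id if sig else None,
                "allele": sig.allele if sig else None,
                "nanoparticle": sig.nanoparticle if sig else None,
                "precursor_charge": sig.precursor_charge if sig else None,
                "missed_cleavages": sig.missed_cleavages if sig else None,
                "n": r.n,
                "n_detected": r.n_detected,
                "p_maj": r.p_maj,
                "p_min": r.p_min,
                "p_best": r.p_best,
                "allele_best": r.allele_best,
                "degenerate": r.degenerate,
                "significant": r.p_best < threshold,
            }
        )
    table = pd.DataFrame(rows)
    sig_table = table[table["significant"]]
    genes = 0
    if variant_to_protein is not None:
        genes = sig_table["variant_id"].map(variant_to_protein).nunique()
    summary = {
        "n_signals": len(table),
        "n_significant": int(table["significant"].sum()),
        "threshold": threshold,
        "n_unique_peptides": int(sig_table["peptide_sequence"].nunique()),
        "n_unique_variants": int(sig_table["variant_id"].nunique()),
        "n_unique_genes": int(genes),
    }
    return table, summary


# ---------------------------------------------------------------------------
# Peptide-level linear model (pX)


def peptide_intensity_genotype_lm(
    intensities, genotypes, signal: Optional[DetectionSignal] = None
) -> PeptideLmResult:
    """OLS of peptide intensity on genotype (0-1-2), missing intensities = 0.

    This is the peptide-level pX model: undetected peptides contribute zero
    intensity, so the slope captures allele-dosage scaling of the variant
    peptide's abundance. Samples with missing genotype are excluded.
    """
    y = np.asarray(intensities, dtype=float)
    g = np.asarray(genotypes, dtype=float)
    if y.shape != g.shape:
        raise AssociationError("intensities and genotypes are not aligned")
    keep = np.isfinite(g) & (g >= 0)
    y = np.nan_to_num(y[keep], nan=0.0)
    g = g[keep]
    if g.size < 3:
        raise AssociationError(f"need >= 3 genotyped samples, got {g.size}")
    if np.ptp(g) == 0:
        raise AssociationError("genotype vector is constant")
    X = sm.add_constant(g)
    fit = sm.OLS(y, X).fit()
    return PeptideLmResult(signal=signal, beta=float(fit.params[1]), p_x=float(fit.pvalues[1]), n=int(g.size))
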