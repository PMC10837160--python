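"""Protein roll-up, inverse-normal transformation, MS-pQTL and PWAS models.

Protein quantities are rolled up per (protein, nanoparticle) from the
peptides of a chosen library — either the median of log2 intensities of
detected peptides (default) or the sum of raw intensities. pQTL models
regress rank-based inverse-normal protein intensities (missing excluded) on
minor-allele dosage with age, sex, BMI, diabetes status and three genotype
principal components as covariates. Comparing the reference-library and
PAV-exclusive-library associations classifies each variant into one of
three regimens: a robust pQTL (significant in both), an epitope effect
(significant only with the reference library — the association is an
artifact of genotype-dependent variant-peptide detection), or underpowered
(significant in neither).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm, rankdata, spearmanr

logger = logging.getLogger(__name__)

COVARIATE_COLUMNS = ["age", "sex", "bmi", "diabetes", "pc1", "pc2", "pc3"]

ROBUST_PQTL = "robust_pqtl"
EPITOPE_EFFECT = "epitope_effect"
UNDERPOWERED = "underpowered"


class QuantError(ValueError):
    pass


@dataclass
class PqtlResult:
    variant_id: str
    protein_group: str
    library_tag: str  # "reference" | "pav_exclusive"
    beta: float
    se: float
    p_y: float
    n: int


@dataclass
class RegimenCall:
    variant_id: str
    protein_group: str
    regimen: str
    p_reference: float
    p_exclusive: float
    discordant: bool = False


# ---------------------------------------------------------------------------
# Roll-up


def rollup_protein(
    peptide_intensities: pd.DataFrame,
    library_peptides,
    method: str = "median_log",
) -> pd.DataFrame:
    """Roll peptide intensities up to (protein, nanoparticle) x sample.

    ``peptide_intensities`` is a long frame with columns ``sample``,
    ``nanoparticle``, ``sequence`` and ``quantity`` (one row per detected
    precursor; charge states of the same peptide each contribute).
    ``library_peptides`` restricts membership: only sequences present in the
    given library contribute, mapped to their protein. ``median_log`` takes
    the median of log2 intensities of the detected member peptides; ``sum``
    adds the raw intensities (missing treated as absent).
    """
    if method not in {"median_log", "sum"}:
        raise QuantError(f"unknown roll-up method {method!r}")
    members = pd.DataFrame(
        {
            "sequence": [p.sequence for p in library_peptides],
            "protein_id": [p.protein_id for p in library_peptides],
        }
    ).drop_duplicates()
    long = peptide_intensities.copy()
    if "nanoparticle" not in long.columns:
        long["nanoparticle"] = "NP1"
    long = long[long["quantity"] > 0]
    merged = long.merge(members, on="sequence", how="inner")
    dropped = set(members["protein_id"]) - set(merged["protein_id"])
    if dropped:
        logger.info("%d proteins have no detected library peptides", len(dropped))
    if merged.empty:
        return pd.DataFrame()
    if method == "median_log":
        merged["value"] = np.log2(merged["quantity"])
        agg = merged.groupby(["protein_id", "nanoparticle", "sample"])["value"].median()
    else:
        agg = merged.groupby(["protein_id", "nanoparticle", "sample"])["quantity"].sum()
    return agg.unstack("sample")


# ---------------------------------------------------------------------------
# Inverse-normal transformation


def inverse_normal(values) -> np.ndarray:
    """Rank-based inverse-normal transform with the Blom offset.

    Average ranks for ties, quantiles (r - 3/8) / (n + 1/4), missing values
    stay missing. All-identical input is untransformable and raises.
    """
    v = np.asarray(values, dtype=float)
    out = np.full(v.shape, np.nan)
    mask = np.isfinite(v)
    n = int(mask.sum())
    if n < 3:
        raise QuantError(f"need >= 3 non-missing values, got {n}")
    obs = v[mask]
    if np.ptp(obs) == 0:
        raise QuantError("all values identical; inverse-normal transform undefined")
    ranks = rankdata(obs, method="average")
    out[mask] = norm.ppf((ranks - 0.375) / (n + 0.25))
    return out


# ---------------------------------------------------------------------------
# Linear models


def _design_matrix(
    genotype: Optional[np.ndarray], covariates: Optional[pd.DataFrame]
) -> pd.DataFrame:
    parts = {}
    if genotype is not None:
        parts["genotype"] = genotype
    X = pd.DataFrame(parts)
    if covariates is not None:
        X = pd.concat([X.reset_index(drop=True), covariates.reset_index(drop=True)], axis=1)
    X.insert(0, "const", 1.0)
    return X


def _check_full_rank(X: pd.DataFrame) -> None:
    mat = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        # name offending columns: those whose removal restores the rank deficit
        collinear = []
        for j, col in enumerate(X.columns):
            sub = np.delete(mat, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                collinear.append(col)
        raise QuantError(f"design matrix is rank-deficient; collinear columns: {collinear}")


def pqtl_lm(
    protein,
    genotype,
    covariates: Optional[pd.DataFrame] = None,
    variant_id: str = "",
    protein_group: str = "",
    library_tag: str = "",
) -> PqtlResult:
    """Covariate-adjusted pQTL model (pY).

    The protein vector is inverse-normalized over its non-missing entries,
    then regressed on minor-allele dosage plus covariates on complete
    cases. Rank-deficient designs and constant genotypes are errors.
    """
    y = np.asarray(protein, dtype=float)
    g = np.asarray(genotype, dtype=float)
    if y.shape != g.shape:
        raise QuantError("protein and genotype are not aligned")
    if covariates is not None:
        cov = pd.DataFrame(covariates).reset_index(drop=True)
        if len(cov) != y.size:
            raise QuantError("covariates are not aligned with protein vector")
        cov_ok = np.isfinite(cov.to_numpy(dtype=float)).all(axis=1)
    else:
        cov = None
        cov_ok = np.ones(y.size, dtype=bool)
    keep = np.isfinite(y) & np.isfinite(g) & (g >= 0) & cov_ok
    n_cov = 0 if cov is None else cov.shape[1]
    if keep.sum() < n_cov + 3:
        raise QuantError(f"only {int(keep.sum())} complete cases for {n_cov + 2}-term model")
    y_t = inverse_normal(y[keep])
    g_k = g[keep]
    if np.ptp(g_k) == 0:
        raise QuantError("genotype vector is constant")
    cov_k = cov.loc[keep].reset_index(drop=True) if cov is not None else None
    X = _design_matrix(g_k, cov_k)
    _check_full_rank(X)
    fit = sm.OLS(y_t, X).fit()
    return PqtlResult(
        variant_id=variant_id,
        protein_group=protein_group,
        library_tag=library_tag,
        beta=float(fit.params["genotype"]),
        se=float(fit.bse["genotype"]),
        p_y=float(fit.pvalues["genotype"]),
        n=int(keep.sum()),
    )


def call_mspqtls(results: Sequence[PqtlResult], threshold: float = 5e-8) -> pd.DataFrame:
    """MS-pQTL table: variants with p_y strictly below genome-wide 5e-8."""
    rows = [
        {
            "variant_id": r.variant_id,
            "protein_group": r.protein_group,
            "library_tag": r.library_tag,
            "beta": r.beta,
            "se": r.se,
            "p_y": r.p_y,
            "n": r.n,
            "significant": r.p_y < threshold,
        }
        for r in results
    ]
    table = pd.DataFrame(
        rows,
        columns=[
            "variant_id",
            "protein_group",
            "library_tag",
            "beta",
            "se",
            "p_y",
            "n",
            "significant",
        ],
    )
    return table[table["significant"]].reset_index(drop=True)


def classify_regimens(
    result_ref: PqtlResult, result_excl: PqtlResult, threshold: float = 5e-8
) -> RegimenCall:
    """Three-regimen classification of a variant/protein pair.

    Significant with both libraries -> robust pQTL; significant with the
    reference library only -> epitope effect (the association is carried by
    the genotype-dependent variant peptides); neither -> underpowered.
    Significance only with the PAV-exclusive library is not an enumerated
    configuration; it is classed robust with a discordance flag.
    """
    sig_ref = result_ref.p_y < threshold
    sig_excl = result_excl.p_y < threshold
    if sig_excl:
        regimen, discordant = ROBUST_PQTL, not sig_ref
    elif sig_ref:
        regimen, discordant = EPITOPE_EFFECT, False
    else:
        regimen, discordant = UNDERPOWERED, False
    return RegimenCall(
        variant_id=result_ref.variant_id,
        protein_group=result_ref.protein_group,
        regimen=regimen,
        p_reference=result_ref.p_y,
        p_exclusive=result_excl.p_y,
        discordant=discordant,
    )


def pwas_lm(
    protein,
    covariates: pd.DataFrame,
    protein_group: str = "",
) -> pd.DataFrame:
    """Proteome-wide association of non-genetic determinants.

    One joint OLS per protein: inverse-normal protein levels against all
    determinants simultaneously; returns coefficient, SE and p per
    determinant. The caller is responsible for the >80% detection filter.
    """
    y = np.asarray(protein, dtype=float)
    cov = pd.DataFrame(covariates).reset_index(drop=True)
    if len(cov) != y.size:
        raise QuantError("covariates are not aligned with protein vector")
    keep = np.isfinite(y) & np.isfinite(cov.to_numpy(dtype=float)).all(axis=1)
    if keep.sum() < cov.shape[1] + 2:
        raise QuantError(
            f"only {int(keep.sum())} complete cases for {cov.shape[1] + 1}-term model"
        )
    y_t = inverse_normal(y[keep])
    X = _design_matrix(None, cov.loc[keep].reset_index(drop=True))
    _check_full_rank(X)
    fit = sm.OLS(y_t, X).fit()
    rows = []
    for det in cov.columns:
        rows.append(
            {
                "protein_group": protein_group,
                "determinant": det,
                "coef": float(fit.params[det]),
                "se": float(fit.bse[det]),
                "p": float(fit.pvalues[det]),
                "n": int(keep.sum()),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Library comparison


def compare_library_quants(
    quant_a: pd.DataFrame,
    quant_b: pd.DataFrame,
    min_obs: int = 3,
    high: float = 0.8,
    low: float = 0.5,
) -> tuple[pd.Series, dict]:
    """Per-protein Spearman correlation between two protein matrices.

    Rows (protein or protein/nanoparticle) and columns (samples) are
    aligned; correlation is pairwise-complete per row; rows with fewer than
    ``min_obs`` shared observations are excluded from summary denominators.
    Returns the rho series plus counts/fractions above ``high`` and below
    ``low``.
    """
    shared_rows = quant_a.index.intersection(quant_b.index)
    shared_cols = quant_a.columns.intersection(quant_b.columns)
    rhos = {}
    excluded = 0
    for row in shared_rows:
        a = quant_a.loc[row, shared_cols].to_numpy(dtype=float)
        b = quant_b.loc[row, shared_cols].to_numpy(dtype=float)
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() < min_obs:
            excluded += 1
            logger.warning("row %r has < %d shared observations; excluded", row, min_obs)
            continue
        rhos[row] = float(spearmanr(a[ok], b[ok]).statistic)
    rho = pd.Series(rhos, dtype=float)
    n = len(rho)
    summary = {
        "n_compared": n,
        "n_excluded": excluded,
        "n_high": int((rho > high).sum()),
        "frac_high": float((rho > high).mean()) if n else np.nan,
        "n_low": int((rho < low).sum()),
        "frac_low": float((rho < low).mean()) if n else np.nan,
    }
    return rho, summary
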