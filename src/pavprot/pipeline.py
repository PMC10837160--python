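"""End-to-end analysis wrappers used by the CLI and the acceptance runs."""

from __future__ import annotations

import logging
from typing import Mapping, Optional, Sequence

import pandas as pd

from .detection_association import (
    FisherResult,
    _normalize_reports,
    call_mspavs,
    detections_from_report,
    scan_signals,
)
from .quantitative_association import (
    COVARIATE_COLUMNS,
    PqtlResult,
    RegimenCall,
    classify_regimens,
    pqtl_lm,
    rollup_protein,
)

logger = logging.getLogger(__name__)


def mspav_analysis(
    reports,
    libraries,
    dosage: pd.DataFrame,
    alpha: float = 0.05,
    variant_to_protein: Optional[Mapping[str, str]] = None,
) -> tuple[pd.DataFrame, dict, list[FisherResult]]:
    """Reports -> detection matrix -> per-signal Fisher tests -> MS-PAV calls."""
    detect, _ = detections_from_report(reports, libraries, samples=list(dosage.index))
    results = scan_signals(detect, dosage)
    table, summary = call_mspavs(results, alpha=alpha, variant_to_protein=variant_to_protein)
    return table, summary, results


def pqtl_comparison(
    reports,
    libraries,
    pavs,
    dosage: pd.DataFrame,
    covariates: pd.DataFrame,
    method: str = "sum",
    threshold: float = 5e-8,
) -> tuple[pd.DataFrame, list[RegimenCall]]:
    """Reference-library vs PAV-exclusive-library pQTL scan per variant.

    Protein quantities are rolled up per nanoparticle from each library's
    peptides (the ``sum`` roll-up preserves the dose response of a missing
    variant peptide; see the methods note), modeled with ``pqtl_lm`` per
    nanoparticle, and — since which nanoparticle carries a protein best is
    not knowable a priori — the nanoparticle with the smallest
    reference-library p-value is flagged and used for the three-regimen
    classification of each variant.
    """
    long = _normalize_reports(reports)
    roll_ref = rollup_protein(long, libraries.reference, method=method)
    roll_excl = rollup_protein(long, libraries.pav_exclusive, method=method)
    samples = list(dosage.index)
    cov = covariates.loc[samples, [c for c in COVARIATE_COLUMNS if c in covariates.columns]]

    rows = []
    calls: list[RegimenCall] = []
    for pav in pavs:
        vid, pid = pav.variant_id, pav.protein_id
        g = dosage.loc[samples, vid].to_numpy(dtype=float)
        per_np: list[tuple[str, PqtlResult, PqtlResult]] = []
        for key in roll_ref.index:
            if key[0] != pid or key not in roll_excl.index:
                continue
            np_label = key[1]
            y_ref = roll_ref.loc[key].reindex(samples).to_numpy(dtype=float)
            y_excl = roll_excl.loc[key].reindex(samples).to_numpy(dtype=float)
            res_ref = pqtl_lm(y_ref, g, cov, variant_id=vid, protein_group=pid, library_tag="reference")
            res_excl = pqtl_lm(
                y_excl, g, cov, variant_id=vid, protein_group=pid, library_tag="pav_exclusive"
            )
            per_np.append((np_label, res_ref, res_excl))
            rows.append(
                {
                    "variant_id": vid,
                    "protein_group": pid,
                    "nanoparticle": np_label,
                    "beta_reference": res_ref.beta,
                    "p_reference": res_ref.p_y,
                    "beta_exclusive": res_excl.beta,
                    "se_exclusive": res_excl.se,
                    "p_exclusive": res_excl.p_y,
                    "n": res_excl.n,
                }
            )
        if not per_np:
            logger.warning("variant %s: protein %s missing from roll-ups", vid, pid)
            continue
        np_best, res_ref, res_excl = min(per_np, key=lambda t: t[1].p_y)
        call = classify_regimens(res_ref, res_excl, threshold=threshold)
        calls.append(call)
        for row in rows:
            if row["variant_id"] == vid:
                row["min_p_nanoparticle"] = row["nanoparticle"] == np_best
                row["regimen"] = call.regimen if row["nanoparticle"] == np_best else ""
    return pd.DataFrame(rows), calls
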