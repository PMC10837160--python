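"""Detection-fraction filters, cross-nanoparticle QC, genotype-concordance flags.

Peptides detected by more than one of the five nanoparticle fractions act
as internal technical replicates: their per-pair Spearman correlations
summarize data quality. A separate flag marks suspect variant-peptide
identifications where both alleles' peptides are detected nearly everywhere
regardless of genotype — the signature of two co-eluting precursors being
confused by the search engine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

logger = logging.getLogger(__name__)


@dataclass
class CorrelationSummary:
    pair_rho: pd.DataFrame  # columns: sequence, np_a, np_b, rho, n
    counts_by_n_nanoparticles: dict[int, int]
    n_peptides: int
    median_rho: float
    median_rho_two_fractions: float


def filter_by_detection_fraction(matrix: pd.DataFrame, min_frac: float) -> pd.DataFrame:
    """Keep rows detected in strictly more than ``min_frac`` of the samples.

    Detection is a strictly positive, non-missing value. Idempotent.
    """
    if not (0 <= min_frac < 1):
        raise ValueError(f"min_frac must be in [0, 1), got {min_frac}")
    detected = matrix.notna() & (matrix > 0)
    frac = detected.mean(axis=1)
    return matrix.loc[frac > min_frac]


def cross_nanoparticle_correlation(
    intensities: pd.DataFrame,
    charge_filter: Optional[int] = 2,
    min_frac: float = 0.2,
    min_shared: int = 3,
    samples: Optional[Sequence[str]] = None,
) -> CorrelationSummary:
    """Spearman correlation of each peptide across nanoparticle fractions.

    ``intensities`` is a long frame with columns ``nanoparticle``,
    ``sample``, ``sequence``, ``precursor_charge`` and ``quantity``. The
    analysis is restricted to precursors of ``charge_filter`` (default 2)
    that pass the detection-fraction filter per (peptide, nanoparticle);
    every nanoparticle pair a peptide appears in contributes one rho over
    pairwise-complete samples (pairs with fewer than ``min_shared`` shared
    samples are skipped).
    """
    long = intensities.copy()
    if charge_filter is not None and "precursor_charge" in long.columns:
        long = long[long["precursor_charge"] == charge_filter]
    long = long[long["quantity"] > 0]
    if samples is None:
        samples = sorted(long["sample"].unique())
    n_samples = len(samples)

    wide = long.pivot_table(
        index=["sequence", "nanoparticle"], columns="sample", values="quantity", aggfunc="max"
    ).reindex(columns=samples)
    frac = wide.notna().mean(axis=1)
    wide = wide.loc[frac > min_frac]

    per_peptide: dict[str, list[str]] = {}
    for seq, np_label in wide.index:
        per_peptide.setdefault(seq, []).append(np_label)

    counts: dict[int, int] = {}
    rows = []
    for seq, np_labels in per_peptide.items():
        k = len(np_labels)
        counts[k] = counts.get(k, 0) + 1
        for i in range(k):
            for j in range(i + 1, k):
                a = wide.loc[(seq, np_labels[i])].to_numpy(dtype=float)
                b = wide.loc[(seq, np_labels[j])].to_numpy(dtype=float)
                ok = np.isfinite(a) & np.isfinite(b)
                if ok.sum() < min_shared:
                    continue
                rho = float(spearmanr(a[ok], b[ok]).statistic)
                rows.append(
                    {
                        "sequence": seq,
                        "np_a": np_labels[i],
                        "np_b": np_labels[j],
                        "rho": rho,
                        "n": int(ok.sum()),
                    }
                )
    pair_rho = pd.DataFrame(rows, columns=["sequence", "np_a", "np_b", "rho", "n"])
    two_frac = {seq for seq, labels in per_peptide.items() if len(labels) == 2}
    rho_two = pair_rho[pair_rho["sequence"].isin(two_frac)]["rho"]
    return CorrelationSummary(
        pair_rho=pair_rho,
        counts_by_n_nanoparticles=dict(sorted(counts.items())),
        n_peptides=len(per_peptide),
        median_rho=float(pair_rho["rho"].median()) if len(pair_rho) else np.nan,
        median_rho_two_fractions=float(rho_two.median()) if len(rho_two) else np.nan,
    )


def genotype_concordance_flags(
    fisher_results: Iterable, threshold: float = 0.9
) -> pd.DataFrame:
    """Flag variants whose allele peptides are detected regardless of genotype.

    For each allele-specific signal the discordant-group detection rate is
    the fraction of samples *lacking* that allele in which the peptide was
    nevertheless detected. A variant is flagged when both its reference and
    alternate peptides exceed ``threshold`` in their discordant groups —
    the pattern of a spectral-confusion false positive.
    """
    rates: dict[str, dict[str, float]] = {}
    for r in fisher_results:
        sig = r.signal
        if sig is None:
            continue
        table = r.table_minor if sig.allele == "alt" else r.table_major
        non_carriers = table[0, 1] + table[1, 1]
        rate = table[0, 1] / non_carriers if non_carriers else np.nan
        entry = rates.setdefault(sig.variant_id, {"ref": np.nan, "alt": np.nan})
        prev = entry[sig.allele]
        entry[sig.allele] = rate if np.isnan(prev) else max(prev, rate)
    rows = []
    for variant_id, entry in rates.items():
        ref_rate, alt_rate = entry["ref"], entry["alt"]
        flagged = (
            np.isfinite(ref_rate)
            and np.isfinite(alt_rate)
            and ref_rate > threshold
            and alt_rate > threshold
        )
        rows.append(
            {
                "variant_id": variant_id,
                "ref_discordant_rate": ref_rate,
                "alt_discordant_rate": alt_rate,
                "flagged": bool(flagged),
            }
        )
    return pd.DataFrame(
        rows, columns=["variant_id", "ref_discordant_rate", "alt_discordant_rate", "flagged"]
    )
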