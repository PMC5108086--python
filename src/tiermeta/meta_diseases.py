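"""Tier 3: combine pathway p-values across diseases and gate on the index disease.

Per pathway, the per-disease enrichment p-values are merged with Fisher's
combined probability test, Bonferroni-corrected across the family of
pathways tested, and finally restricted to pathways that are also
significant (raw enrichment p < alpha) in the focal "index" disease.

Diseases in which a pathway has no overlap with the disease gene set carry
an enrichment p of 1.  The default ``include_ones`` policy keeps those
entries in the combination (full ``df = 2 * n_diseases``, they contribute
``ln 1 = 0`` to the statistic); ``drop_ones`` excludes them, shrinking the
degrees of freedom to ``2 * n_overlapping``.  Both policies yield the same
chi-square statistic and differ only in df.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import P_FLOOR
from .meta_genes import correlate_pvalues

logger = logging.getLogger(__name__)

POLICIES = ("include_ones", "drop_ones")


def combine_across_diseases(
    pathway_p: pd.DataFrame, policy: str = "include_ones"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fisher-combine each pathway's p-values across diseases.

    ``pathway_p`` is a wide table (index: pathway, one column per disease)
    of enrichment p-values on a shared filtered collection.  Returns
    ``(results, diagnostics)``: results carry the original per-disease
    columns plus ``chi2_stat``, ``df`` and ``combined_p``; diagnostics is
    the cross-disease Pearson correlation table (run first, flags warn).
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; expected one of {POLICIES}")
    if pathway_p.shape[1] < 2:
        raise ValueError("need p-values from at least 2 diseases")

    all_missing = pathway_p.isna().all(axis=1)
    if all_missing.any():
        logger.warning(
            "excluding %d pathway(s) absent from every disease: %s",
            int(all_missing.sum()), list(pathway_p.index[all_missing][:5]),
        )
        pathway_p = pathway_p.loc[~all_missing]

    if len(pathway_p) >= 3:
        diagnostics = correlate_pvalues(
            {str(c): pathway_p[c].dropna() for c in pathway_p.columns}
        )
    else:  # too few pathways for a meaningful correlation check
        logger.debug("skipping cross-disease correlation: <3 pathways")
        diagnostics = pd.DataFrame(
            columns=["id_a", "id_b", "pearson_r", "n", "test_p", "flagged"]
        )

    p = np.clip(pathway_p.to_numpy(dtype=float), P_FLOOR, 1.0)
    measured = ~pathway_p.isna().to_numpy()
    if policy == "drop_ones":
        used = measured & (p < 1.0)
    else:
        used = measured
    logs = np.where(used, np.log(p), 0.0)
    chi2_stat = -2.0 * logs.sum(axis=1)
    df = 2 * used.sum(axis=1)
    combined = np.ones(len(pathway_p))
    pos = df > 0
    combined[pos] = np.maximum(stats.chi2.sf(chi2_stat[pos], df[pos]), P_FLOOR)

    results = pathway_p.copy()
    results["chi2_stat"] = chi2_stat
    results["df"] = df
    results["combined_p"] = combined
    results.index.name = "pathway"
    return results, diagnostics


def bonferroni_family(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Bonferroni-correct ``combined_p`` over the family of tested pathways."""
    m = len(results)
    out = results.copy()
    out["bonferroni_p"] = np.minimum(1.0, m * out["combined_p"])
    out["significant"] = out["bonferroni_p"] < alpha
    return out


def filter_by_index_disease(
    results: pd.DataFrame, index_disease: str, alpha: float = 0.05
) -> pd.DataFrame:
    """Keep pathways significant overall *and* in the index disease.

    ``index_significant`` requires the raw enrichment p-value in
    ``index_disease`` to fall below ``alpha``.  The retained table is
    sorted by ``combined_p`` ascending (ties broken by pathway name).
    An empty result is a valid outcome and only warns.
    """
    if index_disease not in results.columns:
        raise ValueError(f"index disease {index_disease!r} not among result columns")
    out = results.copy()
    out["index_significant"] = out[index_disease] < alpha
    kept = out[out["significant"] & out["index_significant"]]
    # stable sorts: pathway name first, then combined_p, so ties break by name
    kept = kept.sort_index(kind="mergesort").sort_values("combined_p", kind="mergesort")
    if kept.empty:
        logger.warning("no pathway is significant both overall and in %s", index_disease)
    return kept
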