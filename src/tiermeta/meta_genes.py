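"""Tier 1: combine per-study gene p-values into per-disease combined p-values.

Fisher's combined probability test is applied per gene over the studies in
which the gene was measured: the statistic ``-2 * sum(ln p_i)`` follows a
chi-square distribution with ``2k`` degrees of freedom under ``k``
independent nulls.  A pairwise Pearson-correlation diagnostic of the
per-study p-value vectors guards the independence assumption (flags warn
but never abort), and four multiple-testing corrections (Bonferroni,
Benjamini-Yekutieli, Benjamini-Hochberg, none) are attached so a single
alpha threshold applies uniformly downstream.
"""

from __future__ import annotations

import itertools
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .diffexpr import P_FLOOR

logger = logging.getLogger(__name__)

CORRECTIONS = ("bonferroni", "by", "bh", "none")
_SM_METHOD = {"bonferroni": "bonferroni", "by": "fdr_by", "bh": "fdr_bh"}

CORR_R_THRESHOLD = 0.30
CORR_P_THRESHOLD = 0.05

META_COLUMNS = [
    "gene", "disease_id", "k", "chi2_stat", "df", "combined_p",
    "p_bonferroni", "p_by", "p_bh", "p_none",
]


def fisher_combine(p_list: Sequence[float]) -> tuple[float, int, float]:
    """Fisher's combined probability test.

    Returns ``(chi2_stat, df, combined_p)`` where ``chi2_stat = -2*sum(ln p)``
    and ``combined_p`` is the upper-tail chi-square probability on
    ``df = 2k``.  Inputs are clamped to ``>= 1e-300`` before taking logs.
    """
    p = np.asarray(p_list, dtype=float)
    if p.size == 0:
        raise ValueError("cannot combine an empty p-value list")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    p = np.clip(p, P_FLOOR, 1.0)
    stat = float(-2.0 * np.log(p).sum())
    df = 2 * p.size
    combined = float(stats.chi2.sf(stat, df))
    return stat, df, max(combined, P_FLOOR)


def adjust_pvalues(p_list: Sequence[float], method: str) -> np.ndarray:
    """Multiple-testing adjusted p-values, input order preserved.

    ``bonferroni``: min(1, m*p).  ``bh``/``by``: step-up adjusted values
    with enforced monotonicity (BY carries the harmonic-sum factor for
    arbitrary dependence).  ``none``: identity.
    """
    p = np.asarray(p_list, dtype=float)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    if method == "none":
        return p.copy()
    if method not in _SM_METHOD:
        raise ValueError(f"unknown correction {method!r}; expected one of {CORRECTIONS}")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method=_SM_METHOD[method])[1]


def correlate_pvalues(vectors: Mapping[str, pd.Series]) -> pd.DataFrame:
    """Pairwise Pearson correlation of p-value vectors over shared ids.

    Each pair is compared on the intersection of its indexes (>= 3 ids
    required).  A pair is ``flagged`` when ``|r| >= 0.30`` and the two-sided
    correlation test has ``p < 0.05``; a constant vector leaves ``r``
    undefined and the pair unflagged, with a warning.
    """
    rows = []
    for (id_a, sa), (id_b, sb) in itertools.combinations(vectors.items(), 2):
        common = sa.index.intersection(sb.index)
        n = len(common)
        if n < 3:
            raise ValueError(f"pair ({id_a}, {id_b}) shares only {n} ids; need >= 3")
        x = sa.loc[common].to_numpy(dtype=float)
        y = sb.loc[common].to_numpy(dtype=float)
        if np.std(x) == 0.0 or np.std(y) == 0.0:
            logger.warning(
                "pair (%s, %s): constant p-value vector, correlation undefined",
                id_a, id_b,
            )
            rows.append((id_a, id_b, np.nan, n, np.nan, False))
            continue
        r, test_p = stats.pearsonr(x, y)
        flagged = bool(abs(r) >= CORR_R_THRESHOLD and test_p < CORR_P_THRESHOLD)
        if flagged:
            logger.warning(
                "pair (%s, %s): p-values correlated (r=%.3f, p=%.3g); Fisher "
                "combination assumes independence", id_a, id_b, r, test_p,
            )
        rows.append((id_a, id_b, float(r), n, float(test_p), flagged))
    return pd.DataFrame(
        rows, columns=["id_a", "id_b", "pearson_r", "n", "test_p", "flagged"]
    )


def combine_disease_genes(
    study_stats: Mapping[str, pd.DataFrame], disease_id: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene Fisher combination over one disease's studies.

    ``study_stats`` maps study_id to a differential-expression table with
    ``gene`` and ``p`` columns.  Genes absent from some studies (platform
    differences) are combined over the studies that measured them, so ``k``
    varies per gene.  Returns ``(meta, diagnostics)``: the per-gene table
    with all four corrections, and the study-pair correlation diagnostic.
    """
    if not study_stats:
        raise ValueError("need at least one study")
    series = {
        sid: df.set_index("gene")["p"].astype(float) for sid, df in study_stats.items()
    }
    if len(series) >= 2:
        diagnostics = correlate_pvalues(series)
    else:
        diagnostics = pd.DataFrame(
            columns=["id_a", "id_b", "pearson_r", "n", "test_p", "flagged"]
        )

    wide = pd.DataFrame(series)  # genes x studies, NaN where unmeasured
    p = np.clip(wide.to_numpy(dtype=float), P_FLOOR, 1.0)
    measured = ~np.isnan(wide.to_numpy(dtype=float))
    k = measured.sum(axis=1)
    if (k == 0).any():
        raise ValueError("gene with no measurements")  # unreachable via join
    with np.errstate(invalid="ignore"):
        logs = np.where(measured, np.log(p), 0.0)
    chi2_stat = -2.0 * logs.sum(axis=1)
    df = 2 * k
    combined = np.maximum(stats.chi2.sf(chi2_stat, df), P_FLOOR)

    meta = pd.DataFrame(
        {
            "gene": wide.index,
            "disease_id": disease_id,
            "k": k,
            "chi2_stat": chi2_stat,
            "df": df,
            "combined_p": combined,
        }
    )
    for method in CORRECTIONS:
        meta[f"p_{method}"] = adjust_pvalues(combined, method)
    return meta.reset_index(drop=True), diagnostics


def select_significant(
    meta: pd.DataFrame, correction: str = "by", alpha: float = 0.05
) -> frozenset[str]:
    """Genes whose adjusted p-value under ``correction`` falls below ``alpha``."""
    if correction not in CORRECTIONS:
        raise ValueError(f"unknown correction {correction!r}; expected one of {CORRECTIONS}")
    col = f"p_{correction}"
    return frozenset(meta.loc[meta[col] < alpha, "gene"])
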