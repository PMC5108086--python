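"""Permutation-null priors, minimum Bayes factors, and minimum posterior probabilities.

A pathway that reaches significance could do so by chance; to quantify
that, case/control labels are repeatedly assigned at random to an unlabeled
healthy cohort and the full gene-selection + enrichment procedure is re-run,
giving ``R`` null p-value vectors per pathway.  The per-pathway prior ``q``
is the fraction of null runs in which the pathway came out significant.

Evidence in an observed p-value or chi-square statistic is bounded with
minimum Bayes factors:

* p-value form (Sellke-Bayarri-Berger): ``BF = -e * p * ln(p)`` for
  ``p < 1/e``, else 1;
* chi-square form (Johnson): ``BF = (v/x)^(-v/2) * exp(-(x - v)/2)`` for
  ``x > v``, else 1,

and turned into a lower bound on the posterior probability of the null via
``posterior = odds / (1 + odds)`` with ``odds = BF * q / (1 - q)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .diffexpr import fit_moderated_t, preprocess
from .enrichment import enrich_disease
from .io import CASE, CONTROL, ExpressionStudy, GeneSetCollection

_INV_E = 1.0 / math.e

CALIBRATION_COLUMNS = ["pathway", "scope", "source", "p_or_x", "bf", "q", "min_posterior"]


@dataclass
class NullRunMatrix:
    """``R x P`` matrix of null pathway p-values (rows: runs, columns: pathways)."""

    runs: pd.DataFrame
    alpha_used: float = 0.05

    def __post_init__(self) -> None:
        if len(self.runs) < 2:
            raise ValueError("need at least R = 2 null runs")
        vals = self.runs.to_numpy(dtype=float)
        if (vals <= 0).any() or (vals > 1).any():
            raise ValueError("null p-values must lie in (0, 1]")

    @property
    def n_runs(self) -> int:
        return len(self.runs)


def generate_null_distributions(
    cohort: ExpressionStudy,
    collection: GeneSetCollection,
    R: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
) -> NullRunMatrix:
    """Run ``R`` random-relabeling null analyses on a healthy cohort.

    Each run assigns a balanced random case/control split (``n//2`` cases),
    fits the moderated t, selects genes at the *uncorrected* ``p < alpha``
    (after FDR correction a null cohort retains essentially nothing), and
    scores every pathway by hypergeometric enrichment.  Deterministic under
    ``seed``.
    """
    if cohort.labels is not None:
        raise ValueError("null cohort must be unlabeled")
    if R < 2:
        raise ValueError("need at least R = 2 null runs")
    n = len(cohort.samples)
    n_case = n // 2
    if n_case < 2 or n - n_case < 2:
        raise ValueError("cohort too small to split into groups of >= 2")
    base = preprocess(cohort)
    universe = frozenset(base.genes)
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(R):
        perm = rng.permutation(n)
        labels = np.empty(n, dtype=object)
        labels[perm[:n_case]] = CASE
        labels[perm[n_case:]] = CONTROL
        labeled = ExpressionStudy(
            study_id=base.study_id,
            disease_id=base.disease_id,
            genes=list(base.genes),
            samples=list(base.samples),
            values=base.values,
            labels=labels.tolist(),
        )
        de = fit_moderated_t(labeled)
        sig = frozenset(de.loc[de["p"] < alpha, "gene"])
        enriched = enrich_disease(sig, universe, collection, disease_id="null")
        rows.append(enriched.set_index("pathway")["p"])
    runs = pd.DataFrame(rows).reset_index(drop=True)
    runs.index.name = "run"
    return NullRunMatrix(runs=runs, alpha_used=alpha)


def estimate_priors(null_matrix: NullRunMatrix, alpha: float = 0.05) -> pd.Series:
    """Per-pathway prior ``q``: fraction of null runs significant at ``alpha``.

    Clamped to ``[0.5/R, 1 - 0.5/R]`` so posterior odds stay finite for
    pathways never (or always) significant by chance.
    """
    R = null_matrix.n_runs
    q = (null_matrix.runs < alpha).mean(axis=0)
    return q.clip(lower=0.5 / R, upper=1.0 - 0.5 / R).rename("q")


def average_null(null_matrix: NullRunMatrix, pooled: bool = False):
    """Average null p-value distribution.

    Default: per-pathway arithmetic mean across runs (a Series indexed by
    pathway, consumed by the QQ diagnostics).  ``pooled=True`` instead
    returns the pooled empirical distribution as a sorted flat array.
    """
    if pooled:
        return np.sort(null_matrix.runs.to_numpy(dtype=float).ravel())
    return null_matrix.runs.mean(axis=0).rename("mean_null_p")


def min_bf_p(p):
    """Minimum Bayes factor for a p-value: ``-e*p*ln(p)`` if ``p < 1/e`` else 1."""
    arr = np.asarray(p, dtype=float)
    if (arr <= 0).any() or (arr > 1).any():
        raise ValueError("p must lie in (0, 1]")
    with np.errstate(divide="ignore"):
        bf = np.where(arr < _INV_E, -math.e * arr * np.log(arr), 1.0)
    return float(bf) if np.isscalar(p) or arr.ndim == 0 else bf


def min_bf_chisq(x, v):
    """Johnson's minimum Bayes factor for a chi-square statistic.

    ``BF = (v/x)^(-v/2) * exp(-(x - v)/2)`` for ``x > v``, else 1; evaluated
    in log space.
    """
    x_arr = np.asarray(x, dtype=float)
    v_arr = np.asarray(v, dtype=float)
    if (v_arr <= 0).any():
        raise ValueError("degrees of freedom v must be positive")
    if (x_arr < 0).any():
        raise ValueError("chi-square statistic x must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        log_bf = (v_arr / 2.0) * (np.log(x_arr) - np.log(v_arr)) - (x_arr - v_arr) / 2.0
    bf = np.where(x_arr > v_arr, np.exp(log_bf), 1.0)
    scalar = np.isscalar(x) and np.isscalar(v)
    return float(bf) if scalar else bf


def min_posterior(bf, q):
    """Lower bound on the posterior probability of the null.

    ``odds = bf * q / (1 - q)``; posterior = ``odds / (1 + odds)``.
    """
    bf_arr = np.asarray(bf, dtype=float)
    q_arr = np.asarray(q, dtype=float)
    if (q_arr <= 0).any() or (q_arr >= 1).any():
        raise ValueError("prior q must lie strictly inside (0, 1)")
    if (bf_arr <= 0).any() or (bf_arr > 1).any():
        raise ValueError("minimum Bayes factor must lie in (0, 1]")
    odds = bf_arr * q_arr / (1.0 - q_arr)
    post = odds / (1.0 + odds)
    scalar = np.isscalar(bf) and np.isscalar(q)
    return float(post) if scalar else post


def calibrate_pathways(
    shared: pd.DataFrame,
    disease_ids: list[str],
    priors: Mapping[str, float] | pd.Series,
) -> pd.DataFrame:
    """Minimum BFs and posteriors for each shared pathway.

    ``shared`` is the tier-3 result table (index: pathway; per-disease p
    columns plus ``chi2_stat`` and ``df``).  Per pathway this yields one row
    per disease (p-value Bayes factor) and one ``combined`` row (Johnson's
    chi-square Bayes factor on the combined statistic), each converted to a
    minimum posterior with that pathway's prior ``q``.
    """
    priors = pd.Series(priors, dtype=float)
    missing = [p for p in shared.index if p not in priors.index]
    if missing:
        raise ValueError(f"missing prior for pathway(s) {missing[:5]}")
    rows = []
    for pathway, row in shared.iterrows():
        q = float(priors.loc[pathway])
        for disease in disease_ids:
            p = float(row[disease])
            bf = min_bf_p(p)
            rows.append(
                (pathway, disease, "per-disease p", p, bf, q, min_posterior(bf, q))
            )
        x, v = float(row["chi2_stat"]), float(row["df"])
        bf = min_bf_chisq(x, v)
        rows.append(
            (pathway, "combined", f"combined chi2 ({x:.4g}, {v:g})", x, bf, q,
             min_posterior(bf, q))
        )
    return pd.DataFrame(rows, columns=CALIBRATION_COLUMNS)
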