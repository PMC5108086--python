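"""Per-study preprocessing and empirical-Bayes moderated-t differential expression.

The moderated t shrinks each gene's residual variance toward a prior
variance ``s0^2`` with ``d0`` prior degrees of freedom, both estimated by
moment matching on the log sample variances across genes (the classic
empirical-Bayes construction for small-sample microarray studies):

    s2_post = (d0 * s0^2 + d_g * s2) / (d0 + d_g)
    t_mod   = beta / sqrt(s2_post * (1/n1 + 1/n2))

with ``beta`` the case-minus-control mean difference, ``s2`` the pooled
within-group variance on ``d_g = n1 + n2 - 2`` degrees of freedom, and
two-sided p-values from Student's t with ``d_g + d0`` degrees of freedom
(standard normal in the ``d0 = inf`` limit).  ``d0 = 0`` reduces exactly to
the ordinary pooled two-sample t-test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .io import ExpressionStudy

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300  # keeps downstream log p finite

STAT_COLUMNS = ["gene", "beta", "s2", "d_g", "s2_post", "t_mod", "df_total", "p"]


@dataclass(frozen=True)
class EBayesHyper:
    """Prior degrees of freedom ``d0`` (may be ``inf``) and prior variance ``s0^2``."""

    d0: float
    s0_2: float

    def __post_init__(self) -> None:
        if not (self.d0 >= 0 or math.isinf(self.d0)):
            raise ValueError(f"d0 must be >= 0 or inf, got {self.d0}")
        if not self.s0_2 > 0:
            raise ValueError(f"s0_2 must be positive, got {self.s0_2}")


def preprocess(study: ExpressionStudy, log_threshold: float = 50.0) -> ExpressionStudy:
    """NA removal and log normalization.

    Gene rows containing any missing value are dropped.  If the remaining
    matrix maximum exceeds ``log_threshold`` the data are taken to be raw
    intensities and replaced by ``log2(x + 1)`` (negative values clamped to
    zero first); otherwise they are passed through as already log-scale.
    """
    values = np.asarray(study.values, dtype=float)
    complete = ~np.isnan(values).any(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info(
            "study %s: dropped %d/%d gene rows with missing values",
            study.study_id, n_dropped, len(study.genes),
        )
    values = values[complete]
    genes = [g for g, keep in zip(study.genes, complete) if keep]
    if len(genes) < 2:
        raise ValueError(f"study {study.study_id}: fewer than 2 genes after NA removal")
    if study.labels is not None and (study.n_case < 2 or study.n_control < 2):
        raise ValueError(f"study {study.study_id}: each group needs >= 2 samples")
    if values.max() > log_threshold:
        logger.info("study %s: applying log2(x+1) transform", study.study_id)
        values = np.log2(np.clip(values, 0.0, None) + 1.0)
    return study.with_values(genes, values)


def _trigamma(x):
    return special.polygamma(1, x)


def trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve ``trigamma(x) = y`` for ``x > 0`` by monotone Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma_inverse requires y > 0")
    if y > 1e7:  # trigamma(x) ~ 1/x^2 as x -> 0
        return 1.0 / math.sqrt(y)
    if y < 1e-6:  # trigamma(x) ~ 1/x as x -> inf
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(_trigamma(x))
        step = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += step
        if abs(step) < tol * x:
            break
    return x


def estimate_hyperparams(s2: np.ndarray, d_g: int) -> EBayesHyper:
    """Moment-matching estimate of ``(d0, s0^2)`` from gene-wise variances.

    Working on ``e = ln s2``: under the scaled-inverse-chi-square prior,
    ``var(e) = trigamma(d_g/2) + trigamma(d0/2)``, which is inverted for
    ``d0``; the mean of ``e`` then yields ``ln s0^2``.  When the observed
    ``var(e)`` does not exceed the pure sampling variance ``trigamma(d_g/2)``
    the no-heterogeneity limit ``d0 = inf`` is returned.
    """
    if d_g < 1:
        raise ValueError("d_g must be >= 1")
    s2 = np.asarray(s2, dtype=float)
    if s2.size < 10:
        raise ValueError("need at least 10 genes to estimate hyperparameters")
    if (s2 < 0).any():
        raise ValueError("negative variances")
    if (s2 == 0).any():
        positive = s2[s2 > 0]
        if positive.size == 0:
            raise ValueError("all gene variances are zero")
        s2 = np.where(s2 == 0, positive.min(), s2)
    e = np.log(s2)
    mean_e = float(e.mean())
    var_e = float(e.var(ddof=1))
    sampling = float(_trigamma(d_g / 2.0))
    excess = var_e - sampling
    if excess <= 0:
        s0_2 = math.exp(mean_e - float(special.digamma(d_g / 2.0)) + math.log(d_g / 2.0))
        return EBayesHyper(d0=math.inf, s0_2=s0_2)
    d0 = 2.0 * trigamma_inverse(excess)
    log_s0_2 = (
        mean_e
        - float(special.digamma(d_g / 2.0))
        + math.log(d_g / 2.0)
        + float(special.digamma(d0 / 2.0))
        - math.log(d0 / 2.0)
    )
    return EBayesHyper(d0=d0, s0_2=math.exp(log_s0_2))


def fit_moderated_t(
    study: ExpressionStudy, hyper: EBayesHyper | str = "estimate"
) -> pd.DataFrame:
    """Moderated-t differential expression for a preprocessed two-group study.

    Returns a DataFrame with columns ``gene, beta, s2, d_g, s2_post, t_mod,
    df_total, p`` (one row per gene).  ``hyper="estimate"`` estimates the
    prior from this study's variances; pass an :class:`EBayesHyper` to fix
    it (``d0=0`` gives the ordinary pooled t-test).
    """
    if study.labels is None:
        raise ValueError(f"study {study.study_id} is unlabeled")
    case = study.case_mask
    n1, n2 = study.n_case, study.n_control
    if n1 < 2 or n2 < 2:
        raise ValueError(f"study {study.study_id}: each group needs >= 2 samples")
    values = study.values
    if np.isnan(values).any():
        raise ValueError(f"study {study.study_id}: run preprocess() first (NA present)")
    x1, x2 = values[:, case], values[:, ~case]
    beta = x1.mean(axis=1) - x2.mean(axis=1)
    d_g = n1 + n2 - 2
    ss = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (x2 - x2.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / d_g

    if isinstance(hyper, str):
        if hyper != "estimate":
            raise ValueError(f"unknown hyper mode {hyper!r}")
        hyper = estimate_hyperparams(s2, d_g)

    se2_factor = 1.0 / n1 + 1.0 / n2
    if math.isinf(hyper.d0):
        s2_post = np.full_like(s2, hyper.s0_2)
        df_total = math.inf
    else:
        s2_post = (hyper.d0 * hyper.s0_2 + d_g * s2) / (hyper.d0 + d_g)
        df_total = d_g + hyper.d0
    if (s2_post == 0).any():
        raise ValueError(
            f"study {study.study_id}: zero posterior variance; use variance "
            "moderation (d0 > 0) for genes with no within-group variability"
        )
    t_mod = beta / np.sqrt(s2_post * se2_factor)
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df=df_total)
    p = np.clip(p, P_FLOOR, 1.0)
    return pd.DataFrame(
        {
            "gene": study.genes,
            "beta": beta,
            "s2": s2,
            "d_g": d_g,
            "s2_post": s2_post,
            "t_mod": t_mod,
            "df_total": df_total,
            "p": p,
        }
    )
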