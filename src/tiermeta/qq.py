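"""QQ-plot series for pathway p-value distributions.

Two diagnostics: observed p-values against uniform theoretical quantiles on
the -log10 scale, and per-disease p-values Fisher-combined with the average
permutation-null distribution, plotted against the chi-square(4) background.
Hazen plotting positions ``(i - 0.5) / n`` are used throughout.  Series are
plain tables (rank, expected, observed) so rendering stays decoupled from
the data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class QQSeries:
    label: str
    points: pd.DataFrame  # columns: rank, expected, observed (sorted by expected)
    scale: str  # "neglog10_p" or "chi2_stat"
    inflation: float | None = None  # median observed / median expected


def qq_uniform(p_list, label: str = "") -> QQSeries:
    """Observed sorted ``-log10 p`` against uniform-order-statistic quantiles."""
    p = np.asarray(p_list, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    n = p.size
    ranks = np.arange(1, n + 1)
    # rank i pairs the i-th smallest p with plotting position (i - 0.5)/n
    expected = -np.log10((ranks - 0.5) / n)  # descending
    observed = -np.log10(np.sort(p))  # descending, aligned with expected
    df = pd.DataFrame({"rank": ranks, "expected": expected, "observed": observed})
    df = df.sort_values("expected", ignore_index=True)
    return QQSeries(label=label, points=df, scale="neglog10_p")


def qq_combined_with_null(
    disease_p: pd.Series, null_mean_p: pd.Series, label: str = ""
) -> QQSeries:
    """Fisher-combine disease p's with average-null p's; compare to chi2(4).

    Per pathway the statistic is ``-2 * (ln p_disease + ln p_null_mean)``;
    sorted observed statistics are paired with chi-square(4) quantiles at
    Hazen plotting positions.  ``inflation`` summarizes calibration as
    median observed over median expected.
    """
    if set(disease_p.index) != set(null_mean_p.index):
        raise ValueError("disease and null pathway sets are not aligned")
    null_mean_p = null_mean_p.loc[disease_p.index]
    pd_arr = disease_p.to_numpy(dtype=float)
    pn_arr = null_mean_p.to_numpy(dtype=float)
    for arr, name in [(pd_arr, "disease"), (pn_arr, "null")]:
        if (arr <= 0).any() or (arr > 1).any():
            raise ValueError(f"{name} p-values must lie in (0, 1]")
    stat = -2.0 * (np.log(pd_arr) + np.log(pn_arr))
    n = stat.size
    ranks = np.arange(1, n + 1)
    expected = stats.chi2.ppf((ranks - 0.5) / n, df=4)
    observed = np.sort(stat)
    df = pd.DataFrame({"rank": ranks, "expected": expected, "observed": observed})
    inflation = float(np.median(observed) / np.median(expected))
    return QQSeries(label=label, points=df, scale="chi2_stat", inflation=inflation)
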