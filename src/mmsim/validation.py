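"""Validation of quality metrics against known degradation levels.

When the degradation applied to each image is known (focal offset, number
of averaged raw frames), any metric can be validated by correlating its
scores with an objective quality score: Pearson linear correlation
(PLCC), Kendall rank correlation (KRCC, tau-b to handle the heavy ties of
integer quality scores) and a root mean squared error computed after
mapping the metric onto the degradation scale with a least-squares line
(the two live on incompatible scales otherwise).
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


def assign_defocus_scores(positions: Sequence[int]) -> pd.Series:
    """Quality score for a defocus series: ``3 - |offset|``.

    In-focus images (offset 0) score 3; the positions furthest from the
    optimal focus (offset +-3) score 0.
    """
    scores = {}
    for p in positions:
        if abs(p) > 3:
            raise ValueError(f"focal offset {p} outside the +-3 step range")
        scores[p] = 3 - abs(int(p))
    return pd.Series([scores[p] for p in positions], index=list(positions), dtype=int)


def assign_noise_scores(
    n_averaged: Sequence[int], mode: str = "ordinal"
) -> pd.Series:
    """Quality score for an averaging series.

    ``mode='ordinal'`` ranks the distinct averaging counts 1..L from
    noisiest to cleanest; ``mode='count'`` uses the number of averaged
    raw frames itself (1, 2, 4, 8, 16, 50) as the score.
    """
    n = list(n_averaged)
    if mode == "count":
        return pd.Series(n, dtype=int)
    if mode != "ordinal":
        raise ValueError(f"unknown mode {mode!r}")
    levels = {v: i + 1 for i, v in enumerate(sorted(set(n)))}
    return pd.Series([levels[v] for v in n], dtype=int)


def correlate(
    metric_scores: Mapping[str, float] | pd.Series,
    degradation: Mapping[str, float] | pd.Series,
) -> tuple[float, float, float]:
    """PLCC, KRCC and RMSE between metric scores and degradation scores.

    The two inputs are aligned by id.  KRCC is Kendall tau-b.  RMSE is
    computed on the residuals of the least-squares line mapping metric
    scores onto the degradation scale.  If either side has zero variance
    the correlations are undefined and returned as 0 with a warning.
    """
    m = pd.Series(metric_scores, dtype=float)
    d = pd.Series(degradation, dtype=float)
    if set(m.index) != set(d.index):
        raise ValueError("metric and degradation ids differ")
    d = d.reindex(m.index)
    if len(m) < 3:
        raise ValueError("need at least 3 pairs")
    x = m.to_numpy()
    y = d.to_numpy()
    if x.std() == 0 or y.std() == 0:
        warnings.warn("zero variance: correlation undefined, returning 0")
        plcc = 0.0
        krcc = 0.0
        fitted = np.full_like(y, y.mean())
    else:
        plcc = float(stats.pearsonr(x, y).statistic)
        krcc = float(stats.kendalltau(x, y, variant="b").statistic)
        slope, intercept = np.polyfit(x, y, deg=1)
        fitted = slope * x + intercept
    rmse = float(np.sqrt(np.mean((fitted - y) ** 2)))
    return plcc, krcc, rmse


def correlation_report(
    tables: Mapping[str, Mapping[str, float] | pd.Series],
    degradation: Mapping[str, float] | pd.Series,
) -> pd.DataFrame:
    """Tabulate PLCC/KRCC/RMSE for several metrics at once."""
    rows = {}
    for metric_id, scores in tables.items():
        plcc, krcc, rmse = correlate(scores, degradation)
        rows[metric_id] = {"PLCC": plcc, "KRCC": krcc, "RMSE": rmse}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "metric_id"
    return df
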