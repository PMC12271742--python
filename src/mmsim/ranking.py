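"""Quality rankings and PCA-based marker reduction.

Rankings sort images from the highest to the lowest normalised score,
with the reference pinned at rank 1 with score 1 and ties broken by
image id.  The marker panel can be reduced for a specific evaluation
problem by fitting a PCA to the markers of a quality series of the
*reference* field of view only — so the variability captured comes from
the degradation, not from the imaged objects — and keeping the markers
that contribute most to the principal components, each loading weighted
by its component's explained variance ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

#: Default number of markers kept by the reduction.
DEFAULT_N_SELECT = 4


def rank_images(
    scores: pd.Series | dict[str, float],
    reference_id: str,
    metric_id: str = "",
) -> pd.DataFrame:
    """Rank images by descending normalised score, reference first.

    Returns a table with columns ``rank`` (1-based), ``image_id``,
    ``metric_id`` and ``score``.  The reference is pinned at rank 1 with
    score 1; remaining ties are broken lexicographically by image id.
    """
    s = pd.Series(scores, dtype=float)
    if reference_id not in s.index:
        raise ValueError(f"reference id {reference_id!r} missing from scores")
    rest = s.drop(reference_id)
    order = sorted(rest.index, key=lambda i: (-rest[i], str(i)))
    ids = [reference_id] + list(order)
    vals = [1.0] + [float(rest[i]) for i in order]
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(ids) + 1),
            "image_id": ids,
            "metric_id": metric_id,
            "score": vals,
        }
    )


@dataclass(frozen=True)
class MarkerRelevance:
    """Result of the PCA marker reduction.

    ``relevance`` maps each marker to the sum over components of
    ``|loading| * explained_variance_ratio``; ``selected`` holds the
    top-N marker ids by descending relevance and ``weights`` their
    relevances renormalised to sum 1 (usable as MMSim weights).
    """

    relevance: pd.Series
    selected: list[str]
    weights: pd.Series

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"relevance": self.relevance})
        df["selected"] = df.index.isin(self.selected)
        df["weight"] = self.weights.reindex(df.index).fillna(0.0)
        df.index.name = "marker"
        return df


class PCAMarkerSelector(BaseEstimator):
    """Select the most degradation-sensitive markers via PCA.

    Fit on the marker matrix of one field of view measured at several
    quality levels (a defocus or noise series).  Columns are first put on
    a common scale (zero-variance columns are excluded and get relevance
    0), a full PCA is fitted, and each marker's relevance is the sum over
    all components of the absolute loading scaled by the component's
    explained variance ratio.  The ``n_select`` most relevant markers are
    kept.

    Parameters
    ----------
    n_select
        Number of markers to keep.
    scaling
        Column scaling before the PCA fit.  ``"maxnorm"`` (default)
        divides each marker by its maximum, matching the scaling the
        similarity itself uses: markers that respond strongly to the
        degradation keep a larger variance and dominate the components.
        ``"zscore"`` standardises every column to unit variance — this
        equalises degradation-driven and noise-driven markers and makes
        the selection far less stable, so it is not the default.
        ``"raw"`` uses the columns as they are.

    Attributes
    ----------
    relevance_ : pd.Series
        Non-negative relevance per marker, in input column order.
    selected_ : list[str]
        Top ``n_select`` marker ids by descending relevance.
    weights_ : pd.Series
        Relevances of the selected markers renormalised to sum 1.
    """

    def __init__(self, n_select: int = DEFAULT_N_SELECT, scaling: str = "maxnorm"):
        self.n_select = n_select
        self.scaling = scaling

    def fit(self, X: pd.DataFrame, y=None) -> "PCAMarkerSelector":
        X = pd.DataFrame(X).astype(float)
        if len(X) < 3:
            raise ValueError(
                "marker reduction needs at least 3 quality variants of the FOV"
            )
        if self.n_select > X.shape[1]:
            raise ValueError("n_select exceeds the number of markers")
        if self.scaling not in ("maxnorm", "zscore", "raw"):
            raise ValueError(f"unknown scaling {self.scaling!r}")
        std = X.std(axis=0, ddof=0)
        active = std[std > 0].index
        relevance = pd.Series(0.0, index=X.columns)
        if len(active) > 0:
            Z = X[active]
            if self.scaling == "maxnorm":
                col_max = Z.max(axis=0).replace(0.0, 1.0)
                Z = Z / col_max
            elif self.scaling == "zscore":
                Z = (Z - Z.mean(axis=0)) / std[active]
            pca = PCA()
            pca.fit(Z.to_numpy())
            # relevance_j = sum_c |loading_cj| * evr_c
            rel = np.abs(pca.components_).T @ pca.explained_variance_ratio_
            relevance[active] = rel
        self.relevance_ = relevance
        order = sorted(
            X.columns, key=lambda m: (-relevance[m], list(X.columns).index(m))
        )
        self.selected_ = list(order[: self.n_select])
        sel_rel = relevance[self.selected_]
        total = sel_rel.sum()
        self.weights_ = sel_rel / total if total > 0 else pd.Series(
            1.0 / len(self.selected_), index=self.selected_
        )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Restrict a marker table to the selected markers."""
        if not hasattr(self, "selected_"):
            raise RuntimeError("PCAMarkerSelector is not fitted")
        return pd.DataFrame(X)[self.selected_]

    def result(self) -> MarkerRelevance:
        if not hasattr(self, "selected_"):
            raise RuntimeError("PCAMarkerSelector is not fitted")
        return MarkerRelevance(
            relevance=self.relevance_, selected=self.selected_, weights=self.weights_
        )


def select_markers_pca(
    reference_fov_markers: pd.DataFrame,
    n_select: int = DEFAULT_N_SELECT,
    scaling: str = "maxnorm",
) -> MarkerRelevance:
    """Functional wrapper over :class:`PCAMarkerSelector`."""
    return (
        PCAMarkerSelector(n_select=n_select, scaling=scaling)
        .fit(reference_fov_markers)
        .result()
    )
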