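"""Single- and multi-marker similarity.

The single-marker similarity (SMSim) compares one quality marker between
an image and a reference with a symmetric, bounded expression of the same
family as the SSIM factors::

    SMSim(m1, m2) = (2 m1 m2 + k) / (m1^2 + m2^2 + k)

It equals 1 iff the two marker values coincide and decreases towards 0 as
they diverge.  The multi-marker similarity (MMSim) is the (optionally
weighted) arithmetic mean of the SMSim scores over the marker panel and
inherits the [0, 1] bound.

Marker values are prepared dataset-wide before comparison: outliers are
clamped to the 0.005/0.995 percentiles and each marker column is divided
by its maximum, so that every marker has data range 1 and the single
stabiliser ``k = 0.01`` applies to all.  :class:`MMSimScorer` holds that
dataset state in fitted attributes so late-arriving images are scored
consistently with the batch the reference was normalised in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from mmsim.image import Image
from mmsim.markers import EPSILON, MarkerExtractor

#: SMSim stabiliser for unit-range (max-normalised) markers.
DEFAULT_K = 0.01


@dataclass(frozen=True)
class SimilarityReport:
    """Per-marker SMSim scores and the MMSim aggregate for one image.

    ``mmsim`` equals the weighted mean of ``per_marker`` under
    ``weights`` (non-negative, summing to 1).
    """

    image_id: str
    reference_id: str
    per_marker: pd.Series
    mmsim: float
    weights: pd.Series

    def to_row(self) -> pd.Series:
        row = self.per_marker.copy()
        row["mmsim"] = self.mmsim
        row.name = self.image_id
        return row


def reports_to_frame(reports: Sequence[SimilarityReport]) -> pd.DataFrame:
    """Stack similarity reports into a table (one row per image)."""
    df = pd.DataFrame([r.to_row() for r in reports])
    df.insert(0, "reference_id", [r.reference_id for r in reports])
    df.index.name = "image_id"
    return df


def smsim(m1: float, m2: float, k: float = DEFAULT_K) -> float:
    """Bounded symmetric similarity of two non-negative marker values."""
    if m1 < 0 or m2 < 0:
        raise ValueError("marker values must be non-negative (regularise upstream)")
    if k <= 0:
        raise ValueError("k must be positive")
    return (2.0 * m1 * m2 + k) / (m1 * m1 + m2 * m2 + k)


def _resolve_weights(
    index: pd.Index, weights: Mapping[str, float] | pd.Series | None
) -> pd.Series:
    if weights is None:
        w = pd.Series(1.0, index=index)
    else:
        w = pd.Series(weights, dtype=float).reindex(index)
        if w.isna().any():
            raise ValueError("weights must cover every marker in the vector")
        if (w < 0).any():
            raise ValueError("weights must be non-negative")
        if w.sum() <= 0:
            raise ValueError("weights must not be all zero")
    return w / w.sum()


def mmsim(
    a: pd.Series | Mapping[str, float],
    b: pd.Series | Mapping[str, float],
    weights: Mapping[str, float] | None = None,
    k: float | pd.Series = DEFAULT_K,
    image_id: str = "",
    reference_id: str = "",
) -> SimilarityReport:
    """Aggregate SMSim over a shared marker set into one MMSim score.

    ``a`` and ``b`` must be normalised marker vectors over the same
    marker set.  With the default uniform weights the aggregate is the
    plain arithmetic mean of the per-marker similarities.
    """
    a = pd.Series(a, dtype=float)
    b = pd.Series(b, dtype=float)
    if set(a.index) != set(b.index):
        raise ValueError("marker sets of the two vectors differ")
    b = b.reindex(a.index)
    k_per = pd.Series(k, index=a.index, dtype=float) if np.isscalar(k) else pd.Series(k).reindex(a.index)
    per = pd.Series(
        [smsim(a[m], b[m], float(k_per[m])) for m in a.index], index=a.index
    )
    w = _resolve_weights(a.index, weights)
    score = float((w * per).sum())
    return SimilarityReport(
        image_id=image_id or str(a.name or ""),
        reference_id=reference_id or str(b.name or ""),
        per_marker=per,
        mmsim=score,
        weights=w,
    )


def clamp_outliers(
    mat: pd.DataFrame, low_pct: float = 0.005, high_pct: float = 0.995
) -> pd.DataFrame:
    """Clamp each marker column to its [low_pct, high_pct] quantiles.

    Quantiles use linear interpolation and are computed over all rows,
    reference included.  Intended for large batches where isolated strong
    artifacts would otherwise dominate the max normalisation.
    """
    if len(mat) == 0:
        raise ValueError("marker matrix is empty")
    low = mat.quantile(low_pct, interpolation="linear")
    high = mat.quantile(high_pct, interpolation="linear")
    return mat.clip(lower=low, upper=high, axis=1)


def max_normalize(mat: pd.DataFrame) -> pd.DataFrame:
    """Divide each marker column by its maximum so the data range is 1."""
    col_max = mat.max(axis=0)
    out = mat.copy()
    for col in mat.columns:
        if col_max[col] <= 0:
            warnings.warn(f"marker {col!r} has non-positive maximum; set to epsilon")
            out[col] = EPSILON
        else:
            out[col] = mat[col] / col_max[col]
    return out


class MMSimScorer(BaseEstimator):
    """Dataset-level MMSim scorer with stored normalisation state.

    ``fit`` ingests a marker table (reference row included), computing the
    per-marker clamp bounds and maxima; ``transform`` applies that stored
    state to any marker table; ``score_reports`` emits one
    :class:`SimilarityReport` per image against the reference.  Because
    the state is frozen at fit time, images scored later are normalised
    exactly as the original batch.

    Parameters
    ----------
    clamp
        Whether to clamp outliers before normalising.  Recommended for
        large datasets, redundant for small ones.
    low_pct, high_pct
        Clamping percentiles.
    normalize
        Whether to max-normalise marker columns.  When off, the SMSim
        stabiliser becomes ``k`` times each marker's fitted data range.
    k
        SMSim stabiliser relative to unit data range.
    weights
        Optional per-marker weights (e.g. PCA relevances); ``None`` means
        the unweighted arithmetic mean.

    Attributes
    ----------
    clamp_low_, clamp_high_ : pd.Series
        Fitted clamp bounds per marker (only when ``clamp``).
    max_norm_ : pd.Series
        Fitted per-marker maxima used for normalisation.
    k_ : pd.Series
        Effective per-marker stabiliser.
    feature_names_in_ : np.ndarray
        Marker ids seen at fit.
    """

    def __init__(
        self,
        clamp: bool = True,
        low_pct: float = 0.005,
        high_pct: float = 0.995,
        normalize: bool = True,
        k: float = DEFAULT_K,
        weights: Mapping[str, float] | None = None,
    ):
        self.clamp = clamp
        self.low_pct = low_pct
        self.high_pct = high_pct
        self.normalize = normalize
        self.k = k
        self.weights = weights

    def fit(self, X: pd.DataFrame, y=None) -> "MMSimScorer":
        X = self._validate(X)
        self.feature_names_in_ = np.asarray(X.columns)
        if self.clamp:
            if len(X) < 2:
                raise ValueError("clamping requires at least 2 rows")
            self.clamp_low_ = X.quantile(self.low_pct, interpolation="linear")
            self.clamp_high_ = X.quantile(self.high_pct, interpolation="linear")
            X = X.clip(lower=self.clamp_low_, upper=self.clamp_high_, axis=1)
        self.max_norm_ = X.max(axis=0)
        if self.normalize:
            self.k_ = pd.Series(self.k, index=X.columns)
        else:
            data_range = (X.max(axis=0) - X.min(axis=0)).clip(lower=EPSILON)
            self.k_ = self.k * data_range
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Apply the fitted clamp and max-normalisation state."""
        self._check_fitted()
        X = self._validate(X)[list(self.feature_names_in_)]
        if self.clamp:
            X = X.clip(lower=self.clamp_low_, upper=self.clamp_high_, axis=1)
        if not self.normalize:
            return X
        out = X.copy()
        for col in X.columns:
            m = self.max_norm_[col]
            if m <= 0:
                warnings.warn(f"marker {col!r} has non-positive maximum; set to epsilon")
                out[col] = EPSILON
            else:
                out[col] = X[col] / m
        return out

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X).transform(X)

    def score_reports(
        self, X: pd.DataFrame, reference: str | pd.Series
    ) -> list[SimilarityReport]:
        """Score every row of ``X`` against the reference.

        ``reference`` is either the id of a row of ``X`` (full-reference
        mode) or a raw marker vector already joined into the fit batch
        (reduced-reference mode); in the latter case it is normalised
        with the stored state before comparison.
        """
        self._check_fitted()
        norm = self.transform(X)
        if isinstance(reference, str):
            if reference not in norm.index:
                raise ValueError(f"reference id {reference!r} not in marker table")
            ref_row = norm.loc[reference]
            ref_id = reference
        else:
            ref_id = str(reference.name or "reference")
            ref_df = self.transform(pd.DataFrame([pd.Series(reference, dtype=float)]))
            ref_row = ref_df.iloc[0]
        return [
            mmsim(
                norm.loc[idx],
                ref_row,
                weights=self.weights,
                k=self.k_,
                image_id=str(idx),
                reference_id=ref_id,
            )
            for idx in norm.index
        ]

    def _validate(self, X: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(X).astype(float)
        if X.index.duplicated().any():
            dup = X.index[X.index.duplicated()].tolist()
            raise ValueError(f"duplicate image ids in marker matrix: {dup}")
        if not np.isfinite(X.to_numpy()).all():
            raise ValueError("marker matrix contains non-finite values")
        if (X.to_numpy() < 0).any():
            raise ValueError("marker values must be non-negative")
        return X

    def _check_fitted(self) -> None:
        if not hasattr(self, "max_norm_"):
            raise RuntimeError("MMSimScorer is not fitted")


def score_dataset(
    images: Sequence[Image],
    reference: str | pd.Series | Mapping[str, float],
    marker_set: tuple[str, ...] | None = None,
    clamp: bool = True,
    normalize: bool = True,
    k: float = DEFAULT_K,
    weights: Mapping[str, float] | None = None,
) -> list[SimilarityReport]:
    """Marker extraction, normalisation and MMSim scoring in one call.

    In full-reference mode ``reference`` is the ``image_id`` of one of
    ``images``.  In reduced-reference mode it is a marker vector (e.g.
    computed once from a single reference field of view, or assembled
    from externally known target values such as a theoretical
    resolution); the vector is joined to the marker matrix before
    clamping and normalisation.  Returns one report per image; the
    reference's self-report scores 1 by construction.
    """
    markers = MarkerExtractor(marker_set=marker_set).transform(images)
    if not isinstance(reference, str):
        ref = pd.Series(reference, dtype=float)
        if ref.name is None:
            ref.name = "reference"
        missing = set(markers.columns) - set(ref.index)
        if missing:
            raise ValueError(f"reference vector lacks markers: {sorted(missing)}")
        markers = pd.concat([markers, ref.reindex(markers.columns).to_frame().T])
        reference_key: str | pd.Series = str(ref.name)
    else:
        if reference not in markers.index:
            raise ValueError(f"reference id {reference!r} not found in dataset")
        reference_key = reference
    scorer = MMSimScorer(
        clamp=clamp and len(markers) >= 2,
        normalize=normalize,
        k=k,
        weights=weights,
    )
    scorer.fit(markers)
    return scorer.score_reports(markers, reference_key)
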