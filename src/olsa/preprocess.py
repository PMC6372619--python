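"""Rank transformation and robust z-scoring against control samples.

Raw expression values are converted, per sample, into within-sample gene
ranks (rank 1 = lowest expression, ties averaged).  Each gene's rank in a
treated sample is then expressed as a robust z-score against the control
samples' rank distribution:

    z = (rank - median(control ranks)) / NIQR,

where NIQR is the interquartile range of the control ranks scaled by a
normal-consistency constant (default 0.7413, i.e. IQR/1.349 matches a
normal standard deviation).  The resulting genes x samples matrix of
z-scores is the response-profile matrix the decomposition consumes: the
origin of its column space represents the untreated (control) state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .io import ExpressionMatrix

__all__ = [
    "DEFAULT_NIQR_CONSTANT",
    "ResponseProfile",
    "rank_transform",
    "robust_zscore",
    "RankResponseTransformer",
]

#: IQR -> normal-sd consistency factor (1/1.349).
DEFAULT_NIQR_CONSTANT = 0.7413


@dataclass
class ResponseProfile:
    """A response-profile matrix D: genes x samples differential values.

    ``provenance`` records whether z came from the internal rank/robust-z
    pipeline or was supplied directly by the user (e.g. log fold changes).
    """

    z: pd.DataFrame
    provenance: str = "ranked_robust_z"
    zero_niqr_genes: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.z.shape[1] < 2:
            raise ValueError("a response-profile matrix needs at least 2 samples")
        if not np.isfinite(self.z.to_numpy()).all():
            raise ValueError("response profile contains non-finite values")


def rank_transform(em: ExpressionMatrix | pd.DataFrame) -> pd.DataFrame:
    """Within-sample ranks of all genes (columns), ascending, ties averaged.

    Every column of the result sums to n(n+1)/2 for n genes; the transform
    is invariant under any strictly monotone per-sample transformation of
    the expression values.
    """
    df = em.data if isinstance(em, ExpressionMatrix) else em
    return df.rank(axis=0, method="average", ascending=True)


def robust_zscore(
    ranks: pd.DataFrame,
    control_mask: np.ndarray,
    niqr_constant: float = DEFAULT_NIQR_CONSTANT,
    keep_controls: bool = False,
) -> ResponseProfile:
    """Robust z-score of each gene's rank against the control rank spread.

    Parameters
    ----------
    ranks : pandas.DataFrame
        Genes x samples rank matrix from :func:`rank_transform`.
    control_mask : boolean array, one entry per sample
        ``True`` marks control columns; at least two are required.
    niqr_constant : float
        Factor applied to the control IQR; NIQR = IQR * niqr_constant.
    keep_controls : bool
        If ``True``, control columns are themselves z-scored and retained in
        the output; by default only treated columns are returned.

    Genes whose control IQR is zero cannot be scaled; their z entries are
    set to 0 and their ids collected in ``zero_niqr_genes`` so gene indices
    stay aligned across data sets.
    """
    control_mask = np.asarray(control_mask, dtype=bool)
    if control_mask.shape != (ranks.shape[1],):
        raise ValueError("control_mask length does not match sample count")
    if control_mask.sum() < 2:
        raise ValueError(
            f"robust z-scoring needs >= 2 control samples, got {int(control_mask.sum())}"
        )
    if niqr_constant <= 0:
        raise ValueError("niqr_constant must be positive")

    ctrl = ranks.to_numpy()[:, control_mask]
    med = np.median(ctrl, axis=1)
    q25, q75 = np.percentile(ctrl, [25, 75], axis=1)  # linear interpolation
    iqr = q75 - q25
    zero = iqr == 0
    if zero.all():
        raise ValueError("degenerate controls: every gene has zero control IQR")
    niqr = iqr * niqr_constant

    cols = np.ones_like(control_mask) if keep_controls else ~control_mask
    x = ranks.to_numpy()[:, cols]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (x - med[:, None]) / niqr[:, None]
    z[zero, :] = 0.0
    zdf = pd.DataFrame(z, index=ranks.index, columns=ranks.columns[cols])
    if zdf.shape[1] < 2:
        raise ValueError("fewer than 2 treated samples after excluding controls")
    return ResponseProfile(zdf, "ranked_robust_z", list(ranks.index[zero]))


class RankResponseTransformer(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer: expression -> rank-based robust z response.

    Follows the sklearn samples x features orientation: ``fit`` takes the
    control samples (rows = samples, columns = genes) and learns each
    gene's control rank median and NIQR; ``transform`` converts new samples
    into response profiles.

    Attributes
    ----------
    median_ : ndarray of shape (n_genes,)
        Median control rank per gene.
    niqr_ : ndarray of shape (n_genes,)
        Normalized interquartile range of control ranks per gene.
    zero_niqr_genes_ : ndarray of int
        Column indices whose control NIQR was zero (z forced to 0).
    """

    def __init__(self, niqr_constant: float = DEFAULT_NIQR_CONSTANT):
        self.niqr_constant = niqr_constant

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=2)
        if self.niqr_constant <= 0:
            raise ValueError("niqr_constant must be positive")
        ranks = _row_ranks(X)
        self.median_ = np.median(ranks, axis=0)
        q25, q75 = np.percentile(ranks, [25, 75], axis=0)
        iqr = q75 - q25
        self.zero_niqr_genes_ = np.flatnonzero(iqr == 0)
        if iqr.shape[0] == self.zero_niqr_genes_.shape[0]:
            raise ValueError("degenerate controls: every gene has zero control IQR")
        if self.zero_niqr_genes_.size:
            warnings.warn(
                f"{self.zero_niqr_genes_.size} gene(s) have zero control NIQR; "
                "their z-scores are set to 0",
                stacklevel=2,
            )
        self.niqr_ = iqr * self.niqr_constant
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} genes, transformer was fitted with "
                f"{self.n_features_in_}"
            )
        ranks = _row_ranks(X)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (ranks - self.median_) / self.niqr_
        z[:, self.zero_niqr_genes_] = 0.0
        return z


def _row_ranks(X: np.ndarray) -> np.ndarray:
    """Ascending average ranks of each row's entries (rank 1 = smallest)."""
    return (
        pd.DataFrame(X).rank(axis=1, method="average", ascending=True).to_numpy()
    )
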