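"""Factor signatures, score rankings, and cross-dataset Spearman validation.

A factor's *signature* is the minimal contribution-ordered gene list that
carries a target share (default 90%) of the factor's squared loading mass.
Because response vectors are unit vectors, a gene's contribution is simply
its squared loading.  Signatures are portable: they can be correlated
(Spearman) against samples of an independent response data set to check
whether the factor's gene pattern is conserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .decomposition import ResponseVectors
from .preprocess import ResponseProfile

__all__ = [
    "FactorSignature",
    "top_fraction_genes",
    "extract_signature",
    "rank_by_score",
    "spearman_validate",
]

# float-tie guard on the cumulative-contribution crossing rule: a gene whose
# cumulative contribution lands exactly on the cutoff terminates the list
_CROSS_EPS = 1e-12


@dataclass
class FactorSignature:
    """Ordered weighted gene list representing one factor.

    ``table`` columns: loading, contribution (squared loading / total
    squared mass), cumulative (running contribution sum); rows are genes in
    descending contribution order.
    """

    factor_id: str
    table: pd.DataFrame
    cutoff: float

    @property
    def genes(self) -> list:
        return list(self.table.index)

    @property
    def loadings(self) -> pd.Series:
        return self.table["loading"]

    def __len__(self) -> int:
        return len(self.table)


def _factor_row(rv: ResponseVectors, factor_id: str) -> pd.Series:
    if factor_id not in rv.loadings.index:
        raise KeyError(
            f"unknown factor {factor_id!r}; available: {list(rv.loadings.index)}"
        )
    return rv.loadings.loc[factor_id]


def _contribution_order(row: pd.Series) -> pd.DataFrame:
    sq = row**2
    total = sq.sum()
    if total == 0:
        raise ValueError(f"factor {row.name!r} has all-zero loadings")
    df = pd.DataFrame({"loading": row, "contribution": sq / total})
    # descending contribution, gene id as the deterministic tie-break
    df = df.sort_index().sort_values("contribution", ascending=False, kind="stable")
    df["cumulative"] = df["contribution"].cumsum()
    return df


def top_fraction_genes(
    rv: ResponseVectors, factor_id: str, fraction: float = 0.01
) -> list:
    """Top genes of a factor by squared loading.

    Returns floor(fraction * n_genes) genes (at least 1), sign-blind,
    boundary ties broken by gene id.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    df = _contribution_order(_factor_row(rv, factor_id))
    count = max(1, int(np.floor(fraction * len(df))))
    return list(df.index[:count])


def extract_signature(
    rv: ResponseVectors, factor_id: str, cutoff: float = 0.9
) -> FactorSignature:
    """Genes from the top until cumulative contribution crosses `cutoff`.

    The crossing gene is included — the list must reach the cutoff.
    """
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must be in (0, 1)")
    df = _contribution_order(_factor_row(rv, factor_id))
    crossing = np.flatnonzero(df["cumulative"].to_numpy() >= cutoff - _CROSS_EPS)
    stop = int(crossing[0]) + 1 if crossing.size else len(df)
    return FactorSignature(factor_id, df.iloc[:stop], cutoff)


def rank_by_score(
    scores: pd.DataFrame, factor_id: str, direction: str = "desc"
) -> pd.DataFrame:
    """Samples of one factor ordered by response score.

    Descending order surfaces the samples driving the factor positively;
    ascending surfaces the antagonists (negative-score samples).  Tied
    scores order by sample id.  Returns a DataFrame indexed by sample with
    ``score`` and 1-based ``rank`` columns.
    """
    if factor_id not in scores.index:
        raise KeyError(f"unknown factor {factor_id!r}")
    if direction not in ("desc", "asc"):
        raise ValueError("direction must be 'desc' or 'asc'")
    s = scores.loc[factor_id].sort_index()
    s = s.sort_values(ascending=(direction == "asc"), kind="stable")
    out = s.to_frame("score")
    out["rank"] = np.arange(1, len(out) + 1)
    out.index.name = "sample"
    return out


def spearman_validate(
    sig: FactorSignature, test, min_overlap: int = 3
) -> pd.DataFrame:
    """Spearman rho between a signature and every sample of a test set.

    For each test sample, rho correlates the signature genes' loading
    values with the sample's response values over the gene-id
    intersection.  Rank invariance makes any per-sample monotone scaling
    of the test data irrelevant, so cross-platform sets need no further
    normalization.

    Returns a DataFrame indexed by test sample with ``rho``, 1-based
    ``rank`` (descending rho, ties by sample id), and ``n_genes`` used.
    """
    test_df = test.z if isinstance(test, ResponseProfile) else test
    common = [g for g in sig.genes if g in test_df.index]
    if len(common) < min_overlap:
        raise ValueError(
            f"only {len(common)} signature gene(s) present in the test set "
            f"(need >= {min_overlap})"
        )
    missing = len(sig) - len(common)
    if missing:
        warnings.warn(
            f"{missing}/{len(sig)} signature genes absent from the test set "
            f"(coverage {len(common) / len(sig):.2f})",
            stacklevel=2,
        )
    x = sig.loadings.loc[common].to_numpy()
    sub = test_df.loc[common]
    rho = np.array(
        [stats.spearmanr(x, sub[c].to_numpy()).statistic for c in sub.columns]
    )
    out = pd.DataFrame({"rho": rho}, index=sub.columns).sort_index()
    out = out.sort_values("rho", ascending=False, kind="stable")
    out["rank"] = np.arange(1, len(out) + 1)
    out["n_genes"] = len(common)
    out.index.name = "sample"
    return out
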