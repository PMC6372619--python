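"""The decomposition engine: mirror-anchored uncentred PCA with varimax.

The pipeline factorizes a response-profile matrix D (genes x samples) into

    D  =  T-scaled D',        D' = D with unit-L2-norm columns,
    S  =  R . D',             scores of samples on each factor,

where R (factors x genes, orthonormal rows) is obtained by:

1. total strength: l_i = ||D column i||_2, the per-sample stimulation
   intensity, factored out so only response *direction* is decomposed;
2. mirror selection: samples whose l_i is an extreme upper outlier under an
   iterative one-sided Grubbs test are excluded from the mirror set (their
   responses are considered irreversible);
3. mirror concatenation: DM = [D' | -P'] where P' is the kept normalized
   columns — the point-symmetric mirror pins the centroid of DM to the
   origin, which biologically is the untreated state;
4. uncentred SVD of DM, retaining the smallest leading set of components
   whose cumulative contribution (sigma^2 share) reaches a threshold;
5. varimax rotation of the retained components (raw criterion, pairwise
   Jacobi sweeps), then contribution-ordered renaming P1..Pk and sign
   canonicalization (largest-|loading| element positive).

No step re-centres the data: the mirror construction does the anchoring,
and when no sample is removed the column mean of DM is exactly zero, so
uncentred SVD and mean-centred PCA coincide.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .config import OLSAConfig
from .preprocess import ResponseProfile

__all__ = [
    "MirrorSelection",
    "ComponentSet",
    "ResponseVectors",
    "OLSAResult",
    "total_strength",
    "grubbs_critical_value",
    "select_mirror_samples",
    "normalize_profiles",
    "build_concatenated",
    "extract_components",
    "varimax_criterion",
    "varimax_rotate",
    "compute_scores",
    "run_olsa",
    "OLSA",
]


# ---------------------------------------------------------------------------
# result containers


@dataclass
class MirrorSelection:
    """Audit trail of the Grubbs gate on total-strength values."""

    kept_sample_ids: list
    removed_sample_ids: list
    history: list = field(default_factory=list)  # (sample_id, G, G_crit, n)
    alpha: float = 0.05

    @property
    def n_kept(self) -> int:
        return len(self.kept_sample_ids)


@dataclass
class ComponentSet:
    """Retained principal components of the concatenated matrix DM."""

    loadings: pd.DataFrame  # genes x k, orthonormal columns
    singular_values: np.ndarray  # all nonzero-rank singular values
    contribution_ratio: np.ndarray  # full spectrum, descending
    cumulative_contribution: np.ndarray
    threshold: float

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


@dataclass
class ResponseVectors:
    """Varimax-rotated response-vector matrix R (factors x genes).

    Rows are orthonormal, named P1..Pk in descending order of
    post-rotation contribution, with the largest-|loading| element of each
    row made positive.
    """

    loadings: pd.DataFrame  # factors x genes
    contribution_ratio: np.ndarray  # post-rotation, descending
    rotation: dict = field(default_factory=dict)

    @property
    def factor_ids(self) -> list:
        return list(self.loadings.index)

    @property
    def gene_ids(self) -> list:
        return list(self.loadings.columns)


@dataclass
class OLSAResult:
    """Everything a full run produces, plus the config echo."""

    response_vectors: ResponseVectors
    response_scores: pd.DataFrame  # factors x samples
    total_strength: pd.Series  # per sample
    mirror: MirrorSelection
    components: ComponentSet
    config: OLSAConfig

    def save(self, outdir) -> list:
        """Write the standard TSV artifact set; returns the file list."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rv = self.response_vectors
        files = {}
        files["response_vectors.tsv"] = rv.loadings.rename_axis("factor")
        files["response_scores.tsv"] = self.response_scores.rename_axis("factor")
        files["total_strength.tsv"] = self.total_strength.rename("l2_norm").rename_axis(
            "sample"
        )
        pre = self.components
        k = pre.n_components
        contrib = pd.DataFrame(
            {
                "pre_rotation_ratio": pre.contribution_ratio[:k],
                "pre_rotation_cumulative": pre.cumulative_contribution[:k],
                "post_rotation_ratio": rv.contribution_ratio,
                "post_rotation_cumulative": np.cumsum(rv.contribution_ratio),
            },
            index=pd.Index(rv.factor_ids, name="factor"),
        )
        files["contributions.tsv"] = contrib
        mirror = pd.DataFrame(
            self.mirror.history, columns=["sample", "grubbs_g", "critical_value", "n"]
        )
        mirror["removed"] = mirror["grubbs_g"] > mirror["critical_value"]
        files["mirror_selection.tsv"] = mirror.set_index("sample")
        for name, obj in files.items():
            obj.to_csv(outdir / name, sep="\t")
        import yaml

        meta = dict(self.config.to_dict())
        meta["n_factors"] = k
        meta["n_samples"] = int(self.response_scores.shape[1])
        meta["n_genes"] = int(rv.loadings.shape[1])
        meta["mirror_removed"] = list(map(str, self.mirror.removed_sample_ids))
        (outdir / "run_metadata.yaml").write_text(yaml.safe_dump(meta))
        return sorted([*files, "run_metadata.yaml"])


# ---------------------------------------------------------------------------
# pipeline stages


def _as_frame(d) -> pd.DataFrame:
    return d.z if isinstance(d, ResponseProfile) else d


def total_strength(d) -> pd.Series:
    """Per-sample L2 norm l_i of the response profile (genes x samples)."""
    df = _as_frame(d)
    l = np.sqrt((df.to_numpy() ** 2).sum(axis=0))
    if (l == 0).any():
        zero = list(df.columns[l == 0])
        raise ValueError(f"zero-norm response profile(s): {zero}")
    return pd.Series(l, index=df.columns, name="l2_norm")


def grubbs_critical_value(n: int, alpha: float) -> float:
    """One-sided Grubbs critical value from the Student-t quantile.

    G_crit = ((n-1)/sqrt(n)) * sqrt(t^2 / (n-2+t^2)) with t the upper
    alpha/n quantile of a t distribution with n-2 degrees of freedom.
    """
    if n < 3:
        raise ValueError("Grubbs test needs n >= 3")
    t = stats.t.ppf(1.0 - alpha / n, n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))


def select_mirror_samples(ts: pd.Series, alpha: float = 0.05) -> MirrorSelection:
    """Iterative one-sided (upper) Grubbs gate on total-strength values.

    While the largest norm's statistic G = (max - mean)/sd exceeds the
    critical value at `alpha`, that sample is removed and the test rerun.
    Only extremely *large* norms are at issue: they mark samples whose
    response is too strong to assume reversibility, so they are excluded
    from the mirror set (but stay in D').
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if len(ts) < 4:
        raise ValueError("Grubbs selection needs at least 4 samples")
    values = ts.astype(float).copy()
    removed: list = []
    history: list = []
    while len(values) > 3:
        n = len(values)
        sd = values.std(ddof=1)
        if sd == 0:
            break
        imax = values.idxmax()
        g = (values.loc[imax] - values.mean()) / sd
        crit = grubbs_critical_value(n, alpha)
        history.append((imax, float(g), float(crit), n))
        if g <= crit:
            break
        removed.append(imax)
        values = values.drop(imax)
    if len(values) < 3:
        raise ValueError("fewer than 3 samples survive the Grubbs gate")
    return MirrorSelection(list(values.index), removed, history, alpha)


def normalize_profiles(d, ts: pd.Series | None = None) -> pd.DataFrame:
    """Divide each sample column by its L2 norm (unit response direction)."""
    df = _as_frame(d)
    if ts is None:
        ts = total_strength(df)
    return df / ts.to_numpy()[None, :]


def build_concatenated(dprime: pd.DataFrame, sel: MirrorSelection) -> pd.DataFrame:
    """Concatenate D' with the mirror M = -P' of the kept columns.

    Mirror columns are labelled ``mirror::<sample>``.  With no removals the
    column mean of the result is exactly zero.
    """
    kept = [s for s in sel.kept_sample_ids if s in dprime.columns]
    if len(kept) != len(sel.kept_sample_ids):
        missing = set(sel.kept_sample_ids) - set(dprime.columns)
        raise ValueError(f"kept samples absent from D': {sorted(map(str, missing))}")
    if not kept:
        raise ValueError("empty mirror selection")
    mirror = -dprime[kept]
    mirror.columns = [f"mirror::{c}" for c in kept]
    return pd.concat([dprime, mirror], axis=1)


def extract_components(dm: pd.DataFrame, threshold: float = 0.8) -> ComponentSet:
    """Uncentred SVD of DM; retain components to a cumulative-contribution cut.

    Contribution ratio of component j is sigma_j^2 / sum(sigma^2); the
    smallest k whose cumulative contribution reaches `threshold` is kept
    (ties break toward inclusion).  The data are *not* re-centred: the
    mirror construction anchors the centroid, and re-centring would shift
    the origin whenever Grubbs removed a sample.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    X = dm.to_numpy()
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    nonzero = s > s[0] * 1e-12 if s.size and s[0] > 0 else np.zeros_like(s, bool)
    if not nonzero.any():
        raise ValueError("concatenated matrix is identically zero")
    u, s = u[:, nonzero], s[nonzero]
    var = s**2
    ratio = var / var.sum()
    cum = np.cumsum(ratio)
    hit = np.flatnonzero(cum >= threshold - 1e-12)
    if hit.size:
        k = int(hit[0]) + 1
    else:
        k = len(s)
        warnings.warn(
            f"cumulative contribution saturates at {cum[-1]:.6f} < {threshold}; "
            "retaining all nonzero components",
            stacklevel=2,
        )
    loadings = pd.DataFrame(
        u[:, :k], index=dm.index, columns=[f"C{i + 1}" for i in range(k)]
    )
    return ComponentSet(loadings, s, ratio, cum, threshold)


def varimax_criterion(loadings: np.ndarray) -> float:
    """Raw varimax criterion: sum over factors of n*var of squared loadings.

    V = sum_j [ sum_i L_ij^4 - (sum_i L_ij^2)^2 / n ].  No Kaiser row
    normalization: rows are genes of orthonormal vectors, not scaled
    variables.
    """
    L2 = np.asarray(loadings) ** 2
    n = L2.shape[0]
    return float((L2**2).sum() - (L2.sum(axis=0) ** 2).sum() / n)


def _varimax(L: np.ndarray, tol: float, max_iter: int):
    """Pairwise-Jacobi varimax sweeps; returns (rotated, Q, sweeps, converged)."""
    L = np.array(L, dtype=float)
    n, k = L.shape
    Q = np.eye(k)
    if k < 2:
        return L, Q, 0, True
    crit = varimax_criterion(L)
    converged = False
    sweeps = 0
    for sweeps in range(1, max_iter + 1):
        for p in range(k - 1):
            for q in range(p + 1, k):
                x, y = L[:, p], L[:, q]
                u = x * x - y * y
                v = 2.0 * x * y
                a, b = u.sum(), v.sum()
                c = (u * u - v * v).sum()
                d = 2.0 * (u * v).sum()
                num = d - 2.0 * a * b / n
                den = c - (a * a - b * b) / n
                phi = 0.25 * np.arctan2(num, den)
                if abs(phi) < 1e-14:
                    continue
                g = np.array(
                    [[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]]
                )
                L[:, [p, q]] = L[:, [p, q]] @ g
                Q[:, [p, q]] = Q[:, [p, q]] @ g
        new = varimax_criterion(L)
        if new - crit < tol:
            converged = True
            break
        crit = new
    return L, Q, sweeps, converged


def varimax_rotate(
    cs: ComponentSet, tol: float = 1e-8, max_iter: int = 1000
) -> ResponseVectors:
    """Rotate retained components to simple structure; order and sign-fix.

    Post-rotation contribution of factor j is recomputed from the rotation
    matrix and the singular-value spectrum (row j of R applied to DM has
    squared mass sum_l Q_lj^2 sigma_l^2); factors are renamed P1..Pk in
    descending order of that contribution.
    """
    k = cs.n_components
    if k < 1:
        raise ValueError("no components to rotate")
    rotated, Q, sweeps, converged = _varimax(cs.loadings.to_numpy(), tol, max_iter)
    if not converged:
        warnings.warn(
            f"varimax did not converge in {max_iter} sweeps; using best-so-far",
            stacklevel=2,
        )
    # contribution of each rotated factor, as a share of the full spectrum
    contrib = (Q**2 * cs.contribution_ratio[:k, None]).sum(axis=0)
    order = np.argsort(-contrib)
    rotated = rotated[:, order]
    contrib = contrib[order]
    # sign canon: each factor's largest-|loading| gene loads positively
    signs = np.sign(rotated[np.abs(rotated).argmax(axis=0), np.arange(k)])
    signs[signs == 0] = 1.0
    rotated *= signs
    loadings = pd.DataFrame(
        rotated.T,
        index=[f"P{i + 1}" for i in range(k)],
        columns=cs.loadings.index,
    )
    meta = {
        "sweeps": sweeps,
        "converged": bool(converged),
        "criterion": varimax_criterion(rotated),
        "tol": tol,
        "max_iter": max_iter,
    }
    return ResponseVectors(loadings, contrib, meta)


def compute_scores(rv: ResponseVectors, dprime: pd.DataFrame) -> pd.DataFrame:
    """Response-score matrix S = R . D' (factors x samples).

    Gene order is re-aligned by id; a gene-set mismatch is a hard error
    listing the symmetric difference.
    """
    r_genes = set(rv.gene_ids)
    d_genes = set(dprime.index)
    if r_genes != d_genes:
        diff = sorted(map(str, r_genes.symmetric_difference(d_genes)))
        raise ValueError(f"gene ids differ between R and D': {diff[:20]}")
    aligned = dprime.loc[rv.loadings.columns]
    return rv.loadings @ aligned


def run_olsa(d, config: OLSAConfig | None = None) -> OLSAResult:
    """Run the full decomposition on a response-profile matrix.

    Parameters
    ----------
    d : pandas.DataFrame or ResponseProfile
        Genes x samples response-profile matrix (robust z of ranks, log
        fold change, ...).
    config : OLSAConfig
        Thresholds and tolerances; defaults reproduce the standard setup
        (cumulative contribution 0.8, Grubbs alpha 0.05).
    """
    config = config or OLSAConfig()
    df = _as_frame(d)
    ts = total_strength(df)
    sel = select_mirror_samples(ts, config.grubbs_alpha)
    dprime = normalize_profiles(df, ts)
    dm = build_concatenated(dprime, sel)
    cs = extract_components(dm, config.cum_threshold)
    if cs.n_components > 1:
        rv = varimax_rotate(cs, config.varimax_tol, config.varimax_max_iter)
    else:
        # a single component: rotation is the identity, sign-fixed
        rv = varimax_rotate(cs, config.varimax_tol, 0)
    scores = compute_scores(rv, dprime)
    return OLSAResult(rv, scores, ts, sel, cs, config)


# ---------------------------------------------------------------------------
# sklearn estimator


class OLSA(TransformerMixin, BaseEstimator):
    """Orthogonal linear separation of response profiles (sklearn API).

    Follows the sklearn orientation (rows = samples, columns = genes);
    ``fit`` runs the mirror-anchored uncentred SVD + varimax pipeline and
    ``transform`` projects unit-normalized profiles onto the response
    vectors, returning samples x factors scores.

    Parameters
    ----------
    cum_threshold : float, default 0.8
        Cumulative-contribution cutoff governing how many components are
        retained for rotation.
    grubbs_alpha : float, default 0.05
        Significance level of the iterative one-sided Grubbs gate that
        excludes extreme-norm (irreversible) samples from the mirror set.
    varimax_tol, varimax_max_iter :
        Convergence control of the pairwise-Jacobi varimax sweeps.

    Attributes
    ----------
    components_ : ndarray (n_factors, n_genes)
        Response vectors R, orthonormal rows, contribution-ordered.
    contribution_ratio_ : ndarray (n_factors,)
        Post-rotation contribution share of each factor.
    explained_variance_ratio_ : ndarray
        Full pre-rotation contribution spectrum of DM.
    total_strength_ : ndarray (n_samples,)
        L2 norm of each training profile.
    mirror_kept_idx_, mirror_removed_idx_ : ndarray of int
        Sample indices kept in / removed from the mirror set.

    Examples
    --------
    >>> import numpy as np
    >>> from olsa import OLSA
    >>> rng = np.random.default_rng(0)
    >>> X = rng.normal(size=(40, 300))          # samples x genes
    >>> scores = OLSA(cum_threshold=0.5).fit_transform(X)
    >>> scores.shape[0]
    40
    """

    def __init__(
        self,
        cum_threshold: float = 0.8,
        grubbs_alpha: float = 0.05,
        varimax_tol: float = 1e-8,
        varimax_max_iter: int = 1000,
    ):
        self.cum_threshold = cum_threshold
        self.grubbs_alpha = grubbs_alpha
        self.varimax_tol = varimax_tol
        self.varimax_max_iter = varimax_max_iter

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=4, ensure_min_features=2)
        d = pd.DataFrame(X.T)  # genes x samples
        config = OLSAConfig(
            cum_threshold=self.cum_threshold,
            grubbs_alpha=self.grubbs_alpha,
            varimax_tol=self.varimax_tol,
            varimax_max_iter=self.varimax_max_iter,
        )
        result = run_olsa(d, config)
        self.result_ = result
        self.components_ = result.response_vectors.loadings.to_numpy()
        self.contribution_ratio_ = result.response_vectors.contribution_ratio
        self.explained_variance_ratio_ = result.components.contribution_ratio
        self.singular_values_ = result.components.singular_values
        self.total_strength_ = result.total_strength.to_numpy()
        self.mirror_kept_idx_ = np.asarray(result.mirror.kept_sample_ids, dtype=int)
        self.mirror_removed_idx_ = np.asarray(
            result.mirror.removed_sample_ids, dtype=int
        )
        self.n_components_ = self.components_.shape[0]
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        """Project samples onto the response vectors.

        Each row is L2-normalized first, so the output is the response
        score of the sample's *direction*; multiply by the row norm to
        recover scores on the raw profile.
        """
        check_is_fitted(self)
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} genes, expected {self.n_features_in_}"
            )
        norms = np.linalg.norm(X, axis=1)
        if (norms == 0).any():
            raise ValueError("zero-norm sample(s) cannot be projected")
        return (X / norms[:, None]) @ self.components_.T
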