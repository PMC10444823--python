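"""Partial least squares path modelling (PLS-PM / PLS-SEM estimation).

Implements the classical iterative outer/inner estimation scheme for
composite latent-variable path models:

1.  initialise outer weights (all +1 within each block);
2.  outer step — each construct's score is its indicator block times the
    outer weights, scaled to unit variance;
3.  inner step — each construct gets a proxy, a weighted sum of adjacent
    construct scores.  Under the default *path* weighting scheme the
    weights toward predecessors are multiple-regression coefficients and
    toward successors plain correlations; *centroid* uses correlation
    signs and *factorial* the correlations themselves;
4.  outer update — Mode A (reflective) weights are the covariances of the
    indicators with the inner proxy, Mode B (formative) weights the
    coefficients of a regression of the proxy on the block;
5.  iterate to a fixed point, then read off loadings (indicator–score
    correlations), structural path coefficients (OLS of each endogenous
    score on its predecessors' scores) and R².

Composite scores are sign-indeterminate; after convergence each construct
is oriented so the sum of its loadings is positive, with weights and path
coefficients updated consistently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .model_spec import ModelSpec, exogenous_and_endogenous, subhealth_model

__all__ = [
    "PLSPathModel",
    "estimate",
    "standardize",
    "DegenerateInputError",
    "CollinearityError",
    "ConvergenceWarning",
]

SCHEMES = ("path", "centroid", "factorial")


class DegenerateInputError(ValueError):
    """A column is constant (zero variance) and cannot be standardized."""


class CollinearityError(ValueError):
    """A Mode-B (formative) block or predecessor set is singular."""


class ConvergenceWarning(UserWarning):
    pass


def standardize(data: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Return ``data`` with each column scaled to mean 0, variance 1 (``ddof``)."""
    sd = data.std(ddof=ddof)
    bad = sd.index[(sd == 0) | sd.isna()].tolist()
    if bad:
        raise DegenerateInputError(f"constant column(s): {bad}")
    return (data - data.mean()) / sd


@dataclass
class _Compiled:
    """Model spec resolved against a column layout, for the array core."""

    names: list[str]
    blocks: list[np.ndarray]          # indicator column indices per construct
    mode_b: list[bool]
    preds: list[np.ndarray]           # predecessor construct indices
    succs: list[np.ndarray]
    paths: list[tuple[int, int]]      # (source idx, target idx), spec order
    columns: list[str]


def _compile(spec: ModelSpec, columns: list[str]) -> _Compiled:
    col_ix = {c: i for i, c in enumerate(columns)}
    missing = [x for x in spec.indicator_names if x not in col_ix]
    if missing:
        raise KeyError(f"indicator column(s) missing from data: {missing}")
    names = spec.construct_names
    con_ix = {n: j for j, n in enumerate(names)}
    blocks = [np.array([col_ix[x] for x in spec.construct(n).indicators]) for n in names]
    mode_b = [spec.construct(n).mode == "formative" for n in names]
    preds = [np.array([con_ix[p] for p in spec.predecessors(n)], dtype=int) for n in names]
    succs = [np.array([con_ix[s] for s in spec.successors(n)], dtype=int) for n in names]
    paths = [(con_ix[s], con_ix[t]) for s, t in spec.paths]
    return _Compiled(names, blocks, mode_b, preds, succs, paths, list(columns))


def _fit_core(
    X: np.ndarray,
    comp: _Compiled,
    scheme: str,
    tol: float,
    max_iter: int,
):
    """Iterative PLS-PM on a standardized array.

    Returns (weights, Y, loadings, betas, r2, iterations, converged) where
    weights/loadings are lists of per-block arrays and betas a list of
    per-endogenous-construct coefficient arrays (aligned with ``preds``).
    """
    n, _ = X.shape
    J = len(comp.names)
    denom = n - 1
    Xb = [X[:, ix] for ix in comp.blocks]
    adj = [np.union1d(comp.preds[j], comp.succs[j]).astype(int) for j in range(J)]

    w = []
    for j in range(J):
        w0 = np.ones(len(comp.blocks[j]))
        y = Xb[j] @ w0
        w.append(w0 / y.std(ddof=1))
    Y = np.column_stack([Xb[j] @ w[j] for j in range(J)])

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        C = (Y.T @ Y) / denom  # correlation matrix of unit-variance scores
        # inner proxies
        E = np.zeros((J, J))
        for j in range(J):
            if scheme == "path":
                P, S = comp.preds[j], comp.succs[j]
                if len(P):
                    try:
                        E[P, j] = np.linalg.solve(C[np.ix_(P, P)], C[P, j])
                    except np.linalg.LinAlgError as exc:
                        raise CollinearityError(
                            f"singular predecessor scores for {comp.names[j]!r}"
                        ) from exc
                if len(S):
                    E[S, j] = C[S, j]
            elif scheme == "centroid":
                E[adj[j], j] = np.sign(C[adj[j], j])
            else:  # factorial
                E[adj[j], j] = C[adj[j], j]
        Z = Y @ E
        # outer update
        w_new = []
        delta = 0.0
        for j in range(J):
            if len(adj[j]) == 0:
                w_new.append(w[j])  # isolated construct: keep initial composite
                continue
            if comp.mode_b[j]:
                Sjj = (Xb[j].T @ Xb[j]) / denom
                cov = (Xb[j].T @ Z[:, j]) / denom
                try:
                    wt = np.linalg.solve(Sjj, cov)
                except np.linalg.LinAlgError as exc:
                    raise CollinearityError(
                        f"singular formative block {comp.names[j]!r}"
                    ) from exc
            else:
                wt = (Xb[j].T @ Z[:, j]) / denom
            y = Xb[j] @ wt
            sd = y.std(ddof=1)
            if sd == 0:
                raise CollinearityError(
                    f"degenerate composite for construct {comp.names[j]!r}"
                )
            wt = wt / sd
            delta = max(delta, float(np.max(np.abs(wt - w[j]))))
            w_new.append(wt)
        w = w_new
        Y = np.column_stack([Xb[j] @ w[j] for j in range(J)])
        if delta < tol:
            converged = True
            break

    loadings = [(Xb[j].T @ Y[:, j]) / denom for j in range(J)]
    C = (Y.T @ Y) / denom
    betas, r2 = [], {}
    for j in range(J):
        P = comp.preds[j]
        if len(P) == 0:
            betas.append(np.empty(0))
            continue
        try:
            b = np.linalg.solve(C[np.ix_(P, P)], C[P, j])
        except np.linalg.LinAlgError as exc:
            raise CollinearityError(
                f"singular predecessor scores for {comp.names[j]!r}"
            ) from exc
        betas.append(b)
        r2[j] = float(b @ C[P, j])
    return w, Y, loadings, betas, r2, it, converged


def _orient(comp: _Compiled, w, Y, loadings, betas):
    """Flip each construct so the sum of its loadings is positive."""
    flip = np.array([-1.0 if lam.sum() < 0 else 1.0 for lam in loadings])
    for j, f in enumerate(flip):
        if f < 0:
            w[j] = -w[j]
            Y[:, j] = -Y[:, j]
            loadings[j] = -loadings[j]
    for j in range(len(comp.names)):
        if len(comp.preds[j]):
            betas[j] = betas[j] * flip[comp.preds[j]] * flip[j]
    return w, Y, loadings, betas, flip


class PLSPathModel(BaseEstimator, TransformerMixin):
    """PLS path-model estimator with a scikit-learn interface.

    Parameters
    ----------
    model : ModelSpec, optional
        Constructs, measurement modes and structural paths.  Defaults to
        the packaged five-construct subhealth model.
    scheme : {"path", "centroid", "factorial"}, default "path"
        Inner weighting scheme.
    tol : float, default 1e-7
        Convergence tolerance on the maximum absolute outer-weight change.
    max_iter : int, default 300
        Iteration cap; non-convergence sets ``converged_ = False`` and
        emits a :class:`ConvergenceWarning`.
    scale : bool, default True
        Standardize columns (mean 0, unit variance, n−1 denominator)
        before estimation.  Estimation requires standardized data; set
        False only if the input is already standardized.

    Attributes
    ----------
    model_ : ModelSpec
    outer_weights_ : pandas.Series, indexed by indicator
    loadings_ : pandas.Series, indexed by indicator
    lv_scores_ : pandas.DataFrame, n × constructs, mean 0 / unit variance
    path_coefficients_ : pandas.Series, indexed "source -> target"
    r_squared_ : pandas.Series per endogenous construct
    iterations_ : int
    converged_ : bool

    Examples
    --------
    >>> from subhealth.simulate import default_population, sample_cohort
    >>> cohort = sample_cohort(default_population(), n=500, seed=7)
    >>> pls = PLSPathModel().fit(cohort.indicators)
    >>> pls.path_coefficients_.round(2)  # doctest: +SKIP
    """

    def __init__(self, model: ModelSpec | None = None, scheme: str = "path",
                 tol: float = 1e-7, max_iter: int = 300, scale: bool = True):
        self.model = model
        self.scheme = scheme
        self.tol = tol
        self.max_iter = max_iter
        self.scale = scale

    # ------------------------------------------------------------------
    def fit(self, X: pd.DataFrame, y=None) -> "PLSPathModel":
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}")
        spec = self.model if self.model is not None else subhealth_model()
        cols = spec.indicator_names
        data = X[cols] if isinstance(X, pd.DataFrame) else pd.DataFrame(X, columns=cols)
        if data.isna().any().any():
            raise ValueError("missing values present; impute before estimation")
        if len(data) <= max(len(c.indicators) for c in spec.constructs):
            raise ValueError("more indicators in a block than subjects")

        self.center_ = data.mean()
        sd = data.std(ddof=1)
        if self.scale:
            bad = sd.index[(sd == 0) | sd.isna()].tolist()
            if bad:
                raise DegenerateInputError(f"constant column(s): {bad}")
            self.scale_ = sd
            Xs = ((data - self.center_) / sd).to_numpy(float)
        else:
            self.scale_ = pd.Series(1.0, index=cols)
            Xs = (data - self.center_).to_numpy(float)

        comp = _compile(spec, cols)
        w, Y, lam, betas, r2, it, conv = _fit_core(
            Xs, comp, self.scheme, self.tol, self.max_iter
        )
        w, Y, lam, betas, _ = _orient(comp, w, Y, lam, betas)
        if not conv:
            warnings.warn(
                f"PLS estimation did not converge in {self.max_iter} iterations",
                ConvergenceWarning,
            )

        self.model_ = spec
        self._compiled_ = comp
        self.outer_weights_ = pd.Series(np.concatenate(w), index=cols, name="outer_weight")
        self.loadings_ = pd.Series(np.concatenate(lam), index=cols, name="loading")
        index = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(len(data))
        self.lv_scores_ = pd.DataFrame(Y, columns=spec.construct_names, index=index)
        names = spec.construct_names
        self.path_coefficients_ = pd.Series(
            {
                f"{s} -> {t}": betas[names.index(t)][list(comp.preds[names.index(t)]).index(names.index(s))]
                for s, t in spec.paths
            },
            name="coefficient",
        ).reindex([f"{s} -> {t}" for s, t in spec.paths])
        _, endo = exogenous_and_endogenous(spec)
        self.r_squared_ = pd.Series(
            {n: r2[names.index(n)] for n in endo}, name="r_squared"
        )
        self.iterations_ = it
        self.converged_ = conv
        return self

    # ------------------------------------------------------------------
    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Composite scores for new subjects, using the fitted weights."""
        if not hasattr(self, "outer_weights_"):
            raise AttributeError("PLSPathModel is not fitted")
        cols = self.model_.indicator_names
        Xs = ((X[cols] - self.center_) / self.scale_).to_numpy(float)
        Y = np.column_stack(
            [Xs[:, ix] @ self.outer_weights_.to_numpy()[ix] for ix in self._compiled_.blocks]
        )
        return pd.DataFrame(Y, columns=self.model_.construct_names, index=X.index)

    def block_loadings(self, construct: str) -> pd.Series:
        return self.loadings_[list(self.model_.construct(construct).indicators)]


def estimate(
    data: pd.DataFrame,
    spec: ModelSpec | None = None,
    scheme: str = "path",
    tol: float = 1e-7,
    max_iter: int = 300,
) -> PLSPathModel:
    """Fit a :class:`PLSPathModel`; thin functional wrapper."""
    return PLSPathModel(model=spec, scheme=scheme, tol=tol, max_iter=max_iter).fit(data)
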