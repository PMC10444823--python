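"""Bootstrap significance testing of structural path coefficients.

Subjects are resampled with replacement B times; the PLS engine is re-run
on each resample after per-resample standardization.  Composite scores are
sign-indeterminate, so each resample's constructs are re-oriented to agree
with the original solution (construct-level flip maximising loading
agreement) before the path coefficients are aggregated — otherwise the
bootstrap SD is inflated artificially.  For each path, t = |β| / sd(β*)
and the two-sided p value comes from the Student t distribution with B−1
degrees of freedom; a path is Supported iff p < α (strict).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model_spec import ModelSpec, subhealth_model
from .pls import _compile, _fit_core, _orient

__all__ = ["BootstrapResult", "bootstrap_paths", "t_statistic", "decide"]


def t_statistic(beta: float, boot_sd: float) -> float:
    """Bootstrap t ratio |β| / sd(β*)."""
    return abs(beta) / boot_sd


def decide(p: float, alpha: float = 0.05) -> str:
    """"Supported" iff p < alpha (strict inequality at the boundary)."""
    return "Supported" if p < alpha else "Rejected"


@dataclass
class BootstrapResult:
    """Per-path bootstrap inference, Table-4-shaped via :meth:`to_frame`."""

    original: pd.Series
    boot_mean: pd.Series
    boot_sd: pd.Series
    t: pd.Series
    p: pd.Series
    decision: pd.Series
    n_boot: int
    seed: int
    alpha: float
    n_discarded: int
    samples: np.ndarray  # B × paths, aligned resample coefficients

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coefficient": self.original,
                "boot_mean": self.boot_mean,
                "boot_sd": self.boot_sd,
                "t": self.t,
                "p": self.p,
                "decision": self.decision,
            }
        ).rename_axis("path")


def bootstrap_paths(
    data: pd.DataFrame,
    spec: ModelSpec | None = None,
    n_boot: int = 5000,
    seed: int = 0,
    alpha: float = 0.05,
    scheme: str = "path",
    tol: float = 1e-7,
    max_iter: int = 300,
) -> BootstrapResult:
    """Bootstrap the structural coefficients of a PLS path model.

    A resample that leaves some indicator constant is discarded and
    redrawn (the count is reported in ``n_discarded``).
    """
    spec = spec if spec is not None else subhealth_model()
    cols = spec.indicator_names
    X = data[cols].to_numpy(float)
    n = X.shape[0]
    comp = _compile(spec, cols)

    def run(mat: np.ndarray):
        sd = mat.std(axis=0, ddof=1)
        if np.any(sd == 0):
            return None
        Z = (mat - mat.mean(axis=0)) / sd
        w, Y, lam, betas, r2, it, conv = _fit_core(Z, comp, scheme, tol, max_iter)
        return _orient(comp, w, Y, lam, betas)

    base = run(X)
    if base is None:
        raise ValueError("constant indicator column in the input data")
    _, _, lam0, betas0, _ = base
    path_names = [f"{s} -> {t}" for s, t in spec.paths]

    def path_vector(betas) -> np.ndarray:
        out = np.empty(len(comp.paths))
        for k, (s, t) in enumerate(comp.paths):
            out[k] = betas[t][list(comp.preds[t]).index(s)]
        return out

    beta0 = path_vector(betas0)

    rng = np.random.default_rng(seed)
    samples = np.empty((n_boot, len(comp.paths)))
    discarded = 0
    b = 0
    while b < n_boot:
        idx = rng.integers(0, n, size=n)
        mat = X[idx]
        sd = mat.std(axis=0, ddof=1)
        if np.any(sd == 0):
            discarded += 1
            continue
        Z = (mat - mat.mean(axis=0)) / sd
        w, Y, lam, betas, _, _, _ = _fit_core(Z, comp, scheme, tol, max_iter)
        # construct-level sign alignment against the original loadings
        flip = np.array(
            [-1.0 if float(lam[j] @ lam0[j]) < 0 else 1.0 for j in range(len(comp.names))]
        )
        for j in range(len(comp.names)):
            if len(comp.preds[j]):
                betas[j] = betas[j] * flip[comp.preds[j]] * flip[j]
        samples[b] = path_vector(betas)
        b += 1

    boot_mean = samples.mean(axis=0)
    boot_sd = samples.std(axis=0, ddof=1)
    tval = np.abs(beta0) / boot_sd
    pval = 2 * stats.t.sf(tval, df=n_boot - 1)
    decisions = ["Supported" if p < alpha else "Rejected" for p in pval]
    mk = lambda v, name: pd.Series(v, index=path_names, name=name)
    return BootstrapResult(
        original=mk(beta0, "coefficient"),
        boot_mean=mk(boot_mean, "boot_mean"),
        boot_sd=mk(boot_sd, "boot_sd"),
        t=mk(tval, "t"),
        p=mk(pval, "p"),
        decision=mk(decisions, "decision"),
        n_boot=n_boot,
        seed=seed,
        alpha=alpha,
        n_discarded=discarded,
        samples=samples,
    )
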