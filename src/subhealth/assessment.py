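"""Reliability and validity battery for a fitted PLS path model.

Reflective blocks: Cronbach's alpha (standardized-item form), average
variance extracted (AVE), composite reliability (CR).  Formative blocks:
outer weights and variance inflation factors (VIF).  Discriminant
validity: heterotrait–monotrait ratio (HTMT) and latent-variable score
correlations.  Printed decision rules: alpha ≥ 0.70, outer weight > 0.20,
AVE ≥ 0.50, CR ≥ 0.70, VIF < 5, HTMT < 0.85, |correlation| < 0.70.

Metrics that are undefined for a block (alpha/AVE/CR of a formative or
single-indicator block, HTMT against a one-indicator block) are reported
as NaN, rendered "–" in the CSV output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pls import PLSPathModel

__all__ = [
    "cronbach_alpha",
    "composite_reliability",
    "ave",
    "outer_vif",
    "htmt",
    "lv_correlation_matrix",
    "assess",
    "apply_thresholds",
    "AssessmentReport",
]

THRESHOLDS = {
    "alpha": 0.70,          # >=
    "outer_weight": 0.20,   # >
    "ave": 0.50,            # >=
    "cr": 0.70,             # >=
    "vif": 5.0,             # <
    "htmt": 0.85,           # <
    "lv_correlation": 0.70, # |r| <
}


def cronbach_alpha(block: pd.DataFrame, standardized: bool = True) -> float:
    """Cronbach's alpha of an indicator block; NaN for a single indicator.

    The default standardized-item form is ``K·r̄ / (1 + (K−1)·r̄)`` with
    ``r̄`` the mean pairwise correlation; ``standardized=False`` gives the
    covariance (raw-score) form.
    """
    K = block.shape[1]
    if K < 2:
        return math.nan
    if standardized:
        R = np.corrcoef(block.to_numpy(float), rowvar=False)
        rbar = (R.sum() - K) / (K * (K - 1))
        return float(K * rbar / (1 + (K - 1) * rbar))
    var_items = block.var(ddof=1).sum()
    var_total = block.sum(axis=1).var(ddof=1)
    return float(K / (K - 1) * (1 - var_items / var_total))


def composite_reliability(loadings) -> float:
    """Composite reliability ρ_c = (Σλ)² / ((Σλ)² + Σ(1 − λ²))."""
    lam = np.asarray(loadings, float)
    if lam.size == 0:
        raise ValueError("empty loading vector")
    s2 = lam.sum() ** 2
    return float(s2 / (s2 + (1 - lam**2).sum()))


def ave(loadings) -> float:
    """Average variance extracted: mean squared loading."""
    lam = np.asarray(loadings, float)
    if lam.size == 0:
        raise ValueError("empty loading vector")
    return float((lam**2).mean())


def outer_vif(block: pd.DataFrame) -> pd.Series:
    """Per-indicator VIF = 1/(1 − R²) against the rest of the block.

    Equal for any two-indicator block.  A perfectly collinear block yields
    an infinite-VIF marker for every indicator.
    """
    if block.shape[1] < 2:
        raise ValueError("VIF needs at least two indicators")
    R = np.corrcoef(block.to_numpy(float), rowvar=False)
    try:
        inv = np.linalg.inv(R)
        vif = np.diag(inv)
        if np.any(vif < 0) or not np.all(np.isfinite(vif)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        vif = np.full(block.shape[1], np.inf)
    return pd.Series(vif, index=block.columns, name="vif")


def htmt(data: pd.DataFrame, block_a: list[str], block_b: list[str]) -> float:
    """Heterotrait–monotrait ratio of two indicator blocks.

    Mean absolute between-block correlation over the geometric mean of the
    two mean absolute within-block (off-diagonal) correlations.  Uses
    absolute correlations throughout; NaN if either block has a single
    indicator.
    """
    if len(block_a) < 2 or len(block_b) < 2:
        return math.nan
    R = np.abs(np.corrcoef(data[list(block_a) + list(block_b)].to_numpy(float), rowvar=False))
    ka = len(block_a)
    hetero = R[:ka, ka:].mean()

    def mono(sub: np.ndarray) -> float:
        k = sub.shape[0]
        return (sub.sum() - k) / (k * (k - 1))

    return float(hetero / math.sqrt(mono(R[:ka, :ka]) * mono(R[ka:, ka:])))


def lv_correlation_matrix(pls: PLSPathModel) -> pd.DataFrame:
    """Pearson correlations of the latent-variable scores; exact unit diagonal."""
    scores = pls.lv_scores_
    C = np.corrcoef(scores.to_numpy(float), rowvar=False)
    np.fill_diagonal(C, 1.0)
    return pd.DataFrame(C, index=scores.columns, columns=scores.columns)


@dataclass
class AssessmentReport:
    """Reliability/validity tables for one fitted model.

    ``constructs``: per-construct mode, alpha, AVE, CR.
    ``indicators``: per-indicator loading, outer weight, VIF (formative).
    ``discriminant``: HTMT below the diagonal, LV correlations above,
    exactly the layout of a combined discriminant-validity table.
    """

    constructs: pd.DataFrame
    indicators: pd.DataFrame
    discriminant: pd.DataFrame
    htmt_matrix: pd.DataFrame
    lv_correlations: pd.DataFrame

    def to_csv(self, path_prefix: str) -> None:
        self.constructs.to_csv(f"{path_prefix}_constructs.csv", na_rep="–")
        self.indicators.to_csv(f"{path_prefix}_indicators.csv", na_rep="–")
        self.discriminant.to_csv(f"{path_prefix}_discriminant.csv", na_rep="–")


def assess(pls: PLSPathModel, data: pd.DataFrame) -> AssessmentReport:
    """Compute the full battery from a fitted model and the training data."""
    spec = pls.model_
    cols = spec.indicator_names
    std = (data[cols] - data[cols].mean()) / data[cols].std(ddof=1)

    crows, irows = [], []
    for con in spec.constructs:
        block = std[list(con.indicators)]
        lam = pls.block_loadings(con.name).to_numpy()
        reflective = con.mode == "reflective"
        crows.append(
            {
                "construct": con.name,
                "mode": con.mode,
                "cronbach_alpha": cronbach_alpha(block) if reflective else math.nan,
                "ave": ave(lam) if reflective else math.nan,
                "cr": composite_reliability(lam) if reflective else math.nan,
            }
        )
        vifs = outer_vif(block) if (not reflective and len(con.indicators) >= 2) else None
        for x in con.indicators:
            irows.append(
                {
                    "indicator": x,
                    "construct": con.name,
                    "loading": pls.loadings_[x],
                    "outer_weight": pls.outer_weights_[x],
                    "vif": float(vifs[x]) if vifs is not None else math.nan,
                }
            )
    constructs = pd.DataFrame(crows).set_index("construct")
    indicators = pd.DataFrame(irows).set_index("indicator")

    names = spec.construct_names
    H = pd.DataFrame(np.nan, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            h = htmt(std, list(spec.construct(a).indicators), list(spec.construct(b).indicators))
            H.loc[a, b] = H.loc[b, a] = h
    C = lv_correlation_matrix(pls)
    combined = pd.DataFrame(np.nan, index=names, columns=names)
    for i, a in enumerate(names):
        combined.loc[a, a] = 1.0
        for b in names[i + 1 :]:
            combined.loc[a, b] = C.loc[a, b]  # correlations above the diagonal
            combined.loc[b, a] = H.loc[b, a]  # HTMT below
    return AssessmentReport(constructs, indicators, combined, H, C)


def apply_thresholds(report: AssessmentReport) -> dict[str, pd.DataFrame]:
    """Pass/fail flags per printed rule; NaN metrics yield NA flags."""
    con = report.constructs
    cflags = pd.DataFrame(index=con.index)
    for flag, col, cut in (
        ("alpha_ok", "cronbach_alpha", THRESHOLDS["alpha"]),
        ("ave_ok", "ave", THRESHOLDS["ave"]),
        ("cr_ok", "cr", THRESHOLDS["cr"]),
    ):
        cflags[flag] = (con[col] >= cut).astype("boolean").mask(con[col].isna())

    ind = report.indicators
    iflags = pd.DataFrame(index=ind.index)
    iflags["weight_ok"] = ind["outer_weight"] > THRESHOLDS["outer_weight"]
    iflags["vif_ok"] = (ind["vif"] < THRESHOLDS["vif"]).astype("boolean").mask(ind["vif"].isna())

    pairs = []
    names = list(report.htmt_matrix.index)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            h = report.htmt_matrix.loc[a, b]
            r = report.lv_correlations.loc[a, b]
            pairs.append(
                {
                    "pair": f"{a} / {b}",
                    "htmt_ok": (h < THRESHOLDS["htmt"]) if not math.isnan(h) else pd.NA,
                    "correlation_ok": abs(r) < THRESHOLDS["lv_correlation"],
                }
            )
    return {
        "constructs": cflags,
        "indicators": iflags,
        "pairs": pd.DataFrame(pairs).set_index("pair"),
    }
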