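"""Synthetic cohorts with a known latent-composite structure.

The generator draws subject-level indicator data from a *composite*
population: every construct is, by construction, an exact unit-variance
linear composite of its own indicator block, while the indicator–construct
correlations equal the specified loadings and the constructs obey the
specified recursive structural equations.  Because the data-generating
process matches the composite model that PLS path modelling estimates,
parameter-recovery experiments measure implementation error rather than
factor-model bias.

Construction per reflective block with loadings λ (all |λ| < 1, K ≥ 2):
``x = λ·η + u`` with residual covariance ``D^{1/2} M D^{1/2}`` where
``D = diag(1 − λ²)`` and ``M`` is the equicorrelation matrix at
``−1/(K−1)``.  ``M`` is singular with null vector **1**, so the weighted
sum ``Σ x_k / (K · sqrt(1−λ_k²)) ∝ η`` recovers the construct exactly.
A block containing a unit loading (or a single indicator) instead uses
independent residuals — the unit-loading indicator *is* the construct.
Formative blocks draw indicators as equicorrelated normals and define the
construct as the stated weighted composite (standardized), conditioning
the block on the structural value of the construct.

Morphology grades are drawn by thresholding independent latent normals at
the cumulative grade marginals; symptom severities are Bernoulli with the
stated prevalences, with half the positives escalated to severity 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_spec import ModelSpec, exogenous_and_endogenous, subhealth_model

__all__ = [
    "PopulationModel",
    "SyntheticCohort",
    "PopulationError",
    "default_population",
    "lv_covariance",
    "implied_covariance",
    "sample_cohort",
    "parameter_recovery_report",
]

GRADE_LEVELS = {
    "tortuosity": ("T1", "T2", "T3"),
    "trunk_length": ("L1", "L2", "L3"),
    "width": ("W1", "W2", "W3"),
}


class PopulationError(ValueError):
    """The declared population implies an inadmissible covariance structure."""


@dataclass
class PopulationModel:
    """Parametric description of the cohort-generating process.

    Parameters
    ----------
    spec : ModelSpec
        Constructs, modes and structural paths.
    loadings : dict
        Target indicator–construct correlation per reflective indicator.
    formative_weights : dict
        Composite weights per formative indicator (pre-normalisation).
    path_coefficients : dict
        ``(source, target) -> β`` for every structural path.
    exo_correlations : dict
        ``(a, b) -> r`` between exogenous constructs (0 if omitted).
    formative_indicator_correlation : float
        Pairwise correlation of formative indicators (default 0.43, which
        puts the two-indicator VIF at ≈1.23).
    grade_marginals : dict
        Three proportions (summing to 1) per morphology dimension.
    symptom_prevalences : dict
        Probability of a positive (severity ≥ 1) per symptom.
    symptom_clusters : dict
        Symptom name -> one of the 11 symptom-cluster labels.
    """

    spec: ModelSpec
    loadings: dict[str, float] = field(default_factory=dict)
    formative_weights: dict[str, float] = field(default_factory=dict)
    path_coefficients: dict[tuple[str, str], float] = field(default_factory=dict)
    exo_correlations: dict[tuple[str, str], float] = field(default_factory=dict)
    formative_indicator_correlation: float = 0.43
    grade_marginals: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    symptom_prevalences: dict[str, float] = field(default_factory=dict)
    symptom_clusters: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for x, lam in self.loadings.items():
            if abs(lam) > 1:
                raise PopulationError(f"|loading| > 1 for indicator {x!r}")
        for dim, probs in self.grade_marginals.items():
            if abs(sum(probs) - 1.0) > 1e-9:
                raise PopulationError(f"grade marginals for {dim!r} do not sum to 1")
        # admissibility of the full structure (raises PopulationError)
        lv_covariance(self)
        for name in self.spec.construct_names:
            _block_structure(self, name)

    def block_loadings(self, construct: str) -> np.ndarray:
        """Population indicator–construct correlations, reflective or formative."""
        L, _, _ = _block_structure(self, construct)
        return L


def _exo_corr(pop: PopulationModel, a: str, b: str) -> float:
    if a == b:
        return 1.0
    return pop.exo_correlations.get((a, b), pop.exo_correlations.get((b, a), 0.0))


def lv_covariance(pop: PopulationModel) -> pd.DataFrame:
    """Model-implied covariance (= correlation) matrix of the constructs.

    Solved recursively along a topological order of the structural graph;
    every construct has unit variance, so the disturbance variance of an
    endogenous construct is 1 minus the variance its predecessors explain.
    Raises :class:`PopulationError` if that residual variance is not
    positive.
    """
    spec = pop.spec
    order = spec.topological_order()
    names = spec.construct_names
    exo, _ = exogenous_and_endogenous(spec)
    J = len(names)
    ix = {n: i for i, n in enumerate(names)}
    Phi = np.eye(J)
    for a in exo:
        for b in exo:
            Phi[ix[a], ix[b]] = _exo_corr(pop, a, b)
    done: list[str] = []
    for name in order:
        j = ix[name]
        if name not in exo:
            preds = spec.predecessors(name)
            beta = np.array([pop.path_coefficients.get((p, name), 0.0) for p in preds])
            pix = [ix[p] for p in preds]
            for other in done:
                cov = float(beta @ Phi[pix, ix[other]])
                Phi[j, ix[other]] = Phi[ix[other], j] = cov
            explained = float(beta @ Phi[np.ix_(pix, pix)] @ beta)
            if explained >= 1.0 - 1e-12:
                raise PopulationError(
                    f"structural disturbance variance for {name!r} is not positive"
                )
            Phi[j, j] = 1.0
        done.append(name)
    return pd.DataFrame(Phi, index=names, columns=names)


def _disturbance_sd(pop: PopulationModel, Phi: pd.DataFrame, name: str) -> float:
    preds = pop.spec.predecessors(name)
    beta = np.array([pop.path_coefficients.get((p, name), 0.0) for p in preds])
    explained = float(beta @ Phi.loc[preds, preds].to_numpy() @ beta)
    return float(np.sqrt(1.0 - explained))


def _block_structure(pop: PopulationModel, construct: str):
    """Return (population loadings L, within-block correlation R, residual cov S).

    ``R = L·L' + S`` and the construct is an exact composite of the block.
    """
    con = pop.spec.construct(construct)
    K = len(con.indicators)
    if con.mode == "formative":
        w = np.array([pop.formative_weights[x] for x in con.indicators], float)
        rho = pop.formative_indicator_correlation
        R = np.full((K, K), rho) + (1 - rho) * np.eye(K)
        scale = float(np.sqrt(w @ R @ w))
        if scale <= 0:
            raise PopulationError(f"degenerate formative weights for {construct!r}")
        w_tilde = w / scale
        L = R @ w_tilde
        S = R - np.outer(L, L)
    else:
        lam = np.array([pop.loadings[x] for x in con.indicators], float)
        d = 1.0 - lam**2
        if K == 1 or np.any(np.abs(lam) >= 1.0 - 1e-9):
            S = np.diag(d)
        elif abs(np.sum(lam / np.sqrt(d))) < 1e-12:
            # construct not recoverable from the block (e.g. all-zero
            # loadings): fall back to independent residuals
            S = np.diag(d)
        else:
            M = np.full((K, K), -1.0 / (K - 1)) + (K / (K - 1)) * np.eye(K)
            S = np.sqrt(np.outer(d, d)) * M
        L = lam
        R = np.outer(L, L) + S
    if np.min(np.linalg.eigvalsh(R)) < -1e-8:
        raise PopulationError(f"inadmissible indicator covariance in block {construct!r}")
    return L, R, S


def implied_covariance(pop: PopulationModel) -> pd.DataFrame:
    """Exact model-implied indicator covariance matrix (analytic oracle).

    Within-block covariance is ``L·L' + S`` from the block construction;
    between blocks it is ``L_j · Φ_jk · L_k'`` with Φ the construct
    covariance from :func:`lv_covariance`.
    """
    spec = pop.spec
    Phi = lv_covariance(pop).to_numpy()
    names = spec.construct_names
    cols = spec.indicator_names
    p = len(cols)
    Sigma = np.zeros((p, p))
    offs: list[np.ndarray] = []
    start = 0
    Ls = []
    for name in names:
        k = len(spec.construct(name).indicators)
        offs.append(np.arange(start, start + k))
        start += k
        Ls.append(_block_structure(pop, name))
    for j, name_j in enumerate(names):
        Lj, Rj, _ = Ls[j]
        Sigma[np.ix_(offs[j], offs[j])] = Rj
        for k in range(j + 1, len(names)):
            Lk, _, _ = Ls[k]
            block = np.outer(Lj, Lk) * Phi[j, k]
            Sigma[np.ix_(offs[j], offs[k])] = block
            Sigma[np.ix_(offs[k], offs[j])] = block.T
    return pd.DataFrame(Sigma, index=cols, columns=cols)


@dataclass
class SyntheticCohort:
    """A generated cohort: indicators, true construct scores, grades, symptoms."""

    indicators: pd.DataFrame
    true_lv_scores: pd.DataFrame
    sv_grades: pd.DataFrame
    symptoms: pd.DataFrame
    seed: int
    n: int


def _sample_lv(pop: PopulationModel, n: int, rng: np.random.Generator) -> pd.DataFrame:
    spec = pop.spec
    exo, _ = exogenous_and_endogenous(spec)
    Phi = lv_covariance(pop)
    eta = pd.DataFrame(index=range(n), columns=spec.construct_names, dtype=float)
    if exo:
        R_exo = Phi.loc[exo, exo].to_numpy()
        chol = np.linalg.cholesky(R_exo + 1e-12 * np.eye(len(exo)))
        eta[exo] = rng.standard_normal((n, len(exo))) @ chol.T
    for name in spec.topological_order():
        if name in exo:
            continue
        preds = spec.predecessors(name)
        beta = np.array([pop.path_coefficients.get((p, name), 0.0) for p in preds])
        zeta_sd = _disturbance_sd(pop, Phi, name)
        eta[name] = eta[preds].to_numpy() @ beta + zeta_sd * rng.standard_normal(n)
    return eta


def sample_cohort(pop: PopulationModel, n: int, seed: int) -> SyntheticCohort:
    """Draw a cohort of ``n`` subjects; bit-reproducible from (pop, n, seed)."""
    if n < 10:
        raise ValueError("n must be at least 10")
    rng = np.random.default_rng(seed)
    spec = pop.spec
    eta = _sample_lv(pop, n, rng)
    X = pd.DataFrame(index=range(n), columns=spec.indicator_names, dtype=float)
    for name in spec.construct_names:
        con = spec.construct(name)
        K = len(con.indicators)
        L, R, S = _block_structure(pop, name)
        e = eta[name].to_numpy()
        # residuals with covariance S (possibly singular: exact composite)
        vals, vecs = np.linalg.eigh(S)
        A = vecs @ np.diag(np.sqrt(np.clip(vals, 0, None)))
        u = rng.standard_normal((n, K)) @ A.T
        X[list(con.indicators)] = np.outer(e, L) + u
    grades = sample_grades(pop, n, rng)
    symptoms = sample_symptoms(pop, n, rng)
    return SyntheticCohort(X, eta, grades, symptoms, seed=seed, n=n)


def sample_grades(pop: PopulationModel, n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Ordinal morphology grades by thresholding latent normals at the marginals."""
    out = {}
    for dim, probs in pop.grade_marginals.items():
        cum = np.cumsum(probs)[:-1]
        z = rng.standard_normal(n)
        from scipy.stats import norm

        idx = np.searchsorted(norm.ppf(cum), z)
        levels = GRADE_LEVELS.get(dim, tuple(f"{dim}{i + 1}" for i in range(len(probs))))
        out[dim] = np.asarray(levels)[idx]
    return pd.DataFrame(out, index=range(n))


def sample_symptoms(pop: PopulationModel, n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Long-format (subject, symptom, severity) table, severity ∈ {0, 1, 2}."""
    frames = []
    for symptom, prev in pop.symptom_prevalences.items():
        positive = rng.random(n) < prev
        severity = positive.astype(int)
        pos_idx = np.flatnonzero(positive)
        if len(pos_idx):
            two = rng.choice(pos_idx, size=len(pos_idx) // 2, replace=False)
            severity[two] = 2
        frames.append(
            pd.DataFrame({"subject": range(n), "symptom": symptom, "severity": severity})
        )
    if not frames:
        return pd.DataFrame(columns=["subject", "symptom", "severity"])
    return pd.concat(frames, ignore_index=True)


def parameter_recovery_report(
    pop: PopulationModel,
    n: int,
    seeds: list[int] | np.ndarray,
    n_boot: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Bias/RMSE of estimated path coefficients over replicate cohorts.

    Fits the PLS engine to one cohort per seed; when ``n_boot > 0`` the
    bootstrap is run as well and the per-path rejection rate at ``alpha``
    is reported (useful for null calibration on a zero-coefficient path).
    """
    from .pls import PLSPathModel
    from .bootstrap import bootstrap_paths

    path_names = [f"{s} -> {t}" for s, t in pop.spec.paths]
    popval = pd.Series(
        {f"{s} -> {t}": pop.path_coefficients.get((s, t), 0.0) for s, t in pop.spec.paths}
    )
    est = np.zeros((len(seeds), len(path_names)))
    rej = np.zeros((len(seeds), len(path_names)))
    for i, seed in enumerate(seeds):
        cohort = sample_cohort(pop, n, int(seed))
        if n_boot > 0:
            res = bootstrap_paths(
                cohort.indicators, pop.spec, n_boot=n_boot, seed=int(seed), alpha=alpha
            )
            est[i] = res.original[path_names].to_numpy()
            rej[i] = (res.decision[path_names] == "Supported").to_numpy()
        else:
            pls = PLSPathModel(model=pop.spec).fit(cohort.indicators)
            est[i] = pls.path_coefficients_[path_names].to_numpy()
    report = pd.DataFrame(index=path_names)
    report["population"] = popval
    report["mean_estimate"] = est.mean(axis=0)
    report["bias"] = report["mean_estimate"] - report["population"]
    report["rmse"] = np.sqrt(((est - popval.to_numpy()) ** 2).mean(axis=0))
    report["rejection_rate"] = rej.mean(axis=0) if n_boot > 0 else np.nan
    return report


# -- packaged default population --------------------------------------------

_TABLE_LOADINGS = {
    "HGB": 1.00, "MCHC": 0.57, "RBC": 0.84, "HCT": 0.97,
    "TC": 0.88, "TG": 0.74, "LDL": 0.72,
    "AKP": 0.70, "ALT": 0.80, "AST": 0.72, "GGT": 0.78,
    "SV-L": 0.64, "SV-a": 0.95, "SV-b": 0.78,
}

_TABLE_PATHS = {
    ("routine_blood_test", "sv_characteristics"): 0.093,
    ("routine_blood_test", "lipid_metabolism"): 0.225,
    ("obesity", "sv_characteristics"): -0.111,
    ("lipid_metabolism", "obesity"): 0.307,
    ("liver_function", "sv_characteristics"): -0.117,
}

# subhealthy-group grade counts out of 627
_GRADE_MARGINALS = {
    "tortuosity": (196 / 627, 269 / 627, 162 / 627),
    "trunk_length": (427 / 627, 109 / 627, 91 / 627),
    "width": (80 / 627, 71 / 627, 476 / 627),
}

# the four printed prevalences plus a realistic default per remaining cluster
_SYMPTOMS = {
    "limb soreness": (0.376, "pain"),
    "fatigue": (0.316, "mental psyche"),
    "shoulder and neck pain": (0.305, "pain"),
    "dry eyes": (0.292, "head"),
    "poor sleep": (0.25, "mental psyche"),
    "dizziness": (0.20, "head"),
    "aversion to cold": (0.18, "cold and heat"),
    "constipation": (0.17, "passing stool and urinating"),
    "bitter taste": (0.16, "taste"),
    "chest tightness": (0.15, "chest and abdomen"),
    "poor appetite": (0.14, "diet"),
    "night sweats": (0.12, "sweating"),
    "coughing up phlegm": (0.10, "coughing-up phlegm"),
    "irregular menstruation": (0.08, "menstruation"),
}


def default_population(spec: ModelSpec | None = None) -> PopulationModel:
    """The packaged subhealth population: printed loadings, weights, paths,
    exogenous correlation, grade marginals and symptom prevalences."""
    return PopulationModel(
        spec=spec if spec is not None else subhealth_model(),
        loadings=dict(_TABLE_LOADINGS),
        formative_weights={"BMI": 0.71, "WHR": 0.46},
        path_coefficients=dict(_TABLE_PATHS),
        exo_correlations={("routine_blood_test", "liver_function"): 0.468},
        formative_indicator_correlation=0.43,
        grade_marginals=dict(_GRADE_MARGINALS),
        symptom_prevalences={k: v[0] for k, v in _SYMPTOMS.items()},
        symptom_clusters={k: v[1] for k, v in _SYMPTOMS.items()},
    )
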