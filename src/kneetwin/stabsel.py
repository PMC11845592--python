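"""Bootstrap elastic-net stability selection and the final logistic model.

For each bootstrap resample of the matched cohort, an elastic-net-penalized
binomial GLM (logit link) is fitted to the standardized design of PC-mode
features plus covariates.  A feature counts as selected when its
coefficient magnitude exceeds a small threshold (default 1e-5 — i.e. it
survived the L1 part of the penalty); the selection frequency across
resamples times the absolute mean coefficient (averaged over ALL fits,
zeros included) is the feature's weighted importance.  Features in the
upper quartile of weighted importance are retained and passed, together
with the unpenalized covariates, to a final unregularized logistic
regression reporting coefficients, Wald intervals and odds ratios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV

__all__ = [
    "StabilityConfig",
    "StabilityResult",
    "FinalModelResult",
    "bootstrap_elastic_net",
    "weighted_importance",
    "retain_upper_quartile",
    "stability_selection",
    "final_logistic",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class StabilityConfig:
    n_boot: int = 1000
    coefficient_threshold: float = 1e-5
    l1_ratio: float = 0.5  # elastic-net mixing; 1 = lasso
    penalty_strength: float | str = "cv"  # inverse-C lambda, or "cv" to pick once
    retention_quantile: float = 0.75
    seed: int = 0
    max_redraws: int = 50

    def __post_init__(self) -> None:
        if self.coefficient_threshold <= 0:
            raise ValueError("coefficient threshold must be positive")
        if not 0 < self.retention_quantile < 1:
            raise ValueError("retention quantile must lie in (0, 1)")
        if not 0 < self.l1_ratio <= 1:
            raise ValueError("elastic-net mixing parameter must lie in (0, 1]")


@dataclass
class StabilityResult:
    table: pd.DataFrame  # feature x {frequency, mean_coefficient, importance, retained}
    coefficients: np.ndarray  # (n_boot, n_features) per-bootstrap coefficients
    cutoff: float
    penalty_strength: float


@dataclass
class FinalModelResult:
    table: pd.DataFrame  # term x {coef, se, p, ci95/99, odds_ratio, or_ci95}
    pseudo_r2: float
    pearson_chi2: float
    log_likelihood: float
    n: int
    model: object = field(repr=False, default=None)


def _choose_penalty(X, y, config: StabilityConfig) -> float:
    """Fix the penalty once by 5-fold CV deviance on the full sample, so
    selection frequencies are comparable across bootstraps."""
    if config.penalty_strength != "cv":
        return float(config.penalty_strength)
    cv = LogisticRegressionCV(
        Cs=np.logspace(-2, 2, 7),
        solver="saga",
        l1_ratios=[config.l1_ratio],
        scoring="neg_log_loss",
        cv=5,
        max_iter=2000,
        tol=1e-3,
        random_state=config.seed,
        n_jobs=1,
        use_legacy_attributes=False,
    )
    cv.fit(X, y)
    return 1.0 / float(np.atleast_1d(cv.C_)[0])


def bootstrap_elastic_net(
    X: pd.DataFrame, y, config: StabilityConfig = StabilityConfig()
) -> StabilityResult:
    """Selection frequency and mean coefficient over bootstrap resamples.

    Rows are drawn with replacement; resamples that land on a single
    outcome class are redrawn (and logged) rather than silently dropped.
    Deterministic given ``config.seed``.  Columns are assumed standardized.
    """
    y = np.asarray(y, dtype=int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("y must be binary with both classes present")
    Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"x{i}" for i in range(Xv.shape[1])
    ]
    n, p = Xv.shape
    lam = _choose_penalty(Xv, y, config)
    rng = np.random.default_rng(config.seed)
    coefs = np.zeros((config.n_boot, p))
    n_redrawn = 0
    model = LogisticRegression(
        solver="saga",
        l1_ratio=config.l1_ratio,
        C=1.0 / lam,
        max_iter=2000,
        tol=1e-4,
        random_state=config.seed,  # saga shuffles; fix it for determinism
    )
    for b in range(config.n_boot):
        for _ in range(config.max_redraws):
            idx = rng.integers(0, n, n)
            yb = y[idx]
            if yb.min() != yb.max():
                break
            n_redrawn += 1
        else:
            raise RuntimeError("could not draw a two-class bootstrap resample")
        model.fit(Xv[idx], yb)
        coefs[b] = model.coef_[0]
    if n_redrawn:
        log.info("bootstrap_elastic_net: redrew %d one-class resamples", n_redrawn)
    frequency = (np.abs(coefs) > config.coefficient_threshold).mean(axis=0)
    mean_coef = coefs.mean(axis=0)  # over ALL fits, zeros included
    importance = weighted_importance(frequency, mean_coef)
    retained, cutoff = retain_upper_quartile(
        importance, quantile=config.retention_quantile
    )
    table = pd.DataFrame(
        {
            "frequency": frequency,
            "mean_coefficient": mean_coef,
            "importance": importance,
            "retained": retained,
        },
        index=pd.Index(names, name="feature"),
    )
    return StabilityResult(
        table=table, coefficients=coefs, cutoff=cutoff, penalty_strength=lam
    )


# the full stability-selection stage under its field name
stability_selection = bootstrap_elastic_net


def weighted_importance(frequency, mean_coefficient) -> np.ndarray:
    """Importance = selection frequency x |mean coefficient|, exactly."""
    frequency = np.asarray(frequency, dtype=float)
    if np.any((frequency < 0) | (frequency > 1)):
        raise ValueError("frequency must lie in [0, 1]")
    return frequency * np.abs(np.asarray(mean_coefficient, dtype=float))


def retain_upper_quartile(
    scores, quantile: float = 0.75
) -> tuple[np.ndarray, float]:
    """Retain scores at or above the linear-interpolation upper quartile.

    Returns (flags, cutoff).  If every score is equal the quartile is
    degenerate: everything is retained, with a warning in the log.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 4:
        raise ValueError("need at least 4 scores for a quartile rule")
    cutoff = float(np.quantile(scores, quantile))  # linear interpolation
    if np.ptp(scores) == 0:
        log.warning("retain_upper_quartile: all scores equal; retaining all")
        return np.ones(scores.size, dtype=bool), cutoff
    return scores >= cutoff, cutoff


def final_logistic(
    X: pd.DataFrame, y, alpha_levels: tuple[float, float] = (0.05, 0.01)
) -> FinalModelResult:
    """Unpenalized binomial GLM (logit) on the retained features + covariates.

    Reports per-term coefficient, standard error, two-sided Wald p, 95%
    and 99% Wald intervals, and odds ratio = exp(coefficient) with the
    exponentiated interval; model-level McFadden pseudo-R^2, Pearson
    chi-squared and log-likelihood.  Perfect separation and rank-deficient
    designs raise with the offending columns named.
    """
    Xd = X.copy() if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
    y = np.asarray(y, dtype=float)
    if Xd.empty or Xd.shape[1] == 0:
        raise ValueError("retained feature set is empty")
    rank = np.linalg.matrix_rank(Xd.to_numpy())
    if rank < Xd.shape[1]:
        # name columns involved in the collinearity via QR pivoting
        _, r = np.linalg.qr(Xd.to_numpy())
        bad = [Xd.columns[i] for i in range(Xd.shape[1]) if abs(r[i, i]) < 1e-10]
        raise ValueError(f"design is rank deficient; collinear columns: {bad}")
    design = sm.add_constant(Xd, has_constant="add")
    model = sm.GLM(y, design, family=sm.families.Binomial())
    with np.errstate(all="ignore"):
        try:
            fit = model.fit(maxiter=200)
        except Exception as err:  # statsmodels PerfectSeparationError
            raise ValueError(f"logistic fit failed: {err}") from err
    mu = fit.fittedvalues
    if np.any(mu < 1e-10) or np.any(mu > 1 - 1e-10):
        extreme = np.abs(fit.params.drop("const", errors="ignore"))
        raise ValueError(
            "perfect (or quasi-perfect) separation detected; "
            f"dominant feature: {extreme.idxmax()!r}"
        )
    rows = []
    z95 = 1.959963984540054
    z99 = 2.5758293035489004
    for term in design.columns:
        b = float(fit.params[term])
        se = float(fit.bse[term])
        rows.append(
            {
                "term": term,
                "coef": b,
                "se": se,
                "p": float(fit.pvalues[term]),
                "ci95_lo": b - z95 * se,
                "ci95_hi": b + z95 * se,
                "ci99_lo": b - z99 * se,
                "ci99_hi": b + z99 * se,
                "odds_ratio": float(np.exp(b)),
                "or_ci95_lo": float(np.exp(b - z95 * se)),
                "or_ci95_hi": float(np.exp(b + z95 * se)),
            }
        )
    llf = float(fit.llf)
    llnull = float(fit.llnull) if hasattr(fit, "llnull") else _null_llf(y)
    pseudo_r2 = 1.0 - llf / llnull if llnull != 0 else np.nan
    return FinalModelResult(
        table=pd.DataFrame(rows).set_index("term"),
        pseudo_r2=pseudo_r2,
        pearson_chi2=float(fit.pearson_chi2),
        log_likelihood=llf,
        n=len(y),
        model=fit,
    )


def _null_llf(y: np.ndarray) -> float:
    p = y.mean()
    return float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))
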