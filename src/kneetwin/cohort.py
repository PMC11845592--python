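"""Cohort construction: outcome derivation, filtering, imputation,
t-SNE embedding with nearest-neighbour matching, and covariate balance.

Outcomes follow radiographic osteoarthritis conventions: a knee is an
OA-incidence case if it is free of radiographic OA at baseline
(Kellgren-Lawrence grade < 2) but reaches KLG >= 2 at any follow-up, and a
control if KLG < 2 at every visit; a knee-replacement case underwent
partial or total replacement after baseline, a control never did.

Matching embeds the standardized covariates of cases and controls jointly
into a 3-D t-SNE space (perplexity = sqrt(N), floored at 5) and pairs each
case with the control at minimum Euclidean embedded distance, with
replacement.  t-SNE is stochastic, so a seed is mandatory and results are
reported per seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.manifold import TSNE

__all__ = [
    "OutcomeDefinition",
    "MatchConfig",
    "MatchResult",
    "BalanceReport",
    "derive_outcomes",
    "filter_dataset",
    "impute",
    "ks_sensitivity",
    "embed_and_match",
    "match_in_embedding",
    "balance_report",
    "cohens_d",
    "cramers_v",
    "standardize_covariates",
]

log = logging.getLogger(__name__)

DEFAULT_CATEGORICAL = ("sex", "race", "injury_history")


@dataclass(frozen=True)
class OutcomeDefinition:
    """Case/control rules over longitudinal KLG grades and surgery flags."""

    name: str  # {"oa_incidence", "knee_replacement"}

    def classify(self, klg: np.ndarray, surgery: int) -> str:
        """Label one knee: 'case', 'control' or 'excluded'.

        ``klg`` is the per-visit trajectory (baseline first); NaN visits
        are ignored except a missing baseline, which excludes the knee.
        """
        if np.isnan(klg[0]):
            return "excluded"
        follow = klg[1:]
        follow = follow[~np.isnan(follow)]
        if self.name == "oa_incidence":
            if klg[0] >= 2:
                return "excluded"
            if follow.size and np.any(follow >= 2):
                return "case"
            if np.all(klg[~np.isnan(klg)] < 2):
                return "control"
            return "excluded"
        if self.name == "knee_replacement":
            return "case" if surgery else "control"
        raise ValueError(f"unknown outcome {self.name!r}")


@dataclass(frozen=True)
class MatchConfig:
    embedding_dim: int = 3
    perplexity: float | None = None  # default sqrt(N), floored at 5
    seed: int = 0
    with_replacement: bool = True


@dataclass
class MatchResult:
    pairs: pd.DataFrame  # columns: case_id, control_id, distance
    embedding: pd.DataFrame  # index subject id, columns e0..e{d-1}, group

    @property
    def n_distinct_controls(self) -> int:
        return int(self.pairs["control_id"].nunique())


@dataclass
class BalanceReport:
    continuous: pd.DataFrame  # covariate x metric, pre- and post-matching
    categorical: pd.DataFrame


def derive_outcomes(
    klg_trajectories: pd.DataFrame, surgery_flags: pd.Series, outcome: str
) -> pd.Series:
    """Label every knee case/control/excluded for one outcome definition.

    ``klg_trajectories``: one row per knee, one column per visit, baseline
    first.  Knees with a missing baseline grade are excluded with a logged
    reason.
    """
    rule = OutcomeDefinition(outcome)
    klg = klg_trajectories.to_numpy(dtype=float)
    labels = []
    n_missing_baseline = 0
    for i, idx in enumerate(klg_trajectories.index):
        lab = rule.classify(klg[i], int(surgery_flags.loc[idx] or 0))
        if lab == "excluded" and np.isnan(klg[i, 0]):
            n_missing_baseline += 1
        labels.append(lab)
    if n_missing_baseline:
        log.info("derive_outcomes: %d knees excluded for missing baseline KLG",
                 n_missing_baseline)
    return pd.Series(labels, index=klg_trajectories.index, name=outcome)


def filter_dataset(
    features: pd.DataFrame,
    feature_columns: list[str],
    covariate_columns: list[str],
    missingness_cap: float = 0.05,
) -> pd.DataFrame:
    """Inclusion/missingness filter applied before any analysis.

    Keeps right-knee rows only, drops subjects missing any imaging
    feature value, and drops covariate columns whose missing fraction
    exceeds ``missingness_cap`` (default: more than 5% missing).
    """
    table = features
    n0 = len(table)
    if "side" in table.columns:
        table = table[table["side"] == "right"]
        log.info("filter_dataset: %d/%d rows are right knees", len(table), n0)
    complete = table[feature_columns].notna().all(axis=1)
    if (~complete).any():
        log.info("filter_dataset: dropping %d subjects missing a PC-mode value",
                 int((~complete).sum()))
    table = table[complete]
    kept_cov = []
    for col in covariate_columns:
        frac = table[col].isna().mean()
        if frac > missingness_cap:
            log.info("filter_dataset: dropping covariate %r (%.1f%% missing)",
                     col, 100 * frac)
        else:
            kept_cov.append(col)
    drop = [c for c in covariate_columns if c not in kept_cov]
    table = table.drop(columns=drop)
    if table.empty:
        raise ValueError("filtering removed every subject")
    return table


def impute(
    table: pd.DataFrame,
    seed: int,
    categorical: tuple[str, ...] = DEFAULT_CATEGORICAL,
    columns: list[str] | None = None,
    n_iter: int = 3,
    n_estimators: int = 50,
) -> pd.DataFrame:
    """Round-robin random-forest imputation of the covariate columns.

    Columns are initially filled with the mode (categorical) or median
    (continuous), then each incomplete column is re-predicted in turn from
    all the others by a RandomForestClassifier / RandomForestRegressor,
    for ``n_iter`` sweeps.  Observed entries are never altered; the result
    is deterministic given ``seed``.  Complete tables pass through
    unchanged.
    """
    cols = columns if columns is not None else [
        c for c in table.columns if table[c].dtype.kind in "ifb"
    ]
    missing = {c: table[c].isna() for c in cols}
    if not any(m.any() for m in missing.values()):
        return table.copy()
    for c in cols:
        if missing[c].all():
            raise ValueError(f"column {c!r} is entirely missing")
    out = table.copy()
    filled = out[cols].copy()
    for c in cols:
        if missing[c].any():
            fill = (
                filled[c].mode().iloc[0] if c in categorical else filled[c].median()
            )
            filled.loc[missing[c], c] = fill
    rng = np.random.default_rng(seed)
    incomplete = [c for c in cols if missing[c].any()]
    for _ in range(n_iter):
        for c in incomplete:
            others = [o for o in cols if o != c]
            X = filled[others].to_numpy(dtype=float)
            y_obs = table.loc[~missing[c], c]
            model_cls = (
                RandomForestClassifier if c in categorical else RandomForestRegressor
            )
            model = model_cls(
                n_estimators=n_estimators,
                random_state=int(rng.integers(2**31 - 1)),
                n_jobs=1,
            )
            if c in categorical:
                model.fit(X[~missing[c].to_numpy()], y_obs.astype(int))
            else:
                model.fit(X[~missing[c].to_numpy()], y_obs.astype(float))
            pred = model.predict(X[missing[c].to_numpy()])
            filled.loc[missing[c], c] = pred
    for c in incomplete:
        out.loc[missing[c], c] = filled.loc[missing[c], c]
    return out


def ks_sensitivity(pre: pd.DataFrame, post: pd.DataFrame) -> pd.DataFrame:
    """Two-sample Kolmogorov-Smirnov statistic per shared column.

    Compares pre- vs post-imputation distributions; NaNs in the pre table
    are dropped column-wise.
    """
    rows = []
    for col in pre.columns:
        if col not in post.columns:
            continue
        a = pre[col].dropna().to_numpy(dtype=float)
        b = post[col].dropna().to_numpy(dtype=float)
        if a.size == 0 or b.size == 0:
            raise ValueError(f"column {col!r} has no observations")
        ks = stats.ks_2samp(a, b)
        rows.append({"covariate": col, "statistic": ks.statistic, "p": ks.pvalue})
    return pd.DataFrame(rows).set_index("covariate")


def standardize_covariates(
    table: pd.DataFrame,
    continuous: list[str],
    categorical: list[str],
) -> pd.DataFrame:
    """z-score continuous covariates, integer-encode categorical ones."""
    out = pd.DataFrame(index=table.index)
    for c in continuous:
        v = table[c].to_numpy(dtype=float)
        out[c] = (v - v.mean()) / max(v.std(), 1e-12)
    for c in categorical:
        codes = pd.Categorical(table[c]).codes.astype(float)
        out[c] = codes
    return out


def embed_and_match(
    covariates: pd.DataFrame,
    case_ids,
    control_ids,
    config: MatchConfig = MatchConfig(),
) -> MatchResult:
    """Joint 3-D t-SNE of cases + controls, then nearest-control matching.

    Perplexity defaults to sqrt(N) rounded, floored at 5 (N = rows
    embedded).  Every case is matched to the control minimizing Euclidean
    distance in the embedding; with replacement, a control may serve
    several cases.  Distance ties break to the lowest control index.
    """
    case_ids = list(case_ids)
    control_ids = list(control_ids)
    if not control_ids:
        raise ValueError("no controls to match against")
    roster = case_ids + control_ids
    X = covariates.loc[roster].to_numpy(dtype=float)
    n = len(roster)
    perplexity = config.perplexity
    if perplexity is None:
        perplexity = max(5.0, float(np.round(np.sqrt(n))))
    perplexity = min(perplexity, n - 1)
    tsne = TSNE(
        n_components=config.embedding_dim,
        perplexity=perplexity,
        random_state=config.seed,
        init="pca" if X.shape[1] >= config.embedding_dim else "random",
    )
    emb = tsne.fit_transform(X)
    embedding = pd.DataFrame(
        emb, index=pd.Index(roster, name="subject_id"),
        columns=[f"e{i}" for i in range(config.embedding_dim)],
    )
    embedding["group"] = ["case"] * len(case_ids) + ["control"] * len(control_ids)
    return match_in_embedding(embedding, case_ids, control_ids, config)


def match_in_embedding(
    embedding: pd.DataFrame, case_ids, control_ids, config: MatchConfig = MatchConfig()
) -> MatchResult:
    """Nearest-control assignment inside a given embedding (the matching
    contract is separable from t-SNE so it can be checked exactly)."""
    dims = [c for c in embedding.columns if c.startswith("e")]
    case_pts = embedding.loc[case_ids, dims].to_numpy(dtype=float)
    ctrl_pts = embedding.loc[control_ids, dims].to_numpy(dtype=float)
    if not config.with_replacement:
        # greedy without replacement: cases in input order take their nearest
        # remaining control
        available = list(range(len(control_ids)))
        rows = []
        for i, cid in enumerate(case_ids):
            d = np.linalg.norm(ctrl_pts[available] - case_pts[i], axis=1)
            j = int(np.argmin(d))
            rows.append((cid, control_ids[available[j]], float(d[j])))
            available.pop(j)
            if not available:
                break
        pairs = pd.DataFrame(rows, columns=["case_id", "control_id", "distance"])
        return MatchResult(pairs=pairs, embedding=embedding)
    # brute-force distance matrix keeps the lowest-index tie-break exact
    d = np.linalg.norm(case_pts[:, None, :] - ctrl_pts[None, :, :], axis=2)
    j = np.argmin(d, axis=1)  # argmin tie-breaks to the lowest index
    pairs = pd.DataFrame(
        {
            "case_id": case_ids,
            "control_id": [control_ids[k] for k in j],
            "distance": d[np.arange(len(case_ids)), j],
        }
    )
    return MatchResult(pairs=pairs, embedding=embedding)


def cohens_d(case: np.ndarray, control: np.ndarray) -> float:
    """Standardized mean difference with pooled SD = sqrt of the average of
    the two Bessel-corrected group variances; 0 for identical groups."""
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    pooled = np.sqrt((case.var(ddof=1) + control.var(ddof=1)) / 2.0)
    if pooled == 0:
        return 0.0
    return float((case.mean() - control.mean()) / pooled)


def cramers_v(group: np.ndarray, values: np.ndarray) -> tuple[float, float, float]:
    """Cramer's V with the chi-squared statistic and p for a group x
    category contingency table; zero cells are tolerated."""
    tab = pd.crosstab(pd.Series(group), pd.Series(values))
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        return 0.0, 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(tab.to_numpy(), correction=False)
    n = tab.to_numpy().sum()
    k = min(tab.shape) - 1
    v = float(np.sqrt(chi2 / (n * k))) if n * k > 0 else 0.0
    return min(v, 1.0), float(chi2), float(p)


def _continuous_metrics(case: np.ndarray, control: np.ndarray, paired: bool) -> dict:
    d = cohens_d(case, control)
    group = np.concatenate([np.ones(len(case)), np.zeros(len(control))])
    vals = np.concatenate([case, control])
    if np.ptp(vals) == 0:
        r, r_p = 0.0, 1.0
    else:
        r, r_p = stats.pointbiserialr(group, vals)
    if paired and len(case) == len(control):
        diff = case - control
        if np.allclose(diff, 0):
            w_stat, w_p = 0.0, 1.0
        else:
            w_stat, w_p = stats.wilcoxon(case, control)
    else:
        w_stat, w_p = np.nan, np.nan
    pooled = vals
    if np.ptp(pooled) == 0:
        sw_w, sw_p = np.nan, 0.0  # constant: flagged non-normal
        ad_stat, ad_sig = np.nan, 0.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sw_w, sw_p = stats.shapiro(pooled[:5000])
            ad = stats.anderson(pooled, dist="norm")
        ad_stat = float(ad.statistic)
        exceeded = ad.statistic > ad.critical_values
        ad_sig = float(ad.significance_level[exceeded][-1]) if exceeded.any() else 15.0
    return {
        "cohens_d": d,
        "point_biserial_r": float(r),
        "point_biserial_p": float(r_p),
        "wilcoxon_stat": float(w_stat),
        "wilcoxon_p": float(w_p),
        "shapiro_w": float(sw_w) if np.isfinite(sw_w) else np.nan,
        "shapiro_p": float(sw_p),
        "anderson_stat": ad_stat,
        "anderson_sig_level": ad_sig,
    }


def balance_report(
    table: pd.DataFrame,
    matches: MatchResult,
    continuous: list[str],
    categorical: list[str],
    outcome_col: str = "outcome",
) -> BalanceReport:
    """Covariate balance before and after matching.

    Pre-matching compares all cases vs all controls; post-matching
    compares the matched case rows against their (possibly repeated)
    matched controls, with the Wilcoxon signed-rank test on the matched
    pairs.  No multiple-testing correction is applied at this stage —
    these are diagnostic checks of matching quality, not hypothesis tests.
    """
    pre_case = table[table[outcome_col] == 1]
    pre_ctrl = table[table[outcome_col] == 0]
    m_case = table.loc[matches.pairs["case_id"]]
    m_ctrl = table.loc[matches.pairs["control_id"]]
    cont_rows, cat_rows = [], []
    for c in continuous:
        pre = _continuous_metrics(
            pre_case[c].to_numpy(dtype=float), pre_ctrl[c].to_numpy(dtype=float),
            paired=False,
        )
        post = _continuous_metrics(
            m_case[c].to_numpy(dtype=float), m_ctrl[c].to_numpy(dtype=float),
            paired=True,
        )
        cont_rows.append(
            {"covariate": c, **{f"pre_{k}": v for k, v in pre.items()},
             **{f"post_{k}": v for k, v in post.items()}}
        )
    for c in categorical:
        v_pre, chi_pre, p_pre = cramers_v(
            np.concatenate([np.ones(len(pre_case)), np.zeros(len(pre_ctrl))]),
            np.concatenate([pre_case[c].to_numpy(), pre_ctrl[c].to_numpy()]),
        )
        v_post, chi_post, p_post = cramers_v(
            np.concatenate([np.ones(len(m_case)), np.zeros(len(m_ctrl))]),
            np.concatenate([m_case[c].to_numpy(), m_ctrl[c].to_numpy()]),
        )
        cat_rows.append(
            {"covariate": c,
             "pre_cramers_v": v_pre, "pre_chi2": chi_pre, "pre_chi2_p": p_pre,
             "post_cramers_v": v_post, "post_chi2": chi_post, "post_chi2_p": p_post}
        )
    return BalanceReport(
        continuous=pd.DataFrame(cont_rows).set_index("covariate"),
        categorical=pd.DataFrame(cat_rows).set_index("covariate")
        if cat_rows else pd.DataFrame(),
    )
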