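"""Group-level inference for temporal brain-state metrics.

Covers covariate residualization, mixed-model group-by-state contrasts with
FDR correction and Cohen's d, the cortisol awakening response AUC_I, and a
group-blocked partial least squares correlation (PLSC) between behaviour and
brain-dynamics blocks with permutation testing and bootstrap stability.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

__all__ = [
    "residualize",
    "benjamini_hochberg",
    "cohens_d",
    "auc_increase",
    "fit_group_state_model",
    "group_state_contrasts",
    "PlscResult",
    "plsc_fit",
    "plsc_permutation_test",
    "plsc_bootstrap",
]

log = logging.getLogger(__name__)


def residualize(values: np.ndarray, covariates: np.ndarray | None = None) -> np.ndarray:
    """OLS residuals of ``values`` against an intercept plus covariates.

    With no covariates this is mean-centring.  Collinear covariate columns
    are dropped with a warning rather than failing.
    """
    y = np.asarray(values, dtype=float)
    n = y.shape[0]
    X = np.ones((n, 1))
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        X = np.column_stack([X, C])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn("collinear covariates dropped during residualization")
        keep = [0]
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, keep + [j]]) == len(keep) + 1:
                keep.append(j)
        X = X[:, keep]
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR adjustment (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.clip(adjusted, 0.0, 1.0)
    out = np.empty_like(adjusted)
    out[order] = adjusted
    return out


def cohens_d(group_a: np.ndarray, group_b: np.ndarray) -> float:
    """Cohen's d: mean difference over the pooled (n-1 weighted) SD."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = np.sqrt(
        ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
        / (a.size + b.size - 2)
    )
    if pooled == 0:
        raise ValueError("zero pooled standard deviation")
    return float((a.mean() - b.mean()) / pooled)


def auc_increase(samples, times=(0.0, 15.0, 30.0, 45.0, 60.0)) -> float:
    """Cortisol awakening response AUC with respect to the increase.

    Trapezoidal area under the five samples minus the baseline sample times
    the total span; may be negative.  Any missing sample makes the result
    undefined (NaN) for that subject.
    """
    s = np.asarray(samples, dtype=float)
    t = np.asarray(times, dtype=float)
    if s.shape != t.shape:
        raise ValueError("samples and times must align")
    if np.any(~np.isfinite(s)):
        return float("nan")
    return float(np.trapezoid(s, t) - s[0] * (t[-1] - t[0]))


# ---------------------------------------------------------------------------
# group-by-state models

_DEFAULT_COVARIATES = ("age", "sex", "psychotropic_medication", "mood_score", "n_retained")


def _contrast_vector(params_index, cap: int) -> np.ndarray:
    """Contrast picking the control-minus-patient difference at one state."""
    c = np.zeros(len(params_index))
    for i, name in enumerate(params_index):
        if "group" in name and "[T.control]" in name and ":" not in name:
            c[i] = 1.0
        if "group" in name and "[T.control]" in name and f"[T.{cap}]" in name:
            c[i] = 1.0
    return c


def _cluster_robust_cov(
    X: np.ndarray, resid: np.ndarray, subjects: np.ndarray, sigma2: float, tau2: float
) -> np.ndarray:
    """Cluster-robust (by subject) sandwich covariance of the fixed effects.

    Uses the GLS weights implied by the fitted random-intercept structure
    (residual variance ``sigma2``, intercept variance ``tau2``); with ``tau2``
    at the zero boundary this reduces to the clustered OLS sandwich.
    """
    A = np.zeros((X.shape[1], X.shape[1]))
    B = np.zeros_like(A)
    for s in np.unique(subjects):
        sel = subjects == s
        Xi, ri = X[sel], resid[sel]
        ni = Xi.shape[0]
        # Sherman-Morrison inverse of sigma2*I + tau2*J
        Wi = (np.eye(ni) - (tau2 / (sigma2 + ni * tau2)) * np.ones((ni, ni))) / sigma2
        XtW = Xi.T @ Wi
        A += XtW @ Xi
        u = XtW @ ri
        B += np.outer(u, u)
    Ainv = np.linalg.inv(A)
    return Ainv @ B @ Ainv


def fit_group_state_model(
    metrics: pd.DataFrame,
    design: pd.DataFrame,
    metric_name: str,
    covariates=_DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Mixed model ``value ~ group*state + covariates`` with a per-subject
    random intercept; returns the per-state group contrast table.

    The contrast is control minus patient, so a positive estimate means the
    metric is lower in patients.  Contrast standard errors use a
    cluster-robust (by subject) sandwich covariance so that per-state
    contrasts stay calibrated when residual variance or covariate slopes
    differ between states; p-values use a t reference with
    (number of subjects - 1) degrees of freedom.  Missing metric cells are
    dropped.  If the variance estimate fails to converge the model falls back
    to an OLS fit (a zero-variance random intercept), flagged in the log.
    """
    df = metrics.loc[metrics["metric"] == metric_name].copy()
    df = df.merge(design, on="subject", how="left", suffixes=("", "_design"))
    covs = [c for c in covariates if c in df.columns]
    df = df.dropna(subset=["value"] + covs).reset_index(drop=True)
    if df["group"].nunique() < 2:
        raise ValueError("need both groups")
    formula = "value ~ C(group, Treatment('patient')) * C(cap)"
    for c in covs:
        formula += f" + C({c})" if df[c].dtype == object else f" + {c}"
    fallback = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = smf.mixedlm(formula, df, groups=df["subject"])
            res = model.fit(reml=True)
            params = res.fe_params
            exog = model.exog
            sigma2 = float(res.scale)
            tau2 = float(res.cov_re.iloc[0, 0])
            if not np.all(np.isfinite(params.values)):
                raise ValueError("non-finite estimates")
        except Exception:
            fallback = True
        if fallback:
            log.warning("mixed model did not converge; falling back to OLS fit")
            ols_model = smf.ols(formula, df)
            res = ols_model.fit()
            params = res.params
            exog = ols_model.exog
            sigma2 = float(res.scale)
            tau2 = 0.0
    resid = df["value"].values - exog @ params.values
    subjects = df["subject"].values
    cov = _cluster_robust_cov(exog, resid, subjects, sigma2, max(tau2, 0.0))
    dof = len(np.unique(subjects)) - 1
    from scipy.stats import t as t_dist

    rows = []
    caps = sorted(df["cap"].unique())
    for cap in caps:
        c = _contrast_vector(list(params.index), cap)
        est = float(c @ params.values)
        se = float(np.sqrt(c @ cov @ c))
        tval = est / se if se > 0 else np.nan
        p = 2.0 * (1.0 - t_dist.cdf(abs(tval), dof))
        rows.append(
            {
                "metric": metric_name,
                "cap": cap,
                "estimate": est,
                "se": se,
                "p": p,
                "converged": not fallback,
            }
        )
    return pd.DataFrame(rows)


def group_state_contrasts(
    metrics: pd.DataFrame,
    design: pd.DataFrame,
    metric_names=("duration", "entries", "occurrence"),
    covariates=_DEFAULT_COVARIATES,
    fdr_family: str = "pooled",
) -> pd.DataFrame:
    """Fit the three metric models and pool their post-hoc contrasts into one
    FDR family (default) or adjust within each model (``fdr_family='model'``).
    Cohen's d is computed from the covariate-residualized per-state values.
    """
    tables = [
        fit_group_state_model(metrics, design, m, covariates) for m in metric_names
    ]
    out = pd.concat(tables, ignore_index=True)
    if fdr_family == "pooled":
        out["p_fdr"] = benjamini_hochberg(out["p"].values)
    elif fdr_family == "model":
        out["p_fdr"] = np.nan
        for m in metric_names:
            sel = out["metric"] == m
            out.loc[sel, "p_fdr"] = benjamini_hochberg(out.loc[sel, "p"].values)
    else:
        raise ValueError("fdr_family must be 'pooled' or 'model'")
    # effect sizes on residualized values
    ds = []
    for _, row in out.iterrows():
        df = metrics[(metrics["metric"] == row["metric"]) & (metrics["cap"] == row["cap"])]
        df = df.merge(design, on="subject", how="left", suffixes=("", "_design"))
        covs = [c for c in covariates if c in df.columns]
        df = df.dropna(subset=["value"] + covs)
        C = pd.get_dummies(df[covs], drop_first=True).astype(float).values if covs else None
        resid = residualize(df["value"].values, C)
        ds.append(cohens_d(resid[df["group"] == "control"], resid[df["group"] == "patient"]))
    out["cohens_d"] = ds
    return out


# ---------------------------------------------------------------------------
# partial least squares correlation


@dataclass
class PlscResult:
    """Point estimates (and optionally inference) of a group-blocked PLSC."""

    singular_values: np.ndarray  # descending, >= 0
    behaviour_saliences: np.ndarray  # (G * n_behaviour, n_components), unit-norm cols
    brain_saliences: np.ndarray  # (n_brain, n_components), unit-norm cols
    groups: list[str]
    behaviour_names: list[str] = field(default_factory=list)
    brain_names: list[str] = field(default_factory=list)
    component_p: np.ndarray | None = None
    bootstrap_intervals: dict | None = None
    stable_flags: dict | None = None


def _zscore_within_group(M: np.ndarray, groups: np.ndarray) -> np.ndarray:
    Z = np.empty_like(M, dtype=float)
    for g in np.unique(groups):
        sel = groups == g
        mu = M[sel].mean(axis=0)
        sd = M[sel].std(axis=0, ddof=1)
        if np.any(sd == 0):
            j = int(np.nonzero(sd == 0)[0][0])
            raise ValueError(f"zero-variance column {j} in group {g}")
        Z[sel] = (M[sel] - mu) / sd
    return Z


def _stacked_correlation(
    Xz: np.ndarray, Yz: np.ndarray, groups: np.ndarray, group_order: list
) -> np.ndarray:
    blocks = []
    for g in group_order:
        sel = groups == g
        n = int(sel.sum())
        blocks.append(Xz[sel].T @ Yz[sel] / (n - 1))
    return np.vstack(blocks)


def _svd_with_sign(R: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    U, S, Vt = np.linalg.svd(R, full_matrices=False)
    V = Vt.T
    for i in range(S.size):
        nz = np.nonzero(np.abs(U[:, i]) > 1e-12)[0]
        if nz.size and U[nz[0], i] < 0:
            U[:, i] *= -1
            V[:, i] *= -1
    return U, S, V


def plsc_fit(
    behaviour: np.ndarray,
    brain: np.ndarray,
    group_labels,
    behaviour_names: list[str] | None = None,
    brain_names: list[str] | None = None,
) -> PlscResult:
    """Group-blocked PLSC point estimates.

    Columns are z-scored within group; the per-group behaviour-by-brain
    correlation blocks are stacked and decomposed by SVD.  Behaviour saliences
    are group-blocked (one block of rows per group); all saliences are
    unit-norm columns.  With standardized data the saliences read like
    correlation coefficients.
    """
    X = np.asarray(behaviour, dtype=float)
    Y = np.asarray(brain, dtype=float)
    groups = np.asarray(group_labels)
    if X.ndim == 1:
        X = X[:, None]
    if Y.ndim == 1:
        Y = Y[:, None]
    if np.isnan(X).any() or np.isnan(Y).any():
        raise ValueError("PLSC inputs must not contain missing cells")
    group_order = sorted(pd.unique(groups))
    for g in group_order:
        if int(np.sum(groups == g)) < 3:
            raise ValueError("need at least 3 subjects per group")
    Xz = _zscore_within_group(X, groups)
    Yz = _zscore_within_group(Y, groups)
    R = _stacked_correlation(Xz, Yz, groups, group_order)
    U, S, V = _svd_with_sign(R)
    return PlscResult(
        singular_values=S,
        behaviour_saliences=U,
        brain_saliences=V,
        groups=list(group_order),
        behaviour_names=behaviour_names or [],
        brain_names=brain_names or [],
    )


def plsc_permutation_test(
    behaviour: np.ndarray,
    brain: np.ndarray,
    group_labels,
    n_permutations: int = 2000,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Permutation p-values per PLSC component.

    Behaviour rows are permuted within group, keeping the group-blocked
    structure; p = (1 + #{permuted singular value >= observed}) / (n + 1).
    """
    rng = np.random.default_rng(rng)
    X = np.atleast_2d(np.asarray(behaviour, dtype=float).T).T
    Y = np.atleast_2d(np.asarray(brain, dtype=float).T).T
    groups = np.asarray(group_labels)
    group_order = sorted(pd.unique(groups))
    Xz = _zscore_within_group(X, groups)
    Yz = _zscore_within_group(Y, groups)
    obs = np.linalg.svd(
        _stacked_correlation(Xz, Yz, groups, group_order), compute_uv=False
    )
    counts = np.zeros_like(obs)
    sels = [np.nonzero(groups == g)[0] for g in group_order]
    Xp = Xz.copy()
    for _ in range(n_permutations):
        for sel in sels:
            Xp[sel] = Xz[sel[rng.permutation(sel.size)]]
        s = np.linalg.svd(
            _stacked_correlation(Xp, Yz, groups, group_order), compute_uv=False
        )
        counts += s >= obs
    return (1.0 + counts) / (n_permutations + 1.0)


def plsc_bootstrap(
    behaviour: np.ndarray,
    brain: np.ndarray,
    group_labels,
    n_boot: int = 500,
    rng: np.random.Generator | int | None = None,
    interval: tuple[float, float] = (5.0, 95.0),
) -> tuple[dict, dict]:
    """Bootstrap salience intervals and stability flags.

    Subjects are resampled with replacement within group; each resample's
    saliences are sign-aligned to the original solution before the 5th-95th
    percentile interval is formed.  A salience is stable when its interval
    excludes zero.
    """
    rng = np.random.default_rng(rng)
    X = np.atleast_2d(np.asarray(behaviour, dtype=float).T).T
    Y = np.atleast_2d(np.asarray(brain, dtype=float).T).T
    groups = np.asarray(group_labels)
    base = plsc_fit(X, Y, groups)
    ref = np.vstack([base.behaviour_saliences, base.brain_saliences])
    sels = [np.nonzero(groups == g)[0] for g in base.groups]
    U_draws = np.empty((n_boot, *base.behaviour_saliences.shape))
    V_draws = np.empty((n_boot, *base.brain_saliences.shape))
    for b in range(n_boot):
        for attempt in range(10):
            idx = np.concatenate([sel[rng.integers(0, sel.size, sel.size)] for sel in sels])
            try:
                fit = plsc_fit(X[idx], Y[idx], groups[idx])
                break
            except ValueError:
                continue
        else:
            log.warning("bootstrap resample %d kept a zero-variance column; NA draw", b)
            U_draws[b] = np.nan
            V_draws[b] = np.nan
            continue
        cat = np.vstack([fit.behaviour_saliences, fit.brain_saliences])
        for i in range(cat.shape[1]):
            if np.dot(cat[:, i], ref[:, i]) < 0:
                cat[:, i] *= -1
        U_draws[b] = cat[: base.behaviour_saliences.shape[0]]
        V_draws[b] = cat[base.behaviour_saliences.shape[0] :]
    lo, hi = interval
    intervals = {
        "behaviour": np.stack(
            [np.nanpercentile(U_draws, lo, axis=0), np.nanpercentile(U_draws, hi, axis=0)]
        ),
        "brain": np.stack(
            [np.nanpercentile(V_draws, lo, axis=0), np.nanpercentile(V_draws, hi, axis=0)]
        ),
    }
    stable = {
        side: (intervals[side][0] > 0) | (intervals[side][1] < 0)
        for side in ("behaviour", "brain")
    }
    return intervals, stable
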