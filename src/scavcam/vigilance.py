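"""Per-image vigilance observations and the mixed-effects logistic model.

Each classifiable image of the focal species becomes one Bernoulli
observation (vigilant = 1; feeding or other non-vigilant = 0) joined to its
covariates: days since 1 January, daily snow depth (cm), and a four-level
factor indexing previous site use by the other species within the same
winter:

    NO_USE       no heterospecific image at the site earlier that winter
    USED_GT_24H  used earlier that winter, but not in the past 24 h
    LOW_LT_24H   heterospecific image count in the past 24 h <= median
    HIGH_LT_24H  heterospecific image count in the past 24 h  > median

The median splitting LOW from HIGH is computed once per focal-species
model, pooled over sites and winters, from the observations that had at
least one heterospecific detection in the prior 24 h; ties go to LOW.
Classification is strictly causal: only detections before the observation
instant are counted.

The model is a logistic regression with a Gaussian random intercept for
survey winter,

    logit P(vigilant) = b0 + b1*days + b2*snow + b3*HIGH + b4*LOW
                        + b5*USED_GT_24H + u_year,   u_year ~ N(0, s^2),

fitted by Laplace-approximated maximum likelihood (per-winter posterior
modes by Newton, quasi-Newton search over fixed effects and log s).
Inference on the fixed effects is Wald (Z, p) from the numerical Hessian.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, xlog1py, xlogy
from statsmodels.tools.numdiff import approx_hess

from .core_io import Behavior, filter_after_analysis_start

PREDICTORS = ["intercept", "days_since_jan1", "snow_cm", "high_lt_24h", "low_lt_24h", "used_gt_24h"]


class UseClass(str, enum.Enum):
    NO_USE = "no_use"
    USED_GT_24H = "used_gt_24h"
    LOW_LT_24H = "low_lt_24h"
    HIGH_LT_24H = "high_lt_24h"


class ConvergenceError(RuntimeError):
    """GLMM fit failed; carries diagnostics and suggests the fixed-effect-year fallback."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message + " (consider refitting with winter as a fixed effect)")
        self.diagnostics = diagnostics or {}
        self.fixed_effect_year_fallback = True


class EmptyMedianError(ValueError):
    """No observation had heterospecific use in the prior window; collapse LOW/HIGH."""


def classify_use(
    obs_time: np.datetime64,
    het_times: np.ndarray,
    window_h: float = 24.0,
    median_threshold: float = 0.0,
) -> UseClass:
    """Use class of one observation given sorted heterospecific detection times.

    ``het_times`` must be restricted to the same site and winter; only
    detections strictly before ``obs_time`` count (an image at the exact
    instant of the first heterospecific detection is still NO_USE).
    """
    het_times = np.asarray(het_times, dtype="datetime64[s]")
    t = np.datetime64(obs_time, "s")
    n_prior = int(np.searchsorted(het_times, t, side="left"))
    if n_prior == 0:
        return UseClass.NO_USE
    lo = np.searchsorted(het_times, t - np.timedelta64(int(window_h * 3600), "s"), side="left")
    n_window = n_prior - int(lo)
    if n_window == 0:
        return UseClass.USED_GT_24H
    return UseClass.LOW_LT_24H if n_window <= median_threshold else UseClass.HIGH_LT_24H


def compute_median_threshold(window_counts: np.ndarray) -> float:
    """Median of the within-window heterospecific image counts (pooled).

    ``window_counts`` are the counts for observations that had at least one
    heterospecific detection in the prior window.  Raises
    :class:`EmptyMedianError` when the compilation is empty.
    """
    counts = np.asarray(window_counts)
    counts = counts[counts >= 1]
    if counts.size == 0:
        raise EmptyMedianError(
            "no observation has heterospecific use within the window; collapse LOW/HIGH into one class"
        )
    return float(np.median(counts))


def build_observations(
    detections: pd.DataFrame,
    focal_species: str,
    other_species: str,
    analysis_start: str = "01-22",
    window_h: float = 24.0,
    median_threshold: float | None = None,
    per_individual: bool = False,
) -> tuple[pd.DataFrame, float | None]:
    """Assemble the vigilance observation table for one focal species.

    ``detections`` must carry a ``depth_cm`` column (see ``core_io.join_snow``).
    Unclassifiable images are excluded from the observations but *all*
    heterospecific detections (any behavior) count toward site-use history.
    Observations dated on or before ``analysis_start`` are dropped.  When
    ``median_threshold`` is None it is computed from the data (pooled over
    sites and winters); pass a value to override.  With ``per_individual``
    each image contributes ``n_individuals`` Bernoulli rows instead of one.

    Returns ``(observations, median_threshold_used)``; the threshold is
    None when every observation is NO_USE/USED_GT_24H.
    """
    if "depth_cm" not in detections.columns:
        raise KeyError("detections must be annotated with snow depth (join_snow) first")
    focal = detections[detections["species"] == focal_species]
    focal = focal[focal["behavior"] != Behavior.UNCLASSIFIABLE.value]
    focal = filter_after_analysis_start(focal, analysis_start)
    het = detections[detections["species"] == other_species]

    ts = pd.to_datetime(focal["timestamp"])
    window = np.timedelta64(int(window_h * 3600), "s")
    n_prior = np.zeros(len(focal), dtype=int)
    n_window = np.zeros(len(focal), dtype=int)
    for (site, year), idx in focal.groupby(["site_id", "year_label"], sort=False).groups.items():
        h = het[(het["site_id"] == site) & (het["year_label"] == year)]
        h_times = np.sort(pd.to_datetime(h["timestamp"]).to_numpy().astype("datetime64[s]"))
        t = ts.loc[idx].to_numpy().astype("datetime64[s]")
        pos = focal.index.get_indexer(idx)
        n_prior[pos] = np.searchsorted(h_times, t, side="left")
        n_window[pos] = n_prior[pos] - np.searchsorted(h_times, t - window, side="left")

    if median_threshold is None:
        try:
            median_threshold = compute_median_threshold(n_window)
        except EmptyMedianError:
            median_threshold = None

    use_class = np.where(
        n_prior == 0,
        UseClass.NO_USE.value,
        np.where(
            n_window == 0,
            UseClass.USED_GT_24H.value,
            np.where(
                n_window <= (median_threshold if median_threshold is not None else np.inf),
                UseClass.LOW_LT_24H.value,
                UseClass.HIGH_LT_24H.value,
            ),
        ),
    )

    obs = pd.DataFrame(
        {
            "image_id": focal["image_id"].values,
            "vigilant": (focal["behavior"] == Behavior.VIGILANT.value).astype(int).values,
            "species": focal_species,
            "site_id": focal["site_id"].values,
            "year_label": focal["year_label"].values,
            "days_since_jan1": (ts - pd.to_datetime(ts.dt.year.astype(str) + "-01-01")).dt.days.values,
            "snow_cm": focal["depth_cm"].values,
            "use_class": use_class,
            "n_individuals": focal["n_individuals"].values,
        }
    )
    if per_individual:
        obs = obs.loc[obs.index.repeat(obs["n_individuals"])].reset_index(drop=True)
    return obs.reset_index(drop=True), median_threshold


@dataclass
class VigilanceFit:
    """Result of the random-intercept logistic fit, Table-1 shaped."""

    table: pd.DataFrame  # predictor, beta, se, z, p, n_images
    sigma_year: float
    cov_fixed: np.ndarray
    predictors: list[str]
    loglik: float
    n_obs: int
    converged: bool
    dropped_levels: list[str] = field(default_factory=list)
    random_effects: dict[str, float] = field(default_factory=dict)
    day_ref: float = 0.0
    snow_ref: float = 0.0

    @property
    def beta(self) -> np.ndarray:
        return self.table["beta"].to_numpy()


def _design(obs: pd.DataFrame, day_ref: float, snow_ref: float) -> tuple[np.ndarray, list[str], list[str]]:
    cols = [np.ones(len(obs)), obs["days_since_jan1"].to_numpy(float) - day_ref, obs["snow_cm"].to_numpy(float) - snow_ref]
    names = ["intercept", "days_since_jan1", "snow_cm"]
    dropped = []
    levels = [
        ("high_lt_24h", UseClass.HIGH_LT_24H.value),
        ("low_lt_24h", UseClass.LOW_LT_24H.value),
        ("used_gt_24h", UseClass.USED_GT_24H.value),
    ]
    if (obs["use_class"] == UseClass.NO_USE.value).sum() == 0:
        # empty baseline class: fold the stalest-use level into the
        # intercept instead so the design stays full rank
        dropped.append("no_use (empty; baseline is used_gt_24h)")
        levels = levels[:2]
    for name, level in levels:
        dummy = (obs["use_class"] == level).to_numpy(float)
        if dummy.sum() == 0:
            dropped.append(name)
        else:
            cols.append(dummy)
            names.append(name)
    return np.column_stack(cols), names, dropped


def _laplace_loglik(
    beta: np.ndarray, log_sigma: float, X: np.ndarray, y: np.ndarray, group_slices: list[slice]
) -> tuple[float, np.ndarray]:
    """Laplace-approximated marginal log-likelihood and per-group modes."""
    sigma2 = np.exp(2.0 * log_sigma)
    eta0 = X @ beta
    total = 0.0
    modes = np.zeros(len(group_slices))
    for g, sl in enumerate(group_slices):
        e = eta0[sl]
        yg = y[sl]
        u = 0.0
        for _ in range(50):  # Newton for the conditional mode
            p = expit(e + u)
            grad = np.sum(yg - p) - u / sigma2
            hess = -np.sum(p * (1.0 - p)) - 1.0 / sigma2
            step = grad / hess
            u -= step
            if abs(step) < 1e-10:
                break
        p = expit(e + u)
        ll_cond = float(np.sum(xlogy(yg, p) + xlog1py(1.0 - yg, -p)))
        neg_f2 = np.sum(p * (1.0 - p)) + 1.0 / sigma2
        # log integral of exp(f): Laplace around the mode
        total += (
            ll_cond
            - 0.5 * u * u / sigma2
            - 0.5 * np.log(sigma2)
            - 0.5 * np.log(neg_f2)
        )
        modes[g] = u
    return total, modes


def fit_vigilance_model(
    obs: pd.DataFrame,
    day_ref: float = 0.0,
    snow_ref: float = 0.0,
) -> VigilanceFit:
    """Fit the random-intercept (winter) logistic vigilance model.

    ``day_ref``/``snow_ref`` are subtracted from the continuous covariates
    before fitting (0 = raw scale); slopes and contrasts are invariant to
    this choice, only the intercept shifts.  Requires >= 2 winter levels.
    Use-class levels absent from the data are dropped from the design and
    recorded in ``dropped_levels``.  Non-convergence or separation raises
    :class:`ConvergenceError`.
    """
    groups = obs["year_label"].to_numpy()
    levels = sorted(pd.unique(groups))
    if len(levels) < 2:
        raise ConvergenceError("need at least 2 winter levels for a year random effect", {"levels": levels})
    y = obs["vigilant"].to_numpy(float)
    if y.min() == y.max():
        raise ConvergenceError("response is constant: complete separation", {"mean_response": float(y.mean())})

    order = np.argsort(groups, kind="mergesort")
    obs_sorted = obs.iloc[order].reset_index(drop=True)
    X, names, dropped = _design(obs_sorted, day_ref, snow_ref)
    y = y[order]
    gs = obs_sorted["year_label"].to_numpy()
    group_slices = []
    start = 0
    for lev in levels:
        n = int(np.sum(gs == lev))
        group_slices.append(slice(start, start + n))
        start += n

    # warm start from the plain (no random effect) logistic fit
    import statsmodels.api as sm

    try:
        start_beta = sm.Logit(y, X).fit(disp=0, maxiter=200).params
    except Exception:
        start_beta = np.zeros(X.shape[1])
    theta0 = np.append(start_beta, np.log(0.2))

    def negll(theta: np.ndarray) -> float:
        ll, _ = _laplace_loglik(theta[:-1], theta[-1], X, y, group_slices)
        if not np.isfinite(ll):
            return 1e12  # keep the optimizer and numerical Hessian in-range
        return -ll

    res = optimize.minimize(
        negll,
        theta0,
        method="L-BFGS-B",
        bounds=[(None, None)] * X.shape[1] + [(-8.0, 3.0)],
        options={"maxiter": 500, "ftol": 1e-11},
    )
    theta = res.x
    if not res.success and res.fun > negll(theta0) - 1e-9:
        raise ConvergenceError("GLMM optimizer failed", {"message": str(res.message), "nit": int(res.nit)})
    if np.abs(theta[:-1]).max() > 30:
        raise ConvergenceError("diverging coefficients: likely separation", {"beta": theta[:-1].tolist()})

    H = approx_hess(theta, negll)
    k = X.shape[1]
    try:
        cov_all = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        raise ConvergenceError("singular Hessian at the optimum", {"hessian_diag": np.diag(H).tolist()})
    cov_fixed = cov_all[:k, :k]
    se = np.sqrt(np.clip(np.diag(cov_fixed), 0, None))
    beta = theta[:k]
    sigma = float(np.exp(theta[-1]))
    from scipy.stats import norm

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.nan)
    p = 2.0 * norm.sf(np.abs(z))

    class_counts = obs["use_class"].value_counts()
    n_images = []
    for name in names:
        if name == "intercept":
            n_images.append(int(class_counts.get(UseClass.NO_USE.value, 0)))
        elif name in ("days_since_jan1", "snow_cm"):
            n_images.append(None)
        else:
            n_images.append(int(class_counts.get(name, 0)))

    ll, modes = _laplace_loglik(beta, theta[-1], X, y, group_slices)
    table = pd.DataFrame({"predictor": names, "beta": beta, "se": se, "z": z, "p": p, "n_images": n_images})
    return VigilanceFit(
        table=table,
        sigma_year=sigma,
        cov_fixed=cov_fixed,
        predictors=names,
        loglik=float(ll),
        n_obs=len(obs),
        converged=bool(res.success),
        dropped_levels=dropped,
        random_effects={lev: float(m) for lev, m in zip(levels, modes)},
        day_ref=day_ref,
        snow_ref=snow_ref,
    )


def predict_vigilance(
    fit: VigilanceFit,
    days_since_jan1: float,
    snow_cm: float,
    use_class: UseClass | str = UseClass.NO_USE,
    conf: float = 0.95,
) -> tuple[float, float, float]:
    """Probability of vigilance at a covariate setting, random effect at 0.

    The CI is delta-method on the logit scale (Wald on the linear
    predictor, then inverse-logit transformed).  Raises ``KeyError`` for a
    use class that was dropped from the fitted design.
    """
    use_class = UseClass(use_class)
    contrast = {
        UseClass.NO_USE: None,
        UseClass.HIGH_LT_24H: "high_lt_24h",
        UseClass.LOW_LT_24H: "low_lt_24h",
        UseClass.USED_GT_24H: "used_gt_24h",
    }[use_class]
    if contrast is not None and contrast not in fit.predictors:
        raise KeyError(f"use class level {use_class.value} was not in the fitted design")
    c = np.zeros(len(fit.predictors))
    c[fit.predictors.index("intercept")] = 1.0
    c[fit.predictors.index("days_since_jan1")] = days_since_jan1 - fit.day_ref
    c[fit.predictors.index("snow_cm")] = snow_cm - fit.snow_ref
    if contrast is not None:
        c[fit.predictors.index(contrast)] = 1.0
    eta = float(c @ fit.beta)
    var = float(c @ fit.cov_fixed @ c)
    from scipy.stats import norm

    zq = norm.ppf(0.5 + conf / 2.0)
    half = zq * np.sqrt(max(var, 0.0))
    return float(expit(eta)), float(expit(eta - half)), float(expit(eta + half))
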