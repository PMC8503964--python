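"""Statistical analysis of contrast-match records.

Three layers, mirroring the standard analysis of a two-condition contrast
matching experiment:

1. ``summarize`` — per (observer, condition, reference-contrast) mean and
   SD of the raw-scale matches.
2. ``fit_loglog`` — pooled ordinary least squares of ln(match) on
   ln(reference contrast), with full inference (SEs, t, 95% CIs, R^2,
   RMSE, F vs the constant model).  A control-condition slope near +1
   means veridical matching; an adaptation slope above +1 means the loss
   of apparent contrast grows as the reference contrast falls.
3. ``fit_lmm`` — a random-intercept linear mixed model fit by maximum
   likelihood to all trial-level log matches simultaneously:

       ln(match) ~ 1 + condition + ln(c) + condition:ln(c) + (1 | observer)

   Estimation profiles the variance ratio lambda = sigma_id^2/sigma_eps^2:
   for fixed lambda the GLS fixed effects and the residual variance have
   closed forms under the block compound-symmetric covariance
   V = sigma_eps^2 (I + lambda Z Z'), so the deviance reduces to a smooth
   1-D function of lambda minimized by bounded search.  The boundary
   sigma_id = 0 (where the model degenerates to OLS) is permitted and
   flagged.

All logarithms are natural.  Fixed-effect inference uses Student t with
residual degrees of freedom n - k; variance-component CIs are Wald
intervals on the log-SD scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
import statsmodels.api as sm

__all__ = [
    "RegressionFit",
    "MixedFit",
    "summarize",
    "pooled_points",
    "fit_loglog",
    "fit_lmm",
    "load_table3",
    "replicate_table2",
    "make_results_figure",
]

FIXED_EFFECT_NAMES = ["(Intercept)", "condition", "log_upper", "condition:log_upper"]


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records.copy()
    from .session import records_to_frame

    return records_to_frame(records)


def summarize(records) -> pd.DataFrame:
    """Per-key raw-scale match summary.

    Returns one row per (observer_id, condition, upper_contrast) with the
    mean, sample SD (n-1 denominator; 0 when n = 1) and count of the
    matched contrasts.  Practice trials are excluded.
    """
    df = _as_frame(records)
    if "is_practice" in df.columns:
        df = df[~df["is_practice"].astype(bool)]
    if df.empty:
        raise ValueError("no non-practice records to summarize")
    grouped = (
        df.groupby(["observer_id", "condition", "upper_contrast"])["matched_contrast"]
        .agg(mean_match="mean", sd_match="std", n="count")
        .reset_index()
    )
    grouped["sd_match"] = grouped["sd_match"].fillna(0.0)
    return grouped


def pooled_points(summary: pd.DataFrame, condition: str) -> tuple[np.ndarray, np.ndarray]:
    """Pool per-observer level means for one condition into (x, y) arrays."""
    sub = summary[summary["condition"] == condition]
    return sub["upper_contrast"].to_numpy(float), sub["mean_match"].to_numpy(float)


@dataclass(frozen=True)
class RegressionFit:
    """Simple linear model of ln(match) on ln(reference contrast)."""

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    slope_t: float
    intercept_t: float
    slope_p: float
    intercept_p: float
    r2: float
    adj_r2: float
    rmse: float
    f_stat: float
    f_p: float
    n_obs: int
    error_df: int

    def predict(self, c: np.ndarray) -> np.ndarray:
        """Fitted match on the raw contrast scale."""
        return np.exp(self.intercept + self.slope * np.log(np.asarray(c, float)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": [self.intercept, self.slope],
                "se": [self.intercept_se, self.slope_se],
                "ci_low": [self.intercept_ci[0], self.slope_ci[0]],
                "ci_high": [self.intercept_ci[1], self.slope_ci[1]],
                "t": [self.intercept_t, self.slope_t],
                "p": [self.intercept_p, self.slope_p],
            },
            index=["Intercept", "log(upperContrast)"],
        )


def fit_loglog(upper, matched=None, *, base: float = math.e) -> RegressionFit:
    """Pooled log-log OLS with full inference.

    Accepts either two positive arrays ``(upper, matched)`` or a single
    iterable of (upper, matched) pairs.  ``base`` changes the logarithm
    applied to both axes; the slope and R^2 are base-invariant, the
    intercept scales by ln(base_old)/ln(base_new).
    """
    if matched is None:
        pts = np.asarray(list(upper), dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be (upper, matched) pairs")
        upper, matched = pts[:, 0], pts[:, 1]
    x = np.asarray(upper, dtype=float)
    y = np.asarray(matched, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("upper and matched must be equal-length 1-D arrays")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("all contrasts must be positive for a log-log fit")
    lx = np.log(x) / math.log(base)
    ly = np.log(y) / math.log(base)
    if np.ptp(lx) == 0:
        raise ValueError("degenerate design: all reference contrasts equal")

    model = sm.OLS(ly, sm.add_constant(lx)).fit()
    ci = model.conf_int(alpha=0.05)
    return RegressionFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        slope_se=float(model.bse[1]),
        intercept_se=float(model.bse[0]),
        slope_ci=(float(ci[1, 0]), float(ci[1, 1])),
        intercept_ci=(float(ci[0, 0]), float(ci[0, 1])),
        slope_t=float(model.tvalues[1]),
        intercept_t=float(model.tvalues[0]),
        slope_p=float(model.pvalues[1]),
        intercept_p=float(model.pvalues[0]),
        r2=float(model.rsquared),
        adj_r2=float(model.rsquared_adj),
        rmse=float(np.sqrt(model.mse_resid)),
        f_stat=float(model.fvalue),
        f_p=float(model.f_pvalue),
        n_obs=int(model.nobs),
        error_df=int(model.df_resid),
    )


# ---------------------------------------------------------------------------
# random-intercept linear mixed model, profiled maximum likelihood


def _profile_nll(lam: float, X, y, starts, sizes):
    """Negative log-likelihood at variance ratio ``lam``, with the fixed
    effects and residual variance concentrated out.

    Per group g of size n_g the inverse correlation is
    (I + lam J)^-1 = I - lam/(1 + lam n_g) J  (Woodbury), so all weighted
    cross-products reduce to per-group sums.
    """
    n = len(y)
    c = lam / (1.0 + lam * sizes)
    Sx = np.add.reduceat(X, starts, axis=0)
    Sy = np.add.reduceat(y, starts)
    XtWX = X.T @ X - (Sx * c[:, None]).T @ Sx
    XtWy = X.T @ y - Sx.T @ (c * Sy)
    ytWy = y @ y - c @ Sy**2
    beta = np.linalg.solve(XtWX, XtWy)
    rss = float(ytWy - beta @ XtWy)
    sigma2 = rss / n
    logdet = float(np.sum(np.log1p(lam * sizes)))
    nll = 0.5 * (n * (math.log(2.0 * math.pi * sigma2) + 1.0) + logdet)
    return nll, beta, sigma2, XtWX


@dataclass(frozen=True)
class MixedFit:
    """Random-intercept LMM fit: fixed-effect table plus variance components
    and information criteria."""

    fixed: pd.DataFrame  # estimate, se, ci_low, ci_high, t, df, p
    sigma_id: float
    sigma_id_ci: tuple[float, float]
    sigma_eps: float
    sigma_eps_ci: tuple[float, float]
    loglik: float
    deviance: float
    aic: float
    bic: float
    n_obs: int
    n_groups: int
    n_dropped: int
    boundary: bool
    lam: float

    @property
    def k_params(self) -> int:
        return len(self.fixed) + 2

    def __str__(self) -> str:  # pragma: no cover - formatting only
        lines = [
            f"Random-intercept LMM (ML), n={self.n_obs}, groups={self.n_groups}",
            f"AIC {self.aic:.2f}  BIC {self.bic:.2f}  logLik {self.loglik:.2f}  "
            f"deviance {self.deviance:.2f}",
            self.fixed.to_string(float_format=lambda v: f"{v:.5g}"),
            f"Random effect SD (observer): {self.sigma_id:.4f} "
            f"CI [{self.sigma_id_ci[0]:.4f}, {self.sigma_id_ci[1]:.4f}]"
            + ("  [boundary]" if self.boundary else ""),
            f"Residual SD: {self.sigma_eps:.4f} "
            f"CI [{self.sigma_eps_ci[0]:.4f}, {self.sigma_eps_ci[1]:.4f}]",
        ]
        return "\n".join(lines)


def _lmm_design(df: pd.DataFrame):
    is_adapt = (df["condition"] == "adaptation").to_numpy(float)
    lc = np.log(df["upper_contrast"].to_numpy(float))
    X = np.column_stack([np.ones(len(df)), is_adapt, lc, is_adapt * lc])
    y = np.log(df["matched_contrast"].to_numpy(float))
    return X, y


def fit_lmm(records, lam_bounds: tuple[float, float] = (1e-9, 150.0)) -> MixedFit:
    """Fit the random-intercept log-log matching model by profiled ML.

    Trial-level records (practice excluded, zero matches dropped with a
    warning) are modeled as

        ln(match)_ij = b0 + b1 ln(c_ij) + [b2 + b3 ln(c_ij)] A_ij + u_i + e_ij

    with observer intercepts u_i ~ N(0, sigma_id^2) and residuals
    e_ij ~ N(0, sigma_eps^2).  ``A`` is the adaptation indicator.
    """
    df = _as_frame(records)
    if "is_practice" in df.columns:
        df = df[~df["is_practice"].astype(bool)]
    n_dropped = int((df["matched_contrast"] <= 0).sum())
    if n_dropped:
        warnings.warn(
            f"excluding {n_dropped} non-positive matched contrasts from the log-scale fit",
            stacklevel=2,
        )
        df = df[df["matched_contrast"] > 0]
    if df["observer_id"].nunique() < 2:
        raise ValueError("need at least 2 observers for a random-intercept model")
    if len(df) < 10:
        raise ValueError("need at least 10 records")

    df = df.sort_values("observer_id", kind="stable").reset_index(drop=True)
    X, y = _lmm_design(df)
    groups = df["observer_id"].to_numpy()
    starts = np.flatnonzero(np.r_[True, groups[1:] != groups[:-1]])
    sizes = np.diff(np.r_[starts, len(groups)]).astype(float)
    n, k = X.shape

    def nll_of_log_lam(u: float) -> float:
        return _profile_nll(math.exp(u), X, y, starts, sizes)[0]

    res = scipy.optimize.minimize_scalar(
        nll_of_log_lam,
        bounds=(math.log(lam_bounds[0]), math.log(lam_bounds[1])),
        method="bounded",
        options={"xatol": 1e-10},
    )
    if not res.success:
        raise RuntimeError(f"profile-likelihood search failed: {res.message}")
    lam = math.exp(res.x)
    nll_opt, beta, sigma2, XtWX = _profile_nll(lam, X, y, starts, sizes)
    nll0, beta0, sigma2_0, XtWX0 = _profile_nll(0.0, X, y, starts, sizes)
    boundary = nll0 <= nll_opt + 1e-10
    if boundary:
        lam, nll_opt, beta, sigma2, XtWX = 0.0, nll0, beta0, sigma2_0, XtWX0

    sigma_eps = math.sqrt(sigma2)
    sigma_id = math.sqrt(lam * sigma2)

    # fixed-effect inference: t with residual df
    cov = sigma2 * np.linalg.inv(XtWX)
    se = np.sqrt(np.diag(cov))
    df_resid = n - k
    tval = beta / se
    pval = 2.0 * scipy.stats.t.sf(np.abs(tval), df_resid)
    tcrit = scipy.stats.t.ppf(0.975, df_resid)
    fixed = pd.DataFrame(
        {
            "estimate": beta,
            "se": se,
            "ci_low": beta - tcrit * se,
            "ci_high": beta + tcrit * se,
            "t": tval,
            "df": df_resid,
            "p": pval,
        },
        index=FIXED_EFFECT_NAMES,
    )

    sigma_id_ci, sigma_eps_ci = _variance_wald_ci(
        X, y, starts, sizes, sigma_id, sigma_eps, boundary
    )

    loglik = -nll_opt
    deviance = 2.0 * nll_opt
    n_par = k + 2
    return MixedFit(
        fixed=fixed,
        sigma_id=sigma_id,
        sigma_id_ci=sigma_id_ci,
        sigma_eps=sigma_eps,
        sigma_eps_ci=sigma_eps_ci,
        loglik=loglik,
        deviance=deviance,
        aic=deviance + 2.0 * n_par,
        bic=deviance + math.log(n) * n_par,
        n_obs=n,
        n_groups=len(sizes),
        n_dropped=n_dropped,
        boundary=boundary,
        lam=lam,
    )


def _variance_wald_ci(X, y, starts, sizes, sigma_id, sigma_eps, boundary):
    """Wald 95% CIs for the two SDs, computed on the log-SD scale from a
    central-difference Hessian of the (beta-profiled) deviance.  At the
    sigma_id = 0 boundary the Wald interval is undefined and reported NaN."""
    n = len(y)

    def nll(theta):
        sid, seps = math.exp(theta[0]), math.exp(theta[1])
        lam = (sid / seps) ** 2
        c = lam / (1.0 + lam * sizes)
        Sx = np.add.reduceat(X, starts, axis=0)
        Sy = np.add.reduceat(y, starts)
        XtWX = X.T @ X - (Sx * c[:, None]).T @ Sx
        XtWy = X.T @ y - Sx.T @ (c * Sy)
        ytWy = y @ y - c @ Sy**2
        beta = np.linalg.solve(XtWX, XtWy)
        rss = float(ytWy - beta @ XtWy)
        logdet = float(np.sum(np.log1p(lam * sizes)))
        return 0.5 * (
            n * math.log(2.0 * math.pi * seps**2) + logdet + rss / seps**2
        )

    z = scipy.stats.norm.ppf(0.975)
    if boundary or sigma_id == 0.0:
        # one-parameter Hessian for the residual SD only
        t0 = math.log(sigma_eps)
        h = 1e-4

        def nll_e(te):
            rss = nll([-50.0, te])  # sigma_id ~ 0
            return rss

        hess = (nll_e(t0 + h) - 2.0 * nll_e(t0) + nll_e(t0 - h)) / h**2
        se_log = 1.0 / math.sqrt(hess) if hess > 0 else float("nan")
        eps_ci = (sigma_eps * math.exp(-z * se_log), sigma_eps * math.exp(z * se_log))
        return (float("nan"), float("nan")), eps_ci

    theta0 = np.array([math.log(sigma_id), math.log(sigma_eps)])
    h = 1e-4
    H = np.empty((2, 2))
    f0 = nll(theta0)
    for i in range(2):
        for j in range(i, 2):
            ei = np.eye(2)[i] * h
            ej = np.eye(2)[j] * h
            if i == j:
                H[i, i] = (nll(theta0 + ei) - 2.0 * f0 + nll(theta0 - ei)) / h**2
            else:
                H[i, j] = H[j, i] = (
                    nll(theta0 + ei + ej)
                    - nll(theta0 + ei - ej)
                    - nll(theta0 - ei + ej)
                    + nll(theta0 - ei - ej)
                ) / (4.0 * h**2)
    try:
        cov = np.linalg.inv(H)
        se_id, se_eps = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:  # pragma: no cover - pathological Hessian
        se_id = se_eps = float("nan")
    id_ci = (sigma_id * math.exp(-z * se_id), sigma_id * math.exp(z * se_id))
    eps_ci = (sigma_eps * math.exp(-z * se_eps), sigma_eps * math.exp(z * se_eps))
    return id_ci, eps_ci


# ---------------------------------------------------------------------------
# bundled two-observer summary dataset and its pooled regression


def load_table3() -> pd.DataFrame:
    """Bundled per-level match summary for the two replication observers.

    Columns: observer_id, condition, upper_contrast, mean_match, sd_match, n
    (mean/SD of 10 raw-scale matches per reference contrast and condition).
    """
    path = resources.files("contrastadapt") / "data" / "table3_matches.csv"
    with resources.as_file(path) as p:
        return pd.read_csv(p)


def replicate_table2() -> dict[str, RegressionFit]:
    """Pooled log-log fits of the bundled summary data, one per condition.

    Control pools 2 observers x 11 levels (22 points); adaptation pools
    2 x 6 (12 points).  Each point is the log of a raw-scale level mean.
    """
    table = load_table3()
    fits = {}
    for condition in ("control", "adaptation"):
        x, y = pooled_points(table, condition)
        fits[condition] = fit_loglog(x, y)
    return fits


def make_results_figure(
    summary: pd.DataFrame,
    fits: Mapping[str, RegressionFit],
    path,
):
    """Log-log scatter of per-level mean matches with the fitted lines.

    Control and adaptation are drawn in distinct markers/colors; the dashed
    diagonal marks veridical matching (match = reference).
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    styles = {
        "control": dict(color="black", marker="o", label="control"),
        "adaptation": dict(color="crimson", marker="^", label="adaptation"),
    }
    fig, ax = plt.subplots(figsize=(5.0, 5.0))
    lo, hi = np.inf, -np.inf
    for condition, style in styles.items():
        x, y = pooled_points(summary, condition)
        if len(x) == 0:
            continue
        lo, hi = min(lo, x.min(), y.min()), max(hi, x.max(), y.max())
        ax.plot(x, y, linestyle="none", fillstyle="none", **style)
        fit = fits.get(condition)
        if fit is not None:
            grid = np.geomspace(x.min(), x.max(), 50)
            ax.plot(grid, fit.predict(grid), color=style["color"], linewidth=1.2)
    if np.isfinite(lo):
        diag = np.geomspace(lo, hi, 2)
        ax.plot(diag, diag, color="gray", linestyle="--", linewidth=0.8)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("reference (upper) contrast")
    ax.set_ylabel("matched contrast")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return fig
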