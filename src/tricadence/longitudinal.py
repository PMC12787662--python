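"""Linear and penalized-smooth mixed models of cadence over a season.

Two Gaussian models of average cadence C for athlete i at week W:

    linear:     C_it = b0 + b1*W_it + b2*season_it + u0_i + u1_i*W_it + e_it
    non-linear: C_it = b0 + f(W_it) + b2*season_it + u0_i + u1_i*W_it + e_it

with u0_i ~ N(0, s_b0^2) random intercepts, u1_i ~ N(0, s_b1^2) random
slopes and e_it ~ N(0, s^2) residuals.  f is a thin-plate regression
spline; random effects are represented as ridge-penalized coefficient
blocks (random-effect smooths), so both models are penalized least-squares
problems whose smoothing parameters / variance-component precisions are
chosen by restricted maximum likelihood (REML).

The smooth carries a double penalty: its curvature penalty plus a separate
shrinkage penalty on the unpenalized linear null space, so the estimated
degrees of freedom of f can fall below 1 when the data carry no trend at
all.  Effective degrees of freedom are traces of the influence matrix;
AIC/BIC use the conditional log-likelihood with effective degrees of
freedom; nested models are compared with a likelihood-ratio statistic
referred to a chi-squared distribution (approximate near the variance
boundary).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .splines import TPRSBasis, tprs_basis

__all__ = [
    "DesignSpec",
    "GamFit",
    "ModelComparison",
    "PredictionCurve",
    "ks_normality",
    "fit_model",
    "model_criteria",
    "compare_models",
    "predict_curve",
    "weekly_percent_change",
]

_LOG_LAMBDA_BOUNDS = (-18.0, 22.0)
_STARTS = (0.0, 4.0, -4.0)  # three fixed multi-start offsets in log-lambda


class ConvergenceError(RuntimeError):
    """REML optimisation failed to produce a finite optimum."""


class RankDeficiencyError(ValueError):
    """Design singular after identifiability constraints."""


class IncomparableFitsError(ValueError):
    """Model comparison attempted across different datasets."""


class IllPosedCriteriaError(ValueError):
    """Information criteria undefined (n_obs <= effective df)."""


@dataclass(frozen=True)
class DesignSpec:
    """Model specification.

    ``model_type`` is ``"linear"`` or ``"nonlinear"``; ``k_basis`` the TPRS
    dimension (>= 3); ``random_effects`` any subset of
    ``("intercept", "slope")`` fitted per participant.  Season is coded with
    season 1 as reference and a season-2 offset (included only when both
    seasons occur in the data).
    """

    model_type: str = "nonlinear"
    k_basis: int = 10
    random_effects: tuple[str, ...] = ("intercept", "slope")

    def __post_init__(self) -> None:
        if self.model_type not in ("linear", "nonlinear"):
            raise ValueError(f"unknown model_type {self.model_type!r}")
        if self.k_basis < 3:
            raise ValueError("k_basis must be >= 3")
        if not set(self.random_effects) <= {"intercept", "slope"}:
            raise ValueError("random_effects must be a subset of {'intercept','slope'}")


@dataclass
class _Block:
    """One penalized coefficient block."""

    name: str
    sl: slice
    penalty: np.ndarray  # within-block penalty (identity for ridge blocks)
    rank: int
    logdet_plus: float  # pseudo log-determinant of `penalty`


@dataclass
class _ModelState:
    """Design, penalties and data needed to evaluate REML and predict."""

    y: np.ndarray
    B: np.ndarray
    fixed_names: list[str]
    blocks: list[_Block]
    participants: list[str]
    weeks: np.ndarray
    has_season: bool
    basis: TPRSBasis | None
    spec: DesignSpec
    data_hash: str
    BtB: np.ndarray = field(init=False)
    Bty: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.BtB = self.B.T @ self.B
        self.Bty = self.B.T @ self.y

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def p(self) -> int:
        return self.B.shape[1]

    def penalty_total(self, log_lambda: np.ndarray) -> np.ndarray:
        S = np.zeros((self.p, self.p))
        for lam, blk in zip(np.exp(log_lambda), self.blocks):
            S[blk.sl, blk.sl] += lam * blk.penalty
        return S

    def solve(self, log_lambda: np.ndarray):
        """Penalized normal-equation solve; returns (coef, chol, rss, pen)."""
        S = self.penalty_total(log_lambda)
        H = self.BtB + S
        try:
            c, low = linalg.cho_factor(H)
        except linalg.LinAlgError as exc:
            raise RankDeficiencyError("penalized design is singular") from exc
        coef = linalg.cho_solve((c, low), self.Bty)
        resid = self.y - self.B @ coef
        rss = float(resid @ resid)
        pen = float(coef @ (S @ coef))
        return coef, (c, low), rss, pen

    def reml(self, log_lambda: np.ndarray) -> float:
        """Negative restricted log-likelihood (profiled over sigma^2)."""
        ll = np.clip(log_lambda, *_LOG_LAMBDA_BOUNDS)
        try:
            _, (c, _), rss, pen = self.solve(ll)
        except RankDeficiencyError:
            return np.inf
        logdet_H = 2.0 * float(np.sum(np.log(np.diag(c))))
        logdet_S = sum(
            blk.rank * lam + blk.logdet_plus for lam, blk in zip(ll, self.blocks)
        )
        m_p = self.p - sum(blk.rank for blk in self.blocks)
        n_r = self.n - m_p
        if n_r <= 0 or rss + pen <= 0:
            return np.inf
        sigma2 = (rss + pen) / n_r
        lr = (
            -0.5 * n_r * (np.log(2.0 * np.pi * sigma2) + 1.0)
            + 0.5 * logdet_S
            - 0.5 * logdet_H
        )
        return -lr


@dataclass
class GamFit:
    """Fitted model state for one discipline's season of cadence data."""

    beta0: float
    beta1: float | None
    beta2: float | None
    smooth_coefs: np.ndarray | None
    b0: dict[str, float]
    b1: dict[str, float]
    var_b0: float | None
    var_b1: float | None
    var_eps: float
    lambdas: dict[str, float]
    edf_smooth: float
    edf_total: float
    edf_test: float
    loglik: float
    reml_score: float
    aic: float
    bic: float
    r2_adj: float
    se_beta: dict[str, float]
    n_obs: int
    rss: float
    tss: float
    boundary_warning: bool
    _state: _ModelState = field(repr=False)
    _coef: np.ndarray = field(repr=False)
    _cov: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        """JSON-serialisable summary of the fit."""
        return {
            "model_type": self._state.spec.model_type,
            "beta0": self.beta0,
            "beta1": self.beta1,
            "beta2": self.beta2,
            "var_b0": self.var_b0,
            "var_b1": self.var_b1,
            "var_eps": self.var_eps,
            "lambdas": self.lambdas,
            "edf_smooth": self.edf_smooth,
            "edf_total": self.edf_total,
            "edf_test": self.edf_test,
            "loglik": self.loglik,
            "reml_score": self.reml_score,
            "aic": self.aic,
            "bic": self.bic,
            "r2_adj": self.r2_adj,
            "n_obs": self.n_obs,
        }


@dataclass
class ModelComparison:
    """Linear vs non-linear verdict for one discipline."""

    D: float
    df: float
    p: float
    aic_linear: float
    aic_nonlinear: float
    bic_linear: float
    bic_nonlinear: float
    r2_linear: float
    r2_nonlinear: float
    boundary_warning: bool = True  # chi-squared reference approximate near variance boundary

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "D", "df", "p", "aic_linear", "aic_nonlinear",
            "bic_linear", "bic_nonlinear", "r2_linear", "r2_nonlinear",
            "boundary_warning",
        )}


@dataclass
class PredictionCurve:
    """Population (or individual-augmented) prediction over a week grid."""

    weeks: np.ndarray
    mean: np.ndarray
    lo95: np.ndarray
    hi95: np.ndarray
    individual: pd.DataFrame | None = None
    extrapolated: np.ndarray | None = None  # mask of grid points beyond the data


# ---------------------------------------------------------------------------
# Normality check
# ---------------------------------------------------------------------------


def ks_normality(values, n_mc: int = 2000, seed: int = 0) -> tuple[float, float]:
    """One-sample Kolmogorov–Smirnov test against a normal with estimated
    mean and SD; the p-value is Monte-Carlo calibrated (Lilliefors-style)
    to account for the estimated parameters.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant sample has no distribution to test")
    stat = stats.kstest(x, "norm", args=(x.mean(), sd)).statistic
    rng = np.random.default_rng(seed)
    sims = rng.standard_normal((n_mc, x.size))
    exceed = 0
    for row in sims:
        s = stats.kstest(row, "norm", args=(row.mean(), row.std(ddof=1))).statistic
        exceed += s >= stat
    p = (1.0 + exceed) / (n_mc + 1.0)
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# Design construction and REML fitting
# ---------------------------------------------------------------------------


def _build_state(data: pd.DataFrame, spec: DesignSpec) -> _ModelState:
    df = data.reset_index(drop=True)
    required = {"participant_id", "week", "cadence"}
    if not required <= set(df.columns):
        raise ValueError(f"data must carry columns {sorted(required)}")
    participants = sorted(df["participant_id"].unique())
    if len(participants) < 2:
        raise RankDeficiencyError("mixed-model fitting needs >= 2 participants")

    y = df["cadence"].to_numpy(dtype=float)
    w = df["week"].to_numpy(dtype=float)
    season = df["season"].to_numpy() if "season" in df.columns else np.ones(len(df))
    has_season = len(np.unique(season)) > 1

    cols: list[np.ndarray] = [np.ones(len(df))]
    fixed_names = ["beta0"]
    if spec.model_type == "linear":
        cols.append(w)
        fixed_names.append("beta1")
    if has_season:
        cols.append((season == 2).astype(float))
        fixed_names.append("beta2")

    blocks: list[_Block] = []
    pos = len(cols)
    basis: TPRSBasis | None = None
    if spec.model_type == "nonlinear":
        basis = tprs_basis(w, spec.k_basis)
        design = basis.design
        # double penalty: separate shrinkage of the smooth's linear null space
        cols.append(design[:, :1].ravel())
        blocks.append(_Block("smooth_null", slice(pos, pos + 1), np.eye(1), 1, 0.0))
        pos += 1
        wig = design[:, 1:]
        S = basis.penalty[1:, 1:]
        eigval = np.clip(linalg.eigvalsh(S), 0.0, None)
        tol = max(eigval) * 1e-10 if eigval.size else 0.0
        rank = int(np.sum(eigval > tol))
        logdet_plus = float(np.sum(np.log(eigval[eigval > tol])))
        cols.extend(wig.T)
        blocks.append(
            _Block("smooth_range", slice(pos, pos + wig.shape[1]), S, rank, logdet_plus)
        )
        pos += wig.shape[1]

    pid_codes = pd.Categorical(df["participant_id"], categories=participants).codes
    indicators = np.zeros((len(df), len(participants)))
    indicators[np.arange(len(df)), pid_codes] = 1.0
    if "intercept" in spec.random_effects:
        cols.extend(indicators.T)
        m = len(participants)
        blocks.append(_Block("rand_intercept", slice(pos, pos + m), np.eye(m), m, 0.0))
        pos += m
    if "slope" in spec.random_effects:
        cols.extend((indicators * w[:, None]).T)
        m = len(participants)
        blocks.append(_Block("rand_slope", slice(pos, pos + m), np.eye(m), m, 0.0))
        pos += m

    B = np.column_stack(cols)
    data_hash = hashlib.sha1(np.ascontiguousarray(y).tobytes()).hexdigest()
    return _ModelState(
        y=y,
        B=B,
        fixed_names=fixed_names,
        blocks=blocks,
        participants=participants,
        weeks=w,
        has_season=has_season,
        basis=basis,
        spec=spec,
        data_hash=data_hash,
    )


def _optimize_reml(state: _ModelState) -> tuple[np.ndarray, float]:
    d = len(state.blocks)
    if d == 0:
        return np.zeros(0), state.reml(np.zeros(0))
    best_x, best_f = None, np.inf
    for start in _STARTS:
        x0 = np.full(d, start)
        res = optimize.minimize(
            state.reml,
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-5, "fatol": 1e-8, "maxiter": 400 * d, "maxfev": 400 * d},
        )
        if np.isfinite(res.fun) and res.fun < best_f:
            best_f, best_x = float(res.fun), np.clip(res.x, *_LOG_LAMBDA_BOUNDS)
    if best_x is None:
        raise ConvergenceError("REML optimisation diverged from every start")
    return best_x, best_f


def fit_model(
    data: pd.DataFrame,
    spec: DesignSpec | None = None,
    *,
    log_lambda_override: np.ndarray | None = None,
) -> GamFit:
    """Fit the linear or penalized-smooth mixed model by REML.

    Parameters
    ----------
    data
        Longitudinal table with columns ``participant_id, week, cadence``
        and optionally ``season``.
    spec
        Model specification; defaults to the non-linear model with random
        intercepts and slopes.
    log_lambda_override
        Fix the log smoothing / precision parameters instead of optimising
        them (one entry per penalized block, in design order: smooth null
        space, smooth range space, random intercepts, random slopes).
    """
    spec = spec or DesignSpec()
    state = _build_state(data, spec)

    if log_lambda_override is not None:
        log_lam = np.asarray(log_lambda_override, dtype=float)
        if log_lam.size != len(state.blocks):
            raise ValueError(f"expected {len(state.blocks)} log-lambdas")
        reml_score = state.reml(log_lam)
    else:
        log_lam, reml_score = _optimize_reml(state)

    log_lam = np.clip(log_lam, *_LOG_LAMBDA_BOUNDS)
    coef, (c, low), rss, pen = state.solve(log_lam)
    Hinv = linalg.cho_solve((c, low), np.eye(state.p))
    M = Hinv @ state.BtB  # influence-matrix factor: diag gives per-column edf
    edf_vec = np.diag(M)
    edf_total = float(np.sum(edf_vec))
    # 2 tr(F) - tr(FF): effective df corrected for smoothing-parameter
    # uncertainty; used as the chi-squared reference in model comparison
    edf_test = float(2.0 * edf_total - np.sum(M * M.T))

    m_p = state.p - sum(blk.rank for blk in state.blocks)
    sigma2 = (rss + pen) / (state.n - m_p)
    cov = sigma2 * Hinv

    names = {blk.name: blk for blk in state.blocks}
    lambdas = {blk.name: float(np.exp(l)) for blk, l in zip(state.blocks, log_lam)}

    edf_smooth = 0.0
    smooth_coefs = None
    if spec.model_type == "nonlinear":
        sl_null, sl_range = names["smooth_null"].sl, names["smooth_range"].sl
        edf_smooth = float(np.sum(edf_vec[sl_null]) + np.sum(edf_vec[sl_range]))
        smooth_coefs = np.concatenate([coef[sl_null], coef[sl_range]])

    def _ridge_block(name: str):
        if name not in names:
            return {}, None
        sl = names[name].sl
        vals = dict(zip(state.participants, coef[sl]))
        var = float(sigma2 / lambdas[name])
        return vals, var

    b0, var_b0 = _ridge_block("rand_intercept")
    b1, var_b1 = _ridge_block("rand_slope")

    fixed_idx = {nm: i for i, nm in enumerate(state.fixed_names)}
    se_beta = {nm: float(np.sqrt(cov[i, i])) for nm, i in fixed_idx.items()}
    beta0 = float(coef[fixed_idx["beta0"]])
    beta1 = float(coef[fixed_idx["beta1"]]) if "beta1" in fixed_idx else None
    beta2 = float(coef[fixed_idx["beta2"]]) if "beta2" in fixed_idx else None

    n = state.n
    # conditional log-likelihood at the fitted values, profiled ML variance
    loglik = -0.5 * n * (np.log(2.0 * np.pi * rss / n) + 1.0)
    tss = float(np.sum((state.y - state.y.mean()) ** 2))
    aic, bic, r2_adj = _criteria(loglik, edf_total, n, rss, tss)

    near_boundary = any(
        l >= _LOG_LAMBDA_BOUNDS[1] - 1.0 or l <= _LOG_LAMBDA_BOUNDS[0] + 1.0 for l in log_lam
    )
    return GamFit(
        beta0=beta0,
        beta1=beta1,
        beta2=beta2,
        smooth_coefs=smooth_coefs,
        b0=b0,
        b1=b1,
        var_b0=var_b0,
        var_b1=var_b1,
        var_eps=float(sigma2),
        lambdas=lambdas,
        edf_smooth=edf_smooth,
        edf_total=edf_total,
        edf_test=edf_test,
        loglik=float(loglik),
        reml_score=float(reml_score),
        aic=aic,
        bic=bic,
        r2_adj=r2_adj,
        se_beta=se_beta,
        n_obs=n,
        rss=rss,
        tss=tss,
        boundary_warning=near_boundary,
        _state=state,
        _coef=coef,
        _cov=cov,
    )


def _criteria(loglik: float, edf_total: float, n: int, rss: float, tss: float):
    if n <= edf_total:
        raise IllPosedCriteriaError("n_obs must exceed the total effective df")
    aic = -2.0 * loglik + 2.0 * edf_total
    bic = -2.0 * loglik + np.log(n) * edf_total
    r2_adj = 1.0 - (rss / (n - edf_total)) / (tss / (n - 1))
    return float(aic), float(bic), float(r2_adj)


def model_criteria(fit: GamFit, n_obs: int | None = None) -> tuple[float, float, float]:
    """(AIC, BIC, adjusted r^2) from the conditional log-likelihood and the
    total effective degrees of freedom."""
    n = fit.n_obs if n_obs is None else n_obs
    return _criteria(fit.loglik, fit.edf_total, n, fit.rss, fit.tss)


def compare_models(fit_lin: GamFit, fit_nl: GamFit) -> ModelComparison:
    """Likelihood-ratio comparison of the nested linear and smooth models.

    D = 2 (loglik_nl - loglik_lin) clipped at zero, referred to a
    chi-squared with df = max(edf_test_nl - edf_test_lin, 0.5), where
    edf_test = 2 tr(F) - tr(FF) is the smoothing-corrected effective df
    (the plain tr(F) difference is measurably anti-conservative under a
    linear truth).  The reference is approximate because the null places
    the smoothing parameter on its boundary.
    """
    if fit_lin._state.data_hash != fit_nl._state.data_hash:
        raise IncomparableFitsError("fits were not computed on the same data")
    D = max(0.0, 2.0 * (fit_nl.loglik - fit_lin.loglik))
    df = max(fit_nl.edf_test - fit_lin.edf_test, 0.5)
    p = float(stats.chi2.sf(D, df)) if D > 0 else 1.0
    return ModelComparison(
        D=float(D),
        df=float(df),
        p=p,
        aic_linear=fit_lin.aic,
        aic_nonlinear=fit_nl.aic,
        bic_linear=fit_lin.bic,
        bic_nonlinear=fit_nl.bic,
        r2_linear=fit_lin.r2_adj,
        r2_nonlinear=fit_nl.r2_adj,
    )


# ---------------------------------------------------------------------------
# Prediction and percentage change
# ---------------------------------------------------------------------------


def _population_rows(fit: GamFit, weeks: np.ndarray, season: int) -> np.ndarray:
    state = fit._state
    rows = np.zeros((weeks.size, state.p))
    idx = {nm: i for i, nm in enumerate(state.fixed_names)}
    rows[:, idx["beta0"]] = 1.0
    if "beta1" in idx:
        rows[:, idx["beta1"]] = weeks
    if "beta2" in idx:
        rows[:, idx["beta2"]] = 1.0 if season == 2 else 0.0
    if state.spec.model_type == "nonlinear":
        names = {blk.name: blk for blk in state.blocks}
        basis_cols = state.basis.evaluate(weeks)
        rows[:, names["smooth_null"].sl] = basis_cols[:, :1]
        rows[:, names["smooth_range"].sl] = basis_cols[:, 1:]
    return rows


def predict_curve(
    fit: GamFit,
    weeks,
    season: int = 1,
    level: str = "group",
) -> PredictionCurve:
    """Predicted population cadence over a week grid with pointwise 95% CIs.

    Group level sets all random effects to zero; CIs use 1.96 x the
    pointwise SE from the coefficient covariance of the fixed + smooth
    terms.  ``level="individual"`` additionally returns one trajectory per
    participant (population curve plus that participant's random intercept
    and slope).  Grid points beyond the observed week range are flagged in
    ``extrapolated`` rather than rejected.
    """
    if level not in ("group", "individual"):
        raise ValueError(f"unknown level {level!r}")
    weeks = np.asarray(weeks, dtype=float)
    state = fit._state
    rows = _population_rows(fit, weeks, season)
    mean = rows @ fit._coef
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", rows, fit._cov, rows), 0.0))
    lo, hi = mean - 1.96 * se, mean + 1.96 * se

    individual = None
    if level == "individual":
        individual = pd.DataFrame(
            {
                pid: mean + fit.b0.get(pid, 0.0) + fit.b1.get(pid, 0.0) * weeks
                for pid in state.participants
            },
            index=weeks,
        )
    extrapolated = (weeks < state.weeks.min()) | (weeks > state.weeks.max())
    return PredictionCurve(
        weeks=weeks,
        mean=mean,
        lo95=lo,
        hi95=hi,
        individual=individual,
        extrapolated=extrapolated,
    )


def weekly_percent_change(
    curve: PredictionCurve, window: tuple[float, float] | None = None
) -> tuple[np.ndarray, float]:
    """Per-week percentage change of the population mean over ``window``.

    Requires a unit-step week grid inside the window; returns the array of
    changes pct[w] = 100 (mean[w+1] - mean[w]) / mean[w] and their
    arithmetic mean.
    """
    w = np.asarray(curve.weeks, dtype=float)
    if window is None:
        window = (float(w.min()), float(w.max()))
    mask = (w >= window[0] - 1e-9) & (w <= window[1] + 1e-9)
    ww, mm = w[mask], np.asarray(curve.mean)[mask]
    if ww.size < 2 or not np.allclose(np.diff(ww), 1.0, atol=1e-9):
        raise ValueError("window must cover a unit-step week grid")
    if np.any(mm[:-1] == 0):
        raise ZeroDivisionError("percentage change undefined where the mean is zero")
    pct = 100.0 * np.diff(mm) / mm[:-1]
    return pct, float(pct.mean())
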