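"""Incremental cost and effect estimation.

The estimation strategy mirrors standard practice in trial-based economic
evaluation:

* missing follow-up costs and utilities are filled by deterministic regression
  imputation on baseline predictors of outcome and of dropout (intention to
  treat);
* adjusted incremental costs can be checked with a gamma-family identity-link
  GLM (skewed costs, additive covariate effects), with the family choice
  guided by a modified Park test;
* the joint incremental cost/effect estimate comes from a two-equation
  seemingly unrelated regression (SUR) fitted by feasible generalized least
  squares, allowing the cost- and effect-equation residuals to be correlated;
* sampling uncertainty is propagated by a nonparametric participant-level
  bootstrap of the SUR (default 2500 replicates) with bias-corrected and
  accelerated (BCa) confidence intervals.

The FGLS solver is written against plain numpy arrays and evaluates whole
batches of bootstrap/jackknife index sets at once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import ndtr, ndtri
from statsmodels.tools.sm_exceptions import DomainWarning

__all__ = [
    "RegressionSpec",
    "SURResult",
    "BootstrapCloud",
    "ReplicateImputer",
    "ResponsePlan",
    "ReimputePlan",
    "regression_impute",
    "modified_park_test",
    "fit_cost_model",
    "fit_effect_model",
    "sur_fit",
    "bootstrap_sur",
    "jackknife_sur",
    "bca_ci",
]


@dataclass(frozen=True)
class RegressionSpec:
    """One equation of the system: response column, adjustment covariates
    (the treatment-arm indicator and an intercept are always included), and
    the family used when the equation is fitted on its own."""

    response: str
    covariates: tuple[str, ...] = ()
    family: str = "gaussian"
    link: str = "identity"

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "gamma"):
            raise ValueError("family must be 'gaussian' or 'gamma'")
        if self.link != "identity":
            raise ValueError("only the identity link is supported")
        object.__setattr__(self, "covariates", tuple(self.covariates))

    def design(self, frame: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
        for col in (self.response, *self.covariates):
            if col not in frame.columns:
                raise KeyError(f"column {col!r} not in analysis frame")
        names = ["const", "arm", *self.covariates]
        X = np.column_stack(
            [np.ones(len(frame)), frame["arm"].to_numpy(float)]
            + [frame[c].to_numpy(float) for c in self.covariates]
        )
        y = frame[self.response].to_numpy(float)
        if np.isnan(X).any() or np.isnan(y).any():
            raise ValueError(
                f"equation {self.response!r} has missing values; impute or filter first"
            )
        return X, y, names


# ---------------------------------------------------------------------------
# Regression imputation

_CLIP_RULES = (("utility_", (0.0, 1.0)), ("isi_", (0.0, 28.0)), ("cost_", (0.0, None)))


def _clip_for(column: str, values: np.ndarray) -> np.ndarray:
    for prefix, (lo, hi) in _CLIP_RULES:
        if column.startswith(prefix):
            return np.clip(values, lo, hi)
    return values


def regression_impute(
    frame: pd.DataFrame,
    outcome_predictors: tuple[str, ...] = ("utility_t0", "isi_t0"),
    dropout_predictors: tuple[str, ...] = ("baseline_depression", "age"),
    seed=None,
) -> pd.DataFrame:
    """Replace missing follow-up values with predicted means from per-column
    OLS regressions on the union of outcome and dropout predictors (plus arm).

    Deterministic: predicted means only, no residual draws (``seed`` is
    accepted for interface symmetry). Imputed utilities/ISI/costs are clipped
    to their valid ranges. A frame with no missing values is returned
    unchanged (a copy). The boolean ``imputed`` column flags rows that
    received at least one imputed value, and ``frame.attrs['imputation']``
    records per-column counts.
    """
    out = frame.copy()
    predictors = ["arm"] + [
        p for p in dict.fromkeys((*outcome_predictors, *dropout_predictors))
        if p != "arm"
    ]
    for p in predictors:
        if p not in out.columns:
            raise KeyError(f"predictor column {p!r} not in frame")
        if out[p].isna().all():
            raise ValueError(f"predictor column {p!r} is entirely missing")
        if out[p].isna().any():
            raise ValueError(f"predictor column {p!r} has missing baseline values")

    targets = [
        c for c in out.columns
        if c not in predictors and pd.api.types.is_numeric_dtype(out[c]) and out[c].isna().any()
    ]
    imputed_any = np.zeros(len(out), dtype=bool)
    counts: dict[str, int] = {}
    X = np.column_stack([np.ones(len(out))] + [out[p].to_numpy(float) for p in predictors])
    for col in targets:
        y = out[col].to_numpy(float)
        obs = ~np.isnan(y)
        beta, *_ = np.linalg.lstsq(X[obs], y[obs], rcond=None)
        pred = _clip_for(col, X[~obs] @ beta)
        y[~obs] = pred
        out[col] = y
        imputed_any |= ~obs
        counts[col] = int((~obs).sum())
    out["imputed"] = imputed_any
    out.attrs["imputation"] = counts
    return out


# ---------------------------------------------------------------------------
# Modified Park test

@dataclass(frozen=True)
class ParkTest:
    slope: float
    slope_se: float
    family: str


_PARK_FAMILIES = {0: "gaussian", 1: "poisson", 2: "gamma", 3: "inverse_gaussian"}


def modified_park_test(residuals, fitted) -> ParkTest:
    """Regress log squared raw residuals on log fitted means; the slope points
    to the variance power and hence the GLM family (0 gaussian, 1 poisson-like,
    2 gamma, 3 inverse gaussian, by rounding)."""
    r = np.asarray(residuals, float)
    mu = np.asarray(fitted, float)
    if np.any(mu <= 0):
        raise ValueError("fitted values must be strictly positive for the Park test")
    if np.ptp(np.log(mu)) < 1e-12:
        raise ValueError("fitted values are constant; the Park regression is degenerate")
    lr2 = np.log(np.maximum(r**2, 1e-300))
    X = sm.add_constant(np.log(mu))
    res = sm.OLS(lr2, X).fit()
    slope = float(res.params[1])
    idx = int(min(max(round(slope), 0), 3))
    return ParkTest(slope=slope, slope_se=float(res.bse[1]), family=_PARK_FAMILIES[idx])


# ---------------------------------------------------------------------------
# Single-equation models

def fit_cost_model(
    frame: pd.DataFrame,
    spec: RegressionSpec,
    zero_floor: float = 0.01,
    zero_fallback_fraction: float = 0.2,
    maxiter: int = 200,
):
    """Adjusted incremental cost from a single-equation model.

    For ``family='gamma'`` an identity-link gamma GLM is fitted by IRLS
    (started at the OLS solution); zero responses are lifted to a small
    positive floor, and if more than ``zero_fallback_fraction`` of responses
    are zero the fit falls back to gaussian OLS (the gamma likelihood is
    undefined at zero). The arm coefficient is the adjusted incremental cost.
    """
    X, y, names = spec.design(frame)
    if spec.family == "gaussian":
        res = sm.OLS(y, X).fit()
    else:
        zeros = y <= 0
        if zeros.mean() > zero_fallback_fraction:
            warnings.warn(
                f"{zeros.mean():.0%} of costs are zero; falling back to gaussian OLS",
                stacklevel=2,
            )
            res = sm.OLS(y, X).fit()
        else:
            y = np.where(zeros, zero_floor, y)
            start = sm.OLS(y, X).fit().params
            with warnings.catch_warnings():
                # the identity link for gamma is intentional (additive effects)
                warnings.simplefilter("ignore", DomainWarning)
                model = sm.GLM(y, X, family=sm.families.Gamma(sm.families.links.Identity()))
            try:
                res = model.fit(start_params=start, maxiter=maxiter)
            except Exception as exc:  # non-convergence or invalid means
                raise RuntimeError(
                    f"gamma GLM failed to converge after {maxiter} iterations: {exc}"
                ) from exc
            if not res.converged:
                raise RuntimeError(
                    f"gamma GLM did not converge after {maxiter} iterations "
                    f"(deviance {res.deviance:.3g})"
                )
    res.exog_names_ = names
    res.arm_effect = float(res.params[1])
    return res


def fit_effect_model(frame: pd.DataFrame, spec: RegressionSpec):
    """Adjusted incremental effect from ordinary least squares (0/1
    symptom-free status, or QALYs adjusted for baseline utility). Raises on
    collinear covariates."""
    X, y, names = spec.design(frame)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear covariates in effect model design")
    res = sm.OLS(y, X).fit()
    res.exog_names_ = names
    res.arm_effect = float(res.params[1])
    return res


# ---------------------------------------------------------------------------
# SUR (two-equation FGLS) and its bootstrap

_REL_TOL_PERFECT = 1e-10  # residual variance below this x response scale == perfect fit
_REL_TOL_SINGULAR = 1e-12


def _solve_batched(A: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Solve A_i x_i = b_i per batch row; rows with singular/ill-posed systems
    get x=0 and ok=False instead of raising."""
    m, k = b.shape
    ok = np.ones(m, dtype=bool)
    try:
        x = np.linalg.solve(A, b[..., None])[..., 0]
    except np.linalg.LinAlgError:
        x = np.zeros_like(b)
        for i in range(m):
            try:
                x[i] = np.linalg.solve(A[i], b[i])
            except np.linalg.LinAlgError:
                ok[i] = False
    bad = ~np.isfinite(x).all(axis=1)
    x[bad] = 0.0
    ok &= ~bad
    return x, ok


def _sur_batched(X1, y1, X2, y2, idx, yb1=None, yb2=None):
    """Feasible-GLS SUR over batches of resample index sets.

    ``yb1``/``yb2`` optionally override the gathered responses with
    replicate-specific values (m, n), e.g. after within-replicate imputation.
    Returns ``(coef, sigma, ok)``: stacked coefficients (m, k1+k2), the 2x2
    residual covariance entries (m, 3) as (s11, s22, s12), and a validity
    mask. A degenerate residual covariance with essentially zero residuals
    falls back to the per-equation OLS solution (which is exact there); a
    singular covariance with non-trivial residuals is marked invalid.
    """
    k1, k2 = X1.shape[1], X2.shape[1]
    Xb1 = X1[idx]
    Xb2 = X2[idx]
    if yb1 is None:
        yb1 = y1[idx]
    if yb2 is None:
        yb2 = y2[idx]
    n = idx.shape[1]

    A1 = np.einsum("mni,mnj->mij", Xb1, Xb1)
    A2 = np.einsum("mni,mnj->mij", Xb2, Xb2)
    C = np.einsum("mni,mnj->mij", Xb1, Xb2)
    v1 = np.einsum("mni,mn->mi", Xb1, yb1)
    v2 = np.einsum("mni,mn->mi", Xb2, yb2)
    u12 = np.einsum("mni,mn->mi", Xb1, yb2)
    u21 = np.einsum("mni,mn->mi", Xb2, yb1)

    b1, ok1 = _solve_batched(A1, v1)
    b2, ok2 = _solve_batched(A2, v2)
    ok = ok1 & ok2

    r1 = yb1 - np.einsum("mnk,mk->mn", Xb1, b1)
    r2 = yb2 - np.einsum("mnk,mk->mn", Xb2, b2)
    s11 = (r1 * r1).sum(axis=1) / n
    s22 = (r2 * r2).sum(axis=1) / n
    s12 = (r1 * r2).sum(axis=1) / n

    scale1 = np.maximum((yb1 * yb1).mean(axis=1), 1.0)
    scale2 = np.maximum((yb2 * yb2).mean(axis=1), 1.0)
    perfect = (s11 <= _REL_TOL_PERFECT * scale1) & (s22 <= _REL_TOL_PERFECT * scale2)
    det = s11 * s22 - s12**2
    singular = det <= _REL_TOL_SINGULAR * np.maximum(s11 * s22, 1e-300)

    coef = np.concatenate([b1, b2], axis=1)  # OLS; overwritten by FGLS where valid
    run_fgls = ok & ~perfect & ~singular
    if run_fgls.any():
        sel = np.flatnonzero(run_fgls)
        d = det[sel]
        w11 = (s22[sel] / d)[:, None, None]
        w22 = (s11[sel] / d)[:, None, None]
        w12 = (-s12[sel] / d)[:, None, None]
        K = k1 + k2
        M = np.empty((sel.size, K, K))
        M[:, :k1, :k1] = w11 * A1[sel]
        M[:, :k1, k1:] = w12 * C[sel]
        M[:, k1:, :k1] = w12 * np.transpose(C[sel], (0, 2, 1))
        M[:, k1:, k1:] = w22 * A2[sel]
        rhs = np.empty((sel.size, K))
        rhs[:, :k1] = w11[:, :, 0] * v1[sel] + w12[:, :, 0] * u12[sel]
        rhs[:, k1:] = w12[:, :, 0] * u21[sel] + w22[:, :, 0] * v2[sel]
        bf, okf = _solve_batched(M, rhs)
        coef[sel] = bf
        ok[sel] &= okf
    ok &= perfect | ~singular  # singular Sigma with real residuals is invalid
    sigma = np.column_stack([s11, s22, s12])
    return coef, sigma, ok


# ---------------------------------------------------------------------------
# Within-replicate imputation: the bootstrap mimics the full estimation
# pipeline by re-running the deterministic regression imputation on each
# resampled data set, so imputation uncertainty propagates into the cloud.

@dataclass
class ReplicateImputer:
    """Re-runs deterministic regression imputation inside each resample.

    ``P`` is the fixed (n, p) predictor design (intercept, arm, baseline
    predictors; always fully observed). ``columns`` maps a column name to its
    raw values (NaN replaced by 0), its observed mask, and the clip range
    applied to predictions.
    """

    P: np.ndarray
    columns: dict[str, tuple[np.ndarray, np.ndarray, tuple[float | None, float | None]]]

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, predictors, columns) -> "ReplicateImputer":
        P = np.column_stack(
            [np.ones(len(frame))] + [frame[p].to_numpy(float) for p in predictors]
        )
        if np.isnan(P).any():
            raise ValueError("imputation predictors must be fully observed")
        cols = {}
        for name in columns:
            y = frame[name].to_numpy(float)
            obs = ~np.isnan(y)
            if not obs.any():
                raise ValueError(f"column {name!r} is entirely missing")
            lo, hi = (0.0, None)
            for prefix, rng in _CLIP_RULES:
                if name.startswith(prefix):
                    lo, hi = rng
            cols[name] = (np.nan_to_num(y), obs, (lo, hi))
        return cls(P=P, columns=cols)

    def impute(self, idx: np.ndarray) -> tuple[dict[str, np.ndarray], np.ndarray]:
        """Completed (m, n) versions of every managed column for each resample
        row, plus a per-replicate validity mask (False when the within-replicate
        imputation regression is singular)."""
        Pb = self.P[idx]
        ok = np.ones(idx.shape[0], dtype=bool)
        out = {}
        for name, (y0, obs, (lo, hi)) in self.columns.items():
            yb = y0[idx]
            mb = obs[idx].astype(float)
            Pm = Pb * mb[:, :, None]
            A = np.einsum("mni,mnj->mij", Pm, Pb)
            b = np.einsum("mni,mn->mi", Pm, yb)
            beta, ok_col = _solve_batched(A, b)
            pred = np.einsum("mnp,mp->mn", Pb, beta)
            if lo is not None or hi is not None:
                pred = np.clip(pred, lo, hi)
            out[name] = np.where(mb > 0, yb, pred)
            ok &= ok_col
        return out, ok


@dataclass(frozen=True)
class ResponsePlan:
    """How one equation's response is rebuilt from an imputed column.

    ``response = base + coef * completed`` in general; when ``threshold`` is
    set the response is the indicator ``completed < threshold`` (the
    symptom-free dichotomization applied after imputing the ISI score).
    """

    column: str
    coef: float = 1.0
    base: np.ndarray | None = None
    threshold: float | None = None

    def build(self, completed: np.ndarray, idx: np.ndarray) -> np.ndarray:
        if self.threshold is not None:
            return (completed < self.threshold).astype(float)
        y = self.coef * completed
        if self.base is not None:
            y = y + self.base[idx]
        return y


@dataclass
class ReimputePlan:
    """Imputer plus the two equations' response recipes."""

    imputer: ReplicateImputer
    cost: ResponsePlan
    effect: ResponsePlan

    def responses(self, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        completed, ok = self.imputer.impute(idx)
        yb1 = self.cost.build(completed[self.cost.column], idx)
        yb2 = self.effect.build(completed[self.effect.column], idx)
        return yb1, yb2, ok


@dataclass
class SURResult:
    """Joint FGLS fit of the cost and effect equations."""

    params_cost: pd.Series
    params_effect: pd.Series
    cov_params: np.ndarray  # stacked (k1+k2) FGLS covariance
    resid_corr: float
    nobs: int

    @property
    def delta_cost(self) -> float:
        return float(self.params_cost["arm"])

    @property
    def delta_effect(self) -> float:
        return float(self.params_effect["arm"])

    @property
    def delta_cost_se(self) -> float:
        return float(np.sqrt(self.cov_params[1, 1]))

    @property
    def delta_effect_se(self) -> float:
        k1 = len(self.params_cost)
        return float(np.sqrt(self.cov_params[k1 + 1, k1 + 1]))


def sur_fit(frame: pd.DataFrame, cost_spec: RegressionSpec, effect_spec: RegressionSpec) -> SURResult:
    """Two-equation SUR by one-step feasible GLS with cross-equation residual
    covariance estimated from per-equation OLS residuals.

    With identical regressor sets in both equations the FGLS solution
    coincides exactly with per-equation OLS (Kruskal's equivalence). Raises if
    the residual covariance is singular while residuals are non-trivial.
    """
    X1, y1, names1 = cost_spec.design(frame)
    X2, y2, names2 = effect_spec.design(frame)
    idx = np.arange(len(y1))[None, :]
    coef, sigma, ok = _sur_batched(X1, y1, X2, y2, idx)
    if not ok[0]:
        raise np.linalg.LinAlgError(
            "SUR system is singular (collinear design or singular residual covariance)"
        )
    k1 = X1.shape[1]
    s11, s22, s12 = sigma[0]
    corr = float(s12 / np.sqrt(s11 * s22)) if s11 > 0 and s22 > 0 else 0.0

    # FGLS parameter covariance (X' (Sigma^-1 x I) X)^-1; falls back to OLS
    # blocks when the residual covariance is degenerate (perfect fit).
    det = s11 * s22 - s12**2
    K = X1.shape[1] + X2.shape[1]
    if det > _REL_TOL_SINGULAR * max(s11 * s22, 1e-300):
        w11, w22, w12 = s22 / det, s11 / det, -s12 / det
        M = np.zeros((K, K))
        M[:k1, :k1] = w11 * (X1.T @ X1)
        M[:k1, k1:] = w12 * (X1.T @ X2)
        M[k1:, :k1] = M[:k1, k1:].T
        M[k1:, k1:] = w22 * (X2.T @ X2)
        cov = np.linalg.inv(M)
    else:
        cov = np.zeros((K, K))
    return SURResult(
        params_cost=pd.Series(coef[0, :k1], index=names1),
        params_effect=pd.Series(coef[0, k1:], index=names2),
        cov_params=cov,
        resid_corr=corr,
        nobs=len(y1),
    )


@dataclass
class BootstrapCloud:
    """Bootstrap replicates of the (incremental cost, incremental effect) pair."""

    pairs: np.ndarray  # (B, 2): delta_cost, delta_effect
    B: int
    seed: int | None
    point: tuple[float, float]
    n_redrawn: int = 0
    point_fit: SURResult | None = field(default=None, repr=False)

    @property
    def delta_cost(self) -> np.ndarray:
        return self.pairs[:, 0]

    @property
    def delta_effect(self) -> np.ndarray:
        return self.pairs[:, 1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "replicate": np.arange(self.B),
                "delta_cost": self.pairs[:, 0],
                "delta_effect": self.pairs[:, 1],
            }
        )


_CHUNK_ELEMENTS = 40_000_000  # cap on m*n per einsum batch to bound memory


def _batched_arm_coefs(X1, y1, X2, y2, idx_iter, expected, reimpute=None):
    """Run _sur_batched over chunks of index sets; returns (m, 2) arm coefs
    and validity mask. ``reimpute`` re-runs the deterministic imputation on
    each resample before the responses enter the system."""
    k1 = X1.shape[1]
    out = np.empty((expected, 2))
    ok_all = np.empty(expected, dtype=bool)
    pos = 0
    for idx in idx_iter:
        yb1 = yb2 = None
        ok_imp = None
        if reimpute is not None:
            yb1, yb2, ok_imp = reimpute.responses(idx)
        coef, _, ok = _sur_batched(X1, y1, X2, y2, idx, yb1=yb1, yb2=yb2)
        if ok_imp is not None:
            ok &= ok_imp
        m = idx.shape[0]
        out[pos : pos + m, 0] = coef[:, 1]
        out[pos : pos + m, 1] = coef[:, k1 + 1]
        ok_all[pos : pos + m] = ok
        pos += m
    return out[:pos], ok_all[:pos]


def bootstrap_sur(
    frame: pd.DataFrame,
    cost_spec: RegressionSpec,
    effect_spec: RegressionSpec,
    B: int = 2500,
    seed: int | None = 0,
    max_failure_fraction: float = 0.05,
    reimpute: ReimputePlan | None = None,
) -> BootstrapCloud:
    """Nonparametric bootstrap of the SUR arm coefficients.

    Participants are the resampling unit. When a ``reimpute`` plan is given,
    the deterministic regression imputation is re-run inside every replicate
    so that imputation uncertainty propagates into the cloud (the frame passed
    in should then be the once-imputed frame, which fixes the point estimate).
    Replicates whose resampled system is singular are redrawn so the cloud
    always holds exactly ``B`` pairs; more than ``max_failure_fraction * B``
    failures aborts with diagnostics.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    X1, y1, names1 = cost_spec.design(frame)
    X2, y2, _ = effect_spec.design(frame)
    point = sur_fit(frame, cost_spec, effect_spec)
    n = len(y1)
    rng = np.random.default_rng(seed)
    chunk = max(1, min(B, _CHUNK_ELEMENTS // max(n * X1.shape[1], 1)))

    pairs = np.empty((B, 2))
    filled = 0
    failures = 0
    max_failures = int(np.ceil(max_failure_fraction * B))
    while filled < B:
        m = min(chunk, B - filled)
        idx = rng.integers(0, n, size=(m, n))
        coefs, ok = _batched_arm_coefs(X1, y1, X2, y2, [idx], m, reimpute=reimpute)
        good = coefs[ok]
        take = min(len(good), B - filled)
        pairs[filled : filled + take] = good[:take]
        filled += take
        failures += int((~ok).sum())
        if failures > max_failures:
            raise RuntimeError(
                f"{failures} of {filled + failures} bootstrap replicates failed "
                f"(> {max_failure_fraction:.0%} of B={B}); the resampled SUR system "
                "is too often singular"
            )
    return BootstrapCloud(
        pairs=pairs,
        B=B,
        seed=seed,
        point=(point.delta_cost, point.delta_effect),
        n_redrawn=failures,
        point_fit=point,
    )


def jackknife_sur(
    frame: pd.DataFrame,
    cost_spec: RegressionSpec,
    effect_spec: RegressionSpec,
    reimpute: ReimputePlan | None = None,
) -> np.ndarray:
    """Leave-one-participant-out SUR arm coefficients, shape (n, 2); feeds the
    BCa acceleration estimate. ``reimpute`` re-runs the imputation on each
    leave-one-out sample, mirroring the bootstrap."""
    X1, y1, _ = cost_spec.design(frame)
    X2, y2, _ = effect_spec.design(frame)
    n = len(y1)
    base = np.arange(n)
    chunk = max(1, _CHUNK_ELEMENTS // max(n * X1.shape[1], 1))

    def idx_iter():
        for start in range(0, n, chunk):
            stop = min(start + chunk, n)
            yield np.stack([np.delete(base, i) for i in range(start, stop)])

    coefs, ok = _batched_arm_coefs(X1, y1, X2, y2, idx_iter(), n, reimpute=reimpute)
    if not ok.all():
        raise np.linalg.LinAlgError("jackknife SUR fit singular for some leave-one-out sample")
    return coefs


def bca_ci(
    replicates,
    point_estimate: float,
    jackknife_estimates=None,
    level: float = 0.95,
) -> tuple[float, float]:
    """Bias-corrected and accelerated bootstrap confidence interval.

    The bias correction ``z0`` comes from the fraction of replicates below the
    full-sample point estimate; the acceleration ``a`` from the skewness of
    jackknife estimates (``a = 0`` when no jackknife values are supplied, in
    which case the interval is the plain bias-corrected percentile interval;
    with ``z0 = 0`` too it reduces to the percentile interval). Endpoints are
    replicate quantiles at the adjusted levels.
    """
    reps = np.asarray(replicates, dtype=float)
    if reps.size < 100:
        raise ValueError("need at least 100 bootstrap replicates for a BCa interval")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    if np.ptp(reps) == 0:
        warnings.warn("all bootstrap replicates identical; degenerate interval", stacklevel=2)
        return (float(point_estimate), float(point_estimate))

    B = reps.size
    prop = np.count_nonzero(reps < point_estimate) / B
    prop = min(max(prop, 1.0 / (B + 1)), B / (B + 1.0))
    z0 = ndtri(prop)

    a = 0.0
    if jackknife_estimates is not None:
        jk = np.asarray(jackknife_estimates, dtype=float)
        d = jk.mean() - jk
        denom = (d**2).sum() ** 1.5
        if denom > 0:
            a = float((d**3).sum() / (6.0 * denom))

    alpha = 1.0 - level
    lo_hi = []
    for z_alpha in (ndtri(alpha / 2), ndtri(1 - alpha / 2)):
        adj = z0 + (z0 + z_alpha) / (1.0 - a * (z0 + z_alpha))
        lo_hi.append(float(np.quantile(reps, min(max(ndtr(adj), 0.0), 1.0))))
    return (lo_hi[0], lo_hi[1])
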