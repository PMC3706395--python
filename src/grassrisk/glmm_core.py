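"""Random-intercept mixed models with a single grouping factor (genus).

Two families are supported:

* binomial (logit link) for the binary high-impact response — the marginal
  likelihood integrates a Normal(0, sigma^2) genus intercept out of each
  genus's Bernoulli likelihood.  The integral is evaluated by adaptive
  Gauss–Hermite quadrature centred and scaled at the conditional mode
  (one node reproduces the Laplace approximation); the outer optimisation
  is quasi-Newton with an analytic quadrature gradient.
* Gaussian for log spread rate — the marginal likelihood is available in
  closed form per genus (compound-symmetric covariance), fitted by maximum
  likelihood (not REML) so AICc is comparable across fixed-effect subsets.

Model comparison uses the small-sample corrected information criterion
AICc = -2 loglik + 2k + 2k(k+1)/(n-k-1), with k counting the fixed effects
plus one genus variance parameter (plus one residual variance for Gaussian
models).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize
from scipy.special import expit

from grassrisk.species_table import (
    GROWTH_FORM_LEVELS,
    INTRO_PATHWAYS,
    LIFE_HISTORIES,
    Dataset,
    SpeciesRecord,
)

#: Canonical predictor order used for enumeration and design-matrix layout.
PREDICTORS = (
    "spread_rate",
    "naturalisation_year",
    "actively_spread",
    "intro_pathway",
    "semi_aquatic",
    "life_history",
    "tufted",
    "rhizomes",
    "stolons",
    "num_regions",
)
#: num_regions is only legal for the spread-rate response (it is nearly
#: collinear with spread rate itself for the binary response).
IMPACT_PREDICTORS = PREDICTORS[:9]

BINARY_RESPONSES = ("high_impact", "impact_env", "impact_pastoral", "impact_agri")
GAUSSIAN_RESPONSES = ("log_spread_rate",)

#: Reference levels for treatment contrasts.  The choice only moves the
#: intercept's interpretation; it is recorded in fit output metadata.
REFERENCE_LEVELS = {
    "intro_pathway": "pasture_or_turf",
    "life_history": "annual",
    "tufted": "no",
    "rhizomes": "no",
    "stolons": "no",
}
_CATEGORICAL_FULL_LEVELS = {
    "intro_pathway": INTRO_PATHWAYS,
    "life_history": LIFE_HISTORIES,
    "tufted": GROWTH_FORM_LEVELS,
    "rhizomes": GROWTH_FORM_LEVELS,
    "stolons": GROWTH_FORM_LEVELS,
}
_CONTINUOUS = ("spread_rate", "naturalisation_year", "num_regions")

#: Calendar years are centred here before entering the design matrix, purely
#: for numerical conditioning; slopes are unaffected.
YEAR_ORIGIN = 1900


class RankDeficientError(ValueError):
    """Design matrix not full rank; message names the collinear columns."""


@dataclass(frozen=True)
class ModelSpec:
    """A response, an ordered subset of fixed-effect predictors, and the
    (always-present) genus random intercept."""

    response: str
    fixed_predictors: tuple[str, ...] = ()
    grouping: str = "genus"

    def __post_init__(self) -> None:
        if self.response not in BINARY_RESPONSES + GAUSSIAN_RESPONSES:
            raise ValueError(f"unknown response {self.response!r}")
        object.__setattr__(self, "fixed_predictors", tuple(self.fixed_predictors))
        seen = set()
        for p in self.fixed_predictors:
            if p not in PREDICTORS:
                raise ValueError(f"unknown predictor {p!r}")
            if p in seen:
                raise ValueError(f"duplicate predictor {p!r}")
            seen.add(p)
        if self.response in BINARY_RESPONSES and "num_regions" in seen:
            raise ValueError(
                "num_regions is only permitted for the log_spread_rate response "
                "(collinear with spread rate for impact models)"
            )
        if self.grouping != "genus":
            raise ValueError("only a genus random intercept is supported")

    @property
    def formula(self) -> str:
        fixed = " + ".join(self.fixed_predictors) if self.fixed_predictors else "1"
        return f"{self.response} ~ {fixed} + (1 | genus)"


@dataclass(frozen=True)
class _Column:
    name: str
    predictor: Optional[str]  # None for the intercept
    level: Optional[str]  # categorical indicator level, else None

    def value_for(self, record: SpeciesRecord) -> float:
        if self.predictor is None:
            return 1.0
        v = getattr(record, self.predictor)
        if self.level is not None:
            return 1.0 if v == self.level else 0.0
        if self.predictor == "naturalisation_year":
            return float(v) - YEAR_ORIGIN
        return float(v)


def build_design(dataset: Dataset, predictors: Sequence[str]) -> tuple[np.ndarray, list[_Column]]:
    """Design matrix with intercept and treatment contrasts.

    Indicator columns are built for the non-reference levels actually present
    in the data, so subsets missing a level stay full rank.
    """
    df = dataset.frame
    cols: list[_Column] = [_Column("(intercept)", None, None)]
    arrays = [np.ones(len(df))]
    for p in predictors:
        if p in _CATEGORICAL_FULL_LEVELS:
            ref = REFERENCE_LEVELS[p]
            present = [l for l in _CATEGORICAL_FULL_LEVELS[p] if l != ref and (df[p] == l).any()]
            for level in present:
                cols.append(_Column(f"{p}[{level}]", p, level))
                arrays.append((df[p] == level).to_numpy(float))
        elif p in _CONTINUOUS:
            x = df[p].to_numpy(float)
            if p == "naturalisation_year":
                x = x - YEAR_ORIGIN
            cols.append(_Column(p, p, None))
            arrays.append(x)
        else:  # binary
            cols.append(_Column(p, p, None))
            arrays.append(df[p].to_numpy(float))
    X = np.column_stack(arrays)
    _check_full_rank(X, [c.name for c in cols])
    return X, cols


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    bad = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
    if bad:
        raise RankDeficientError(f"design matrix is rank deficient; collinear column(s): {bad}")


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC; requires n > k + 1."""
    if k < 1:
        raise ValueError("k counts at least the genus variance parameter (k >= 1)")
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass
class FitResult:
    """A fitted random-intercept model and its information-criterion summary."""

    spec: ModelSpec
    coefficients: dict[str, float]
    genus_effects: dict[str, float]
    genus_sd: float
    residual_sd: Optional[float]
    loglik: float
    k: int
    n: int
    aicc: float
    converged: bool
    _columns: list[_Column] = field(default_factory=list, repr=False)

    @property
    def genus_variance(self) -> float:
        return self.genus_sd**2

    @property
    def residual_variance(self) -> Optional[float]:
        return None if self.residual_sd is None else self.residual_sd**2

    @property
    def params(self) -> np.ndarray:
        """Internal parameter vector (beta..., log sd...) for warm starts."""
        beta = np.array(list(self.coefficients.values()))
        logs = [math.log(max(self.genus_sd, 1e-8))]
        if self.residual_sd is not None:
            logs.append(math.log(max(self.residual_sd, 1e-8)))
        return np.concatenate([beta, logs])

    def linear_predictor(self, record: SpeciesRecord, use_genus_effect: bool = True) -> float:
        eta = sum(
            coef * col.value_for(record)
            for col, coef in zip(self._columns, self.coefficients.values())
        )
        if use_genus_effect:
            if record.genus not in self.genus_effects:
                raise KeyError(
                    f"genus {record.genus!r} was not present in the fitted data; "
                    "cannot apply a genus effect (fixed-effects-only prediction "
                    "is available with use_genus_effect=False)"
                )
            eta += self.genus_effects[record.genus]
        return eta

    def to_json(self) -> str:
        return json.dumps(
            {
                "formula": self.spec.formula,
                "coefficients": self.coefficients,
                "genus_sd": self.genus_sd,
                "residual_sd": self.residual_sd,
                "loglik": self.loglik,
                "k": self.k,
                "n": self.n,
                "aicc": self.aicc,
                "converged": self.converged,
                "reference_levels": REFERENCE_LEVELS,
            },
            indent=2,
        )


def predict_probability(fit: FitResult, record: SpeciesRecord, use_genus_effect: bool = True) -> float:
    """Probability that ``record`` is high impact under a binomial fit.

    With ``use_genus_effect`` the genus conditional mode is added to the
    fixed linear predictor; the record's genus must then have been present
    in the fitted data (singleton-genus hold-outs are the one case where it
    is not).
    """
    if fit.spec.response not in BINARY_RESPONSES:
        raise ValueError("predict_probability applies to binomial fits only")
    return float(expit(fit.linear_predictor(record, use_genus_effect)))


# ---------------------------------------------------------------------------
# binomial family
# ---------------------------------------------------------------------------

_SQRT2 = math.sqrt(2.0)
_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


class _GroupedData:
    """Rows sorted by genus with reduceat boundaries for per-genus sums."""

    def __init__(self, X: np.ndarray, y: np.ndarray, genus: np.ndarray):
        order = np.argsort(genus, kind="stable")
        self.X = X[order]
        self.y = y[order]
        g = genus[order]
        self.genus_labels, starts = np.unique(g, return_index=True)
        self.starts = starts
        self.gidx = np.repeat(np.arange(len(starts)), np.diff(np.append(starts, len(g))))
        self.J = len(self.genus_labels)

    def group_sum(self, a: np.ndarray) -> np.ndarray:
        return np.add.reduceat(a, self.starts, axis=0)


class _BinomialAGHQ:
    """Negative marginal log-likelihood (and gradient) via adaptive
    Gauss–Hermite quadrature over the genus intercepts."""

    def __init__(self, data: _GroupedData, n_quad: int = 15):
        self.d = data
        z, w = np.polynomial.hermite.hermgauss(n_quad)
        self.z = z
        self.logw_corr = np.log(w) + z**2  # log w_k + z_k^2
        self.u_hat = np.zeros(data.J)  # warm-started across outer iterations

    def _modes(self, eta0: np.ndarray, sigma: float) -> tuple[np.ndarray, np.ndarray]:
        """Per-genus conditional modes and curvatures by damped Newton.

        The conditional log-density is strictly concave in u, so Newton with
        a step cap converges; the cap guards early overshoot.
        """
        d = self.d
        u = self.u_hat.copy()
        inv_s2 = 1.0 / sigma**2
        for _ in range(60):
            mu = expit(eta0 + u[d.gidx])
            grad = d.group_sum(d.y - mu) - u * inv_s2
            if np.max(np.abs(grad)) < 1e-10:
                break
            hess = -(d.group_sum(mu * (1.0 - mu)) + inv_s2)
            u = u + np.clip(-grad / hess, -4.0, 4.0)
        mu = expit(eta0 + u[d.gidx])
        curv = d.group_sum(mu * (1.0 - mu)) + inv_s2
        self.u_hat = u
        return u, curv

    def value_and_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        d = self.d
        beta, log_sigma = theta[:-1], theta[-1]
        sigma = math.exp(log_sigma)
        eta0 = d.X @ beta
        u_hat, curv = self._modes(eta0, sigma)
        tau = 1.0 / np.sqrt(curv)

        # quadrature points per genus: u_jk = u_hat_j + sqrt(2) tau_j z_k
        U = u_hat[:, None] + _SQRT2 * tau[:, None] * self.z[None, :]  # (J, K)
        eta = eta0[:, None] + U[d.gidx, :]  # (n, K)
        # row-wise Bernoulli loglik, summed per genus
        row_ll = d.y[:, None] * eta - np.logaddexp(0.0, eta)
        ll_jk = d.group_sum(row_ll)  # (J, K)
        h = ll_jk - U**2 / (2.0 * sigma**2) - log_sigma - _LOG_SQRT_2PI
        A = self.logw_corr[None, :] + h
        A_max = A.max(axis=1, keepdims=True)
        expA = np.exp(A - A_max)
        sumA = expA.sum(axis=1)
        log_int = np.log(_SQRT2 * tau) + A_max[:, 0] + np.log(sumA)
        value = -float(np.sum(log_int))

        # gradient = posterior-expected complete-data score (quadrature weights)
        omega = expA / sumA[:, None]  # (J, K)
        resid = d.y[:, None] - expit(eta)  # (n, K)
        row_w = omega[d.gidx, :]
        g_beta = d.X.T @ np.sum(row_w * resid, axis=1)
        g_logs = float(np.sum(omega * (U**2 / sigma**2 - 1.0)))
        return value, -np.concatenate([g_beta, [g_logs]])

    def exact_loglik(self, theta: np.ndarray, n_points: int = 401, span: float = 45.0) -> float:
        """High-accuracy marginal log-likelihood at ``theta``.

        The per-genus integrand is log-concave, so a dense trapezoid rule on
        an interval where the log-integrand stays within ``span`` nats of its
        mode is effectively exact.  Used for the reported log-likelihood;
        Hermite rules can be visibly off for heavily skewed boundary fits
        (huge genus variance on near-separated data).
        """
        d = self.d
        beta, log_sigma = theta[:-1], theta[-1]
        sigma = math.exp(log_sigma)
        eta0 = d.X @ beta
        u_hat, curv = self._modes(eta0, sigma)
        # half-width covering both the likelihood scale and the prior scale
        half = np.sqrt(2.0 * span) * np.maximum(1.0 / np.sqrt(curv), sigma)
        grid = np.linspace(-1.0, 1.0, n_points)
        U = u_hat[:, None] + half[:, None] * grid[None, :]  # (J, P)
        eta = eta0[:, None] + U[d.gidx, :]
        row_ll = d.y[:, None] * eta - np.logaddexp(0.0, eta)
        h = d.group_sum(row_ll) - U**2 / (2.0 * sigma**2) - log_sigma - _LOG_SQRT_2PI
        h_max = h.max(axis=1, keepdims=True)
        du = half * (2.0 / (n_points - 1))
        integral = np.trapezoid(np.exp(h - h_max), dx=1.0, axis=1) * du
        return float(np.sum(h_max[:, 0] + np.log(integral)))


def _logistic_start(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """A few ridge-damped IRLS steps of plain logistic regression."""
    beta = np.zeros(X.shape[1])
    p_bar = min(max(y.mean(), 1e-3), 1 - 1e-3)
    beta[0] = math.log(p_bar / (1 - p_bar))
    for _ in range(8):
        mu = expit(X @ beta)
        W = np.clip(mu * (1 - mu), 1e-6, None)
        H = X.T @ (W[:, None] * X) + 1e-6 * np.eye(X.shape[1])
        g = X.T @ (y - mu) - 1e-6 * beta
        beta = beta + np.linalg.solve(H, g)
        beta = np.clip(beta, -12, 12)
    return beta


_LOG_SIGMA_BOUNDS = (-7.0, 3.0)
_COEF_SANITY_BOUND = 30.0


def fit_binomial_glmm(
    dataset: Dataset,
    spec: ModelSpec,
    n_quad: int = 15,
    start_params: Optional[np.ndarray] = None,
    fix_genus_sd: Optional[float] = None,
    optimizer_options: Optional[dict] = None,
) -> FitResult:
    """Maximum-likelihood fit of a logit model with a genus random intercept.

    ``fix_genus_sd`` pins the random-effect standard deviation (0 collapses
    the model to ordinary logistic regression); otherwise it is estimated on
    the log scale, bounded away from exact zero, with a boundary fit
    reported as a near-zero variance.
    """
    if spec.response not in BINARY_RESPONSES:
        raise ValueError(f"{spec.response!r} is not a binary response")
    df = dataset.frame
    y = df[spec.response].to_numpy(float)
    X, cols = build_design(dataset, spec.fixed_predictors)
    data = _GroupedData(X, y, df["genus"].to_numpy())
    obj = _BinomialAGHQ(data, n_quad=n_quad)
    p = X.shape[1]

    if fix_genus_sd is not None and fix_genus_sd <= 1e-8:
        # degenerate limit: plain logistic regression, exact
        beta = _logistic_start(data.X, data.y)
        res = optimize.minimize(
            lambda b: _plain_logistic_nll(data.X, data.y, b),
            beta,
            jac=lambda b: -(data.X.T @ (data.y - expit(data.X @ b))),
            method="L-BFGS-B",
        )
        beta = res.x
        ll = -_plain_logistic_nll(data.X, data.y, beta)
        sigma = 0.0
        u_hat = np.zeros(data.J)
        success = bool(res.success)
    else:
        beta0 = start_params[:-1] if start_params is not None else _logistic_start(data.X, data.y)
        if fix_genus_sd is not None:
            logs0 = math.log(fix_genus_sd)
            bounds = [(None, None)] * p + [(logs0, logs0)]
        else:
            logs0 = float(start_params[-1]) if start_params is not None else math.log(0.5)
            # a warm start at the variance boundary has a flat gradient in
            # log sigma and can stall the optimiser; restart it mid-range
            logs0 = float(np.clip(logs0, math.log(0.2), math.log(2.0)))
            bounds = [(None, None)] * p + [_LOG_SIGMA_BOUNDS]
        theta0 = np.concatenate([beta0, [logs0]])
        options = {"maxiter": 500, "ftol": 1e-12, "gtol": 1e-7}
        options.update(optimizer_options or {})
        res = optimize.minimize(
            obj.value_and_grad,
            theta0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options=options,
        )
        beta = res.x[:-1]
        sigma = math.exp(res.x[-1])
        ll = -float(res.fun)
        eta0 = data.X @ beta
        u_hat, _ = obj._modes(eta0, sigma)
        success = bool(res.success) or float(np.max(np.abs(res.jac))) < 1e-3
        ll = obj.exact_loglik(res.x)

    converged = success and np.all(np.isfinite(beta)) and np.all(np.abs(beta) < _COEF_SANITY_BOUND)
    k = p + 1
    # AICc is undefined when n <= k + 1; such fits are legal (e.g. tiny
    # hold-out refits) but carry NaN and are excluded from rankings.
    aicc_val = aicc(float(ll), k, len(y)) if len(y) > k + 1 else math.nan
    return FitResult(
        spec=spec,
        coefficients={c.name: float(b) for c, b in zip(cols, beta)},
        genus_effects={g: float(u) for g, u in zip(data.genus_labels, u_hat)},
        genus_sd=float(sigma),
        residual_sd=None,
        loglik=float(ll),
        k=k,
        n=len(y),
        aicc=aicc_val,
        converged=bool(converged),
        _columns=cols,
    )


def _plain_logistic_nll(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    return float(np.sum(np.logaddexp(0.0, eta) - y * eta))


# ---------------------------------------------------------------------------
# Gaussian family
# ---------------------------------------------------------------------------


def _gaussian_profile(
    data: _GroupedData, sigma_u: float, sigma_e: float
) -> tuple[np.ndarray, float, np.ndarray]:
    """GLS beta, marginal loglik and genus modes for fixed variance parts.

    Per genus the covariance is sigma_e^2 I + sigma_u^2 J (compound
    symmetry), inverted by Woodbury; the whole computation is O(n p^2).
    """
    d = data
    s2e, s2u = sigma_e**2, sigma_u**2
    n_j = np.diff(np.append(d.starts, len(d.y)))
    lam = s2u / (s2e + n_j * s2u)  # shrinkage per genus

    def vinv(a: np.ndarray) -> np.ndarray:
        # V^{-1} a with a row-aligned array (supports 2-D)
        gs = np.add.reduceat(a, d.starts, axis=0)
        return (a - (lam[:, None] if a.ndim == 2 else lam)[d.gidx] * gs[d.gidx]) / s2e

    A = d.X.T @ vinv(d.X)
    b = d.X.T @ vinv(d.y)
    beta = np.linalg.solve(A, b)
    r = d.y - d.X @ beta
    quad = float(r @ vinv(r))
    logdet = float(np.sum(n_j * math.log(s2e) + np.log1p(n_j * s2u / s2e)))
    ll = -0.5 * (len(d.y) * math.log(2 * math.pi) + logdet + quad)
    u_hat = lam * np.add.reduceat(r, d.starts)
    return beta, ll, u_hat


def fit_gaussian_lmm(
    dataset: Dataset,
    spec: ModelSpec,
    start_params: Optional[np.ndarray] = None,
    fix_genus_sd: Optional[float] = None,
) -> FitResult:
    """ML fit of a Gaussian genus-random-intercept model for log spread rate."""
    if spec.response not in GAUSSIAN_RESPONSES:
        raise ValueError(f"{spec.response!r} is not a Gaussian response")
    df = dataset.frame
    if (df["spread_rate"] <= 0).any():
        raise ValueError("spread_rate must be strictly positive to take logs")
    y = np.log(df["spread_rate"].to_numpy(float))
    X, cols = build_design(dataset, spec.fixed_predictors)
    data = _GroupedData(X, y, df["genus"].to_numpy())

    sd_y = max(float(np.std(y)), 1e-3)

    def nll(logsd: np.ndarray) -> float:
        su = math.exp(logsd[0]) if fix_genus_sd is None else fix_genus_sd
        se = math.exp(logsd[-1])
        return -_gaussian_profile(data, su, se)[1]

    if fix_genus_sd is not None:
        x0 = np.array([math.log(sd_y)])
        bounds = [(math.log(sd_y) - 10, math.log(sd_y) + 5)]
    else:
        x0 = np.array([math.log(sd_y / 2), math.log(sd_y)])
        if start_params is not None:
            x0 = np.clip(start_params[-2:], math.log(sd_y) - 12, math.log(sd_y) + 5)
        lo, hi = math.log(sd_y) - 12, math.log(sd_y) + 5
        bounds = [(lo, hi), (lo, hi)]
    res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds, options={"ftol": 1e-13})
    if fix_genus_sd is not None:
        sigma_u, sigma_e = fix_genus_sd, math.exp(res.x[-1])
    else:
        sigma_u, sigma_e = math.exp(res.x[0]), math.exp(res.x[1])
    beta, ll, u_hat = _gaussian_profile(data, max(sigma_u, 1e-10), sigma_e)

    k = X.shape[1] + 2
    aicc_val = aicc(float(ll), k, len(y)) if len(y) > k + 1 else math.nan
    return FitResult(
        spec=spec,
        coefficients={c.name: float(b) for c, b in zip(cols, beta)},
        genus_effects={g: float(u) for g, u in zip(data.genus_labels, u_hat)},
        genus_sd=float(sigma_u),
        residual_sd=float(sigma_e),
        loglik=float(ll),
        k=k,
        n=len(y),
        aicc=aicc_val,
        converged=bool(res.success),
        _columns=cols,
    )


def fit_model(dataset: Dataset, spec: ModelSpec, **kwargs) -> FitResult:
    """Dispatch to the binomial or Gaussian fitter by response family."""
    if spec.response in BINARY_RESPONSES:
        return fit_binomial_glmm(dataset, spec, **kwargs)
    return fit_gaussian_lmm(dataset, spec, **kwargs)
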