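"""Latent-state binding model: logistic prior, NB emissions, EM fitting.

Every candidate motif i has a hidden binding state b_i in {0, 1}.  The
prior probability of binding y_i = P(b_i = 1) depends on the motif's
match quality f, TSS proximity d and conservation c through a logistic
link:

    logit(y_i) = beta0 + beta1*f_i + beta2*d_i + beta3*c_i

Conditional on the state, the flanking DNase tag count n_i follows a
negative binomial: NB(K1, r1) when bound, NB(K0, r0) when unbound, with
pmf C(n+K-1, n) (1-r)^K r^n (gamma-function form for non-integer K, so
the mean is K*r/(1-r)).  Parameters are estimated by EM: the E-step
computes posterior responsibilities gamma_i = P(b_i = 1 | f, d, c, n),
and the M-step refits the logistic coefficients on the fractional
responsibilities and each NB component by weighted maximum likelihood
(profile likelihood in K, with r profiled out at r = m/(m+K) for the
weighted mean m).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .errors import ConfigurationError, FitError

__all__ = [
    "ModelParams",
    "FitReport",
    "nb_pmf",
    "nb_logpmf",
    "logistic_prior",
    "initialize_prior_states",
    "e_step",
    "m_step",
    "observed_loglik",
    "expected_complete_loglik",
    "fit_em",
    "predict",
    "split_train_test",
    "DEFAULT_CALL_THRESHOLD",
]

DEFAULT_CALL_THRESHOLD = 0.99
_LOG_FLOOR = np.log(1e-300)


@dataclass
class ModelParams:
    """Logistic prior coefficients plus the two NB emission components."""

    beta0: float
    beta1: float
    beta2: float
    beta3: float
    K0: float
    r0: float
    K1: float
    r1: float

    def __post_init__(self) -> None:
        betas = (self.beta0, self.beta1, self.beta2, self.beta3)
        if not all(np.isfinite(b) for b in betas):
            raise ConfigurationError("non-finite logistic coefficients")
        if not (self.K0 > 0 and self.K1 > 0):
            raise ConfigurationError("NB size parameters K must be positive")
        if not (0 < self.r0 < 1 and 0 < self.r1 < 1):
            raise ConfigurationError("NB probabilities r must lie in (0, 1)")

    @property
    def unbound_mean(self) -> float:
        return self.K0 * self.r0 / (1 - self.r0)

    @property
    def bound_mean(self) -> float:
        return self.K1 * self.r1 / (1 - self.r1)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**{k: d[k] for k in ("beta0", "beta1", "beta2", "beta3", "K0", "r0", "K1", "r1")})


@dataclass
class FitReport:
    """EM diagnostics: log-likelihood trajectory and convergence flag."""

    iterations: int = 0
    loglik: list[float] = field(default_factory=list)
    converged: bool = False
    seed: int | None = None


def nb_logpmf(n, K: float, r: float):
    """Log pmf of NB(K, r): C(n+K-1, n) (1-r)^K r^n (mean K r / (1-r))."""
    if K <= 0 or not (0 < r < 1):
        raise ConfigurationError(f"invalid NB parameters K={K}, r={r}")
    # scipy's nbinom counts failures n before K successes with success
    # probability p, pmf C(n+K-1, n) p^K (1-p)^n; our r is 1 - p.
    return stats.nbinom.logpmf(n, K, 1.0 - r)


def nb_pmf(n, K: float, r: float):
    return np.exp(nb_logpmf(n, K, r))


def logistic_prior(params: ModelParams, f, d, c):
    """Prior binding probability from the logistic link."""
    s = params.beta0 + params.beta1 * np.asarray(f) + params.beta2 * np.asarray(d) + params.beta3 * np.asarray(c)
    return special.expit(s)


def initialize_prior_states(n_counts, top_fraction: float = 0.05) -> np.ndarray:
    """Hard initial responsibilities: top fraction of tag counts bound.

    The cutoff is the count of the ceil(top_fraction * N)-th largest motif;
    ties at the cutoff are all initialized bound.  Degenerate count vectors
    (all equal, hence no top stratum) are rejected.
    """
    counts = np.asarray(n_counts)
    n = counts.size
    if n < 20:
        raise FitError("too few motifs to initialize (need >= 20)")
    if counts.max() == counts.min():
        raise FitError(
            "all tag counts identical: cannot pick a top stratum; "
            "use a larger or more varied motif set"
        )
    k = max(1, int(round(top_fraction * n)))
    cutoff = np.sort(counts)[::-1][k - 1]
    init = (counts >= cutoff).astype(float)
    if init.all():
        raise FitError("top-count initialization is degenerate (everything bound)")
    return init


def _component_logpmf(params: ModelParams, n):
    lp0 = np.maximum(nb_logpmf(n, params.K0, params.r0), _LOG_FLOOR)
    lp1 = np.maximum(nb_logpmf(n, params.K1, params.r1), _LOG_FLOOR)
    return lp0, lp1


def e_step(params: ModelParams, features: pd.DataFrame) -> np.ndarray:
    """Posterior responsibilities gamma_i = P(b_i=1 | f, d, c, n)."""
    y = logistic_prior(params, features["f"], features["d"], features["c"])
    lp0, lp1 = _component_logpmf(params, features["n"].to_numpy())
    with np.errstate(divide="ignore"):
        a1 = np.log(y) + lp1
        a0 = np.log1p(-y) + lp0
    return special.expit(a1 - a0)


def observed_loglik(params: ModelParams, features: pd.DataFrame) -> float:
    """Marginal log-likelihood of the tag counts given the features."""
    y = logistic_prior(params, features["f"], features["d"], features["c"])
    lp0, lp1 = _component_logpmf(params, features["n"].to_numpy())
    with np.errstate(divide="ignore"):
        a = np.stack([np.log1p(-y) + lp0, np.log(y) + lp1])
    return float(special.logsumexp(a, axis=0).sum())


def expected_complete_loglik(params: ModelParams, features: pd.DataFrame, gamma) -> float:
    """E-step objective the M-step maximizes, at fixed responsibilities."""
    gamma = np.asarray(gamma, dtype=float)
    y = logistic_prior(params, features["f"], features["d"], features["c"])
    lp0, lp1 = _component_logpmf(params, features["n"].to_numpy())
    s = params.beta0 + params.beta1 * features["f"] + params.beta2 * features["d"] + params.beta3 * features["c"]
    s = s.to_numpy(float)
    prior_term = gamma * special.log_expit(s) + (1 - gamma) * special.log_expit(-s)
    return float(np.sum(prior_term + gamma * lp1 + (1 - gamma) * lp0))


def _fit_weighted_logistic(X: np.ndarray, gamma: np.ndarray, x0: np.ndarray) -> np.ndarray:
    """Maximize sum_i [gamma_i log y_i + (1-gamma_i) log(1-y_i)] over betas."""

    def negloglik(beta):
        s = X @ beta
        return -np.sum(gamma * special.log_expit(s) + (1 - gamma) * special.log_expit(-s))

    def grad(beta):
        y = special.expit(X @ beta)
        return X.T @ (y - gamma)

    res = optimize.minimize(negloglik, x0, jac=grad, method="BFGS")
    # BFGS may report line-search failure at an already-optimal point;
    # accept any solution not worse than the start.
    if negloglik(res.x) > negloglik(x0) + 1e-9:
        raise FitError(f"logistic M-step failed: {res.message}")
    return res.x


def _fit_weighted_nb(n: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted NB MLE via profile likelihood in K.

    For fixed K the weighted MLE of r solves mean = K r/(1-r), i.e.
    r = m/(m+K); the remaining 1-D profile is maximized over log K.
    """
    wsum = w.sum()
    if wsum <= 0:
        raise FitError("NB component received zero total weight")
    m = float(np.dot(w, n) / wsum)
    if m <= 0:
        # all mass on zero counts: NB degenerates toward a point mass at 0
        return 1.0, 1e-8

    def neg_profile(logK):
        K = np.exp(logK)
        r = m / (m + K)
        ll = np.dot(
            w,
            special.gammaln(n + K) - special.gammaln(K) - special.gammaln(n + 1.0)
            + n * np.log(r),
        ) + wsum * K * np.log1p(-r)
        return -ll

    res = optimize.minimize_scalar(neg_profile, bounds=(-12.0, 12.0), method="bounded")
    if not res.success:
        raise FitError("NB M-step profile optimization failed")
    K = float(np.exp(res.x))
    r = m / (m + K)
    return K, float(np.clip(r, 1e-12, 1 - 1e-12))


def m_step(features: pd.DataFrame, gamma: np.ndarray, previous: ModelParams | None = None) -> ModelParams:
    """Maximize the expected complete-data log-likelihood given gamma."""
    gamma = np.asarray(gamma, dtype=float)
    if np.any((gamma < 0) | (gamma > 1)):
        raise FitError("responsibilities must lie in [0, 1]")
    if np.ptp(gamma) == 0:
        raise FitError("all responsibilities identical: mixture unidentifiable")
    X = np.column_stack(
        [
            np.ones(len(features)),
            features["f"].to_numpy(float),
            features["d"].to_numpy(float),
            features["c"].to_numpy(float),
        ]
    )
    x0 = (
        np.array([previous.beta0, previous.beta1, previous.beta2, previous.beta3])
        if previous is not None
        else np.zeros(4)
    )
    betas = _fit_weighted_logistic(X, gamma, x0)
    n = features["n"].to_numpy(float)
    K1, r1 = _fit_weighted_nb(n, gamma)
    K0, r0 = _fit_weighted_nb(n, 1.0 - gamma)
    return ModelParams(*betas, K0=K0, r0=r0, K1=K1, r1=r1)


def fit_em(
    features: pd.DataFrame,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int | None = None,
    top_fraction: float = 0.05,
    init_gamma: np.ndarray | None = None,
) -> tuple[ModelParams, FitReport]:
    """Fit the model by EM from the top-tag-count initialization.

    Convergence is declared when the relative change of the observed-data
    log-likelihood falls below ``tol``.  The trajectory is checked to be
    non-decreasing (up to numerical tolerance) at every step; a decrease
    is a hard error since EM guarantees monotonicity.
    """
    if len(features) < 1000:
        warnings.warn(
            f"fitting on {len(features)} motifs; >= 1000 recommended", stacklevel=2
        )
    report = FitReport(seed=seed)
    gamma = (
        np.asarray(init_gamma, dtype=float)
        if init_gamma is not None
        else initialize_prior_states(features["n"].to_numpy(), top_fraction)
    )
    params = m_step(features, gamma)
    ll = observed_loglik(params, features)
    report.loglik.append(ll)
    for it in range(1, max_iter + 1):
        gamma = e_step(params, features)
        params = m_step(features, gamma, previous=params)
        new_ll = observed_loglik(params, features)
        if new_ll < ll - 1e-6 * max(1.0, abs(ll)):
            raise FitError(
                f"log-likelihood decreased at iteration {it}: {ll} -> {new_ll}"
            )
        report.loglik.append(new_ll)
        report.iterations = it
        if abs(new_ll - ll) <= tol * max(1.0, abs(ll)):
            report.converged = True
            ll = new_ll
            break
        ll = new_ll
    else:
        warnings.warn(f"EM did not converge in {max_iter} iterations", stacklevel=2)
    return params, report


def predict(
    params: ModelParams,
    features: pd.DataFrame,
    threshold: float = DEFAULT_CALL_THRESHOLD,
) -> pd.DataFrame:
    """One E-step pass: per-motif prior, posterior and hard call."""
    y = logistic_prior(params, features["f"], features["d"], features["c"])
    gamma = e_step(params, features)
    out = features.copy()
    out["y"] = np.asarray(y)
    out["gamma"] = gamma
    out["call"] = gamma >= threshold
    return out


def split_train_test(
    features: pd.DataFrame, n_train: int = 10000, n_test: int = 10000, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint uniform train/test samples of motifs, without replacement.

    If the population is smaller than n_train + n_test, both sizes are
    scaled down proportionally (with a warning).
    """
    n = len(features)
    if n < n_train + n_test:
        scale = n / (n_train + n_test)
        n_train = max(1, int(n_train * scale))
        n_test = max(1, n - n_train)
        warnings.warn(
            f"population {n} smaller than requested split; using {n_train}/{n_test}",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=n_train + n_test, replace=False)
    return (
        features.iloc[idx[:n_train]].reset_index(drop=True),
        features.iloc[idx[n_train:]].reset_index(drop=True),
    )
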