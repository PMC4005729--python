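"""Binomial N-mixture models for repeated-count surveys under imperfect detection.

The hierarchical model: latent site abundance ``N_i ~ dist(lambda_i)`` with
``log lambda_i`` linear in site covariates, and observed counts
``y_ij ~ Binomial(N_i, p_ij)`` with ``logit p_ij`` linear in observation- and
site-level covariates. ``dist`` is Poisson, negative binomial (mean/size
parameterisation, variance lambda + lambda^2/size) or zero-inflated Poisson
(point mass psi at zero mixed with Poisson(lambda)).

The likelihood marginalises the latent abundance by summing from the largest
observed count at each site up to a truncation bound K:

    L_i = sum_{N=max_j y_ij}^{K} f(N | lambda_i) * prod_j C(N, y_ij)
          p_ij^{y_ij} (1 - p_ij)^{N - y_ij}

Missing counts are allowed and simply dropped from the inner product.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, gammaln, logsumexp
from statsmodels.tools.numdiff import approx_hess2

from .design import build_obs_design, build_site_design, profile_row

FAMILIES = ("poisson", "negbin", "zip")

_LGAM = np.array([0.0])  # gammaln(arange(n)) cache, grown on demand


def _lgam_table(n: int) -> np.ndarray:
    global _LGAM
    if len(_LGAM) < n:
        _LGAM = gammaln(np.arange(max(n, 2 * len(_LGAM)), dtype=float))
    return _LGAM


@dataclass
class CountData:
    """Site x survey counts plus covariates.

    counts: float matrix (R x J), NaN marks a missing survey.
    site_covariates: one row per site (e.g. invader status, habitat class).
    obs_covariates: name -> (R x J) numeric array (e.g. cloud %, temperature).
    """

    counts: np.ndarray
    site_covariates: pd.DataFrame
    obs_covariates: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D site x survey matrix")
        if len(self.site_covariates) != self.counts.shape[0]:
            raise ValueError("site covariate table does not match count rows")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.counts, initial=0) < 0:
                raise ValueError("counts must be non-negative")
        for name, arr in self.obs_covariates.items():
            if np.shape(arr) != self.counts.shape:
                raise ValueError(f"observation covariate {name!r} does not match counts")

    @property
    def n_sites(self) -> int:
        return self.counts.shape[0]

    @property
    def n_surveys(self) -> int:
        return self.counts.shape[1]

    @property
    def max_count(self) -> int:
        if np.all(np.isnan(self.counts)):
            return 0
        return int(np.nanmax(self.counts))


@dataclass
class ModelSpec:
    """One candidate model: family plus covariate terms for each level."""

    family: str = "poisson"
    abundance_terms: list[str] = field(default_factory=list)
    detection_terms: list[str] = field(default_factory=list)
    truncation_K: int | None = None  # default: max observed count + 100

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")

    def label(self) -> str:
        det = "+".join(self.detection_terms) or "1"
        ab = "+".join(self.abundance_terms) or "1"
        return f"p({det}) lam({ab}) [{self.family}]"


@dataclass
class NMixtureFit:
    """A fitted N-mixture model on the link scales."""

    spec: ModelSpec
    params: np.ndarray
    param_names: list[str]
    log_likelihood: float
    n_params: int
    converged: bool
    boundary: bool
    se: np.ndarray | None
    cov: np.ndarray | None
    truncation_K: int
    data: CountData
    abundance_infos: list[dict]
    detection_infos: list[dict]
    n_abundance: int
    n_detection: int

    @property
    def se_available(self) -> bool:
        return self.se is not None

    def coef_table(self) -> pd.DataFrame:
        se = self.se if self.se is not None else np.full(len(self.params), np.nan)
        return pd.DataFrame({"estimate": self.params, "se": se}, index=self.param_names)

    def extra_param(self) -> float | None:
        """log(size) for negbin, logit(psi) for zip, None for poisson."""
        if self.spec.family == "poisson":
            return None
        return float(self.params[-1])


def _designs(data: CountData, spec: ModelSpec):
    Xa, a_names, a_infos = build_site_design(data.site_covariates, spec.abundance_terms)
    Xd, d_names, d_infos = build_obs_design(
        data.obs_covariates, data.site_covariates, spec.detection_terms, data.n_surveys
    )
    extra = []
    if spec.family == "negbin":
        extra = ["log(size)"]
    elif spec.family == "zip":
        extra = ["logit(psi)"]
    names = [f"lam:{n}" for n in a_names] + [f"p:{n}" for n in d_names] + extra
    return Xa, Xd, a_infos, d_infos, names


def _resolve_K(data: CountData, spec: ModelSpec) -> int:
    K = spec.truncation_K if spec.truncation_K is not None else data.max_count + 100
    if K < data.max_count:
        raise ValueError(f"truncation_K={K} is below the maximum observed count {data.max_count}")
    return int(K)


def _count_logpmf(N: np.ndarray, log_lam: np.ndarray, family: str, extra: float | None,
                  lgam: np.ndarray) -> np.ndarray:
    """log f(N | lambda_i) for each site (rows) and N value (columns)."""
    lam = np.exp(log_lam)[:, None]
    llam = log_lam[:, None]
    Nn = N[None, :]
    with np.errstate(invalid="ignore"):
        pois = np.where(Nn == 0, -lam, Nn * llam - lam - lgam[Nn + 1])
    if family == "poisson":
        return pois
    if family == "zip":
        a = extra  # logit of the zero-inflation probability psi
        log_psi = -np.logaddexp(0.0, -a)
        log_1mpsi = -np.logaddexp(0.0, a)
        out = log_1mpsi + pois
        out[:, 0] = np.logaddexp(log_psi, out[:, 0])
        return out
    # negbin: size k, p = k/(k+lam); stable via log(k+lam) = logaddexp(log k, log lam)
    log_k = extra
    k = np.exp(log_k)
    log_kplam = np.logaddexp(log_k, llam)
    with np.errstate(invalid="ignore"):
        term_n = np.where(Nn == 0, 0.0, Nn * (llam - log_kplam))
    return gammaln(Nn + k) - gammaln(k) - lgam[Nn + 1] + k * (log_k - log_kplam) + term_n


def _loglik_core(y: np.ndarray, obs_mask: np.ndarray, Xa: np.ndarray, Xd: np.ndarray,
                 params: np.ndarray, family: str, K: int, block: int = 512) -> float:
    n_a = Xa.shape[1]
    n_d = Xd.shape[2]
    beta = params[:n_a]
    alpha = params[n_a:n_a + n_d]
    extra = float(params[-1]) if family != "poisson" else None
    if not np.all(np.isfinite(beta)) or (family != "poisson" and not np.isfinite(extra)):
        raise ValueError("non-finite parameters")

    log_lam = Xa @ beta
    eta = np.tensordot(Xd, alpha, axes=([2], [0]))  # (R, J)
    with np.errstate(over="ignore"):
        lp = -np.logaddexp(0.0, -eta)   # log p
        l1p = -np.logaddexp(0.0, eta)   # log (1 - p)

    N = np.arange(K + 1)
    lgam = _lgam_table(K + 2)
    yi = np.where(obs_mask, np.nan_to_num(y), 0.0).astype(np.int64)

    total = 0.0
    R = y.shape[0]
    for lo in range(0, R, block):
        sl = slice(lo, min(lo + block, R))
        yb = yi[sl][:, :, None]
        mb = obs_mask[sl][:, :, None]
        d = N[None, None, :] - yb
        valid = d >= 0
        dc = np.where(valid, d, 0)
        logC = lgam[yb + dc + 1] - lgam[yb + 1] - lgam[dc + 1]
        with np.errstate(invalid="ignore"):
            t_succ = np.where(yb == 0, 0.0, yb * lp[sl][:, :, None])
            t_fail = np.where(dc == 0, 0.0, dc * l1p[sl][:, :, None])
        binom = np.where(valid, logC + t_succ + t_fail, -np.inf)
        binom = np.where(mb, binom, 0.0)
        site_binom = binom.sum(axis=1)  # (r, K+1)
        logf = _count_logpmf(N, log_lam[sl], family, extra, lgam)
        total += float(logsumexp(logf + site_binom, axis=1).sum())
    return total


def nmixture_loglik(data: CountData, spec: ModelSpec, params: np.ndarray) -> float:
    """Integrated N-mixture log-likelihood at the given link-scale parameters.

    Parameter order: abundance coefficients (log link, intercept first), then
    detection coefficients (logit link, intercept first), then log(size) for
    negbin or logit(psi) for zip.
    """
    Xa, Xd, _, _, names = _designs(data, spec)
    params = np.asarray(params, dtype=float)
    if len(params) != len(names):
        raise ValueError(f"expected {len(names)} parameters ({names}), got {len(params)}")
    K = _resolve_K(data, spec)
    obs_mask = ~np.isnan(data.counts)
    return _loglik_core(data.counts, obs_mask, Xa, Xd, params, spec.family, K)


def _default_starts(data: CountData, n_a: int, n_d: int, family: str) -> np.ndarray:
    site_max = np.nanmax(np.nan_to_num(data.counts), axis=1)
    lam0 = max(np.mean(site_max), 0.5) / 0.5  # crude: assume p ~ 0.5
    x0 = np.zeros(n_a + n_d + (0 if family == "poisson" else 1))
    x0[0] = np.log(lam0)
    if family == "negbin":
        x0[-1] = 0.0       # size = 1
    elif family == "zip":
        x0[-1] = -1.0      # psi ~ 0.27
    return x0


def _cov_from_hessian(H: np.ndarray) -> tuple[np.ndarray | None, np.ndarray | None]:
    """Invert the observed information; parameters with (numerically) zero
    curvature — typically boundary estimates — get NaN variance and the
    remaining block is inverted on its own. Returns (None, None) if nothing
    invertible remains."""
    def _try_inv(M):
        try:
            C = np.linalg.inv(M)
        except np.linalg.LinAlgError:
            return None
        d = np.diag(C)
        if np.all(np.isfinite(d)) and np.all(d > 0):
            return C
        return None

    C = _try_inv(H)
    if C is not None:
        return C, np.sqrt(np.diag(C))
    diag = np.abs(np.diag(H))
    keep = diag > 1e-8 * max(1.0, diag.max())
    if keep.sum() == 0:
        return None, None
    sub = _try_inv(H[np.ix_(keep, keep)])
    if sub is None:
        return None, None
    cov = np.full_like(H, np.nan, dtype=float)
    cov[np.ix_(keep, keep)] = sub
    se = np.sqrt(np.where(keep, np.diag(cov), np.nan))
    return cov, se


def fit(data: CountData, spec: ModelSpec, starts: np.ndarray | None = None,
        seed: int = 0, compute_se: bool = True) -> NMixtureFit:
    """Maximise the integrated likelihood by quasi-Newton iteration.

    Standard errors come from the inverse of the numerically-evaluated
    observed information at the optimum; a singular information matrix leaves
    them flagged unavailable rather than silently wrong.
    """
    obs_mask = ~np.isnan(data.counts)
    if not obs_mask.any():
        raise ValueError("no non-missing counts to fit")
    Xa, Xd, a_infos, d_infos, names = _designs(data, spec)
    K = _resolve_K(data, spec)
    n_a, n_d = Xa.shape[1], Xd.shape[2]
    y = data.counts

    def nll(x):
        try:
            return -_loglik_core(y, obs_mask, Xa, Xd, x, spec.family, K)
        except (ValueError, FloatingPointError):
            return np.inf

    x0 = np.asarray(starts, dtype=float) if starts is not None else _default_starts(
        data, n_a, n_d, spec.family)
    if len(x0) != len(names):
        raise ValueError(f"expected {len(names)} starting values, got {len(x0)}")

    res = minimize(nll, x0, method="BFGS", options={"gtol": 1e-5, "maxiter": 500})
    if not res.success:
        res2 = minimize(nll, res.x, method="Nelder-Mead",
                        options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-8})
        if res2.fun <= res.fun:
            res = res2

    params = res.x
    ll = -res.fun
    converged = bool(res.success) and np.isfinite(ll)
    # boundary diagnosis: extreme link parameters, or fitted rates pinned at
    # the edge of their range (lambda ~ 0, p ~ 0 or 1)
    lam_fit = np.exp(Xa @ params[:n_a])
    p_fit = expit(np.tensordot(Xd, params[n_a:n_a + n_d], axes=([2], [0])))
    boundary = bool(np.max(np.abs(params)) > 10.0 or lam_fit.min() < 1e-2
                    or p_fit.min() < 1e-3 or p_fit.max() > 1 - 1e-3)
    # a fitted mean above the truncation bound means the latent sum was cut
    # off mid-mass: the optimum is an artifact of the bound, not a real MLE
    if lam_fit.max() > K:
        converged = False

    se = cov = None
    if compute_se and converged:
        try:
            H = approx_hess2(params, nll)
            cov, se = _cov_from_hessian(H)
        except (np.linalg.LinAlgError, ValueError):
            se = cov = None

    return NMixtureFit(
        spec=spec, params=params, param_names=names, log_likelihood=float(ll),
        n_params=len(params), converged=converged, boundary=boundary,
        se=se, cov=cov, truncation_K=K, data=data,
        abundance_infos=a_infos, detection_infos=d_infos,
        n_abundance=n_a, n_detection=n_d,
    )


@dataclass
class Prediction:
    estimate: float
    se: float
    lower: float
    upper: float


def predict(fit_result: NMixtureFit, target: str, covariate_profile: dict) -> Prediction:
    """Covariate-conditional abundance or detection with a 95% Wald CI.

    The CI is a delta-method interval on the response scale; abundance is
    floored at 0 and detection clipped to [0, 1].
    """
    if target not in ("abundance", "detection"):
        raise ValueError("target must be 'abundance' or 'detection'")
    if fit_result.se is None:
        raise ValueError("standard errors unavailable; cannot form confidence interval")
    n_a, n_d = fit_result.n_abundance, fit_result.n_detection
    if target == "abundance":
        x = profile_row(fit_result.abundance_infos, covariate_profile)
        idx = slice(0, n_a)
    else:
        x = profile_row(fit_result.detection_infos, covariate_profile)
        idx = slice(n_a, n_a + n_d)
    coef = fit_result.params[idx]
    V = fit_result.cov[idx, :][:, idx]
    if not np.all(np.isfinite(V)):
        raise ValueError("covariance unavailable for the requested coefficients")
    eta = float(x @ coef)
    se_eta = float(np.sqrt(x @ V @ x))
    if target == "abundance":
        est = np.exp(eta)
        se_resp = est * se_eta
        lo = max(est - 1.96 * se_resp, 0.0)
        hi = est + 1.96 * se_resp
    else:
        est = expit(eta)
        se_resp = est * (1 - est) * se_eta
        lo = max(est - 1.96 * se_resp, 0.0)
        hi = min(est + 1.96 * se_resp, 1.0)
    return Prediction(float(est), float(se_resp), float(lo), float(hi))


def percent_decline(lambda_without: float, lambda_with: float) -> float:
    """Percent decline in abundance relative to a baseline: 100*(1 - with/without)."""
    if lambda_without <= 0:
        raise ValueError("baseline abundance must be positive")
    return 100.0 * (1.0 - lambda_with / lambda_without)


def expected_counts(fit_result: NMixtureFit) -> np.ndarray:
    """Model-expected count for every (site, survey) cell: E[y_ij] = E[N_i] p_ij.

    For zip, E[N_i] = (1 - psi) lambda_i; for negbin the mean is lambda_i.
    """
    lam, p = fitted_rates(fit_result)
    return lam[:, None] * p


def fitted_rates(fit_result: NMixtureFit) -> tuple[np.ndarray, np.ndarray]:
    """(E[N_i] per site, p_ij per cell) at the fitted parameters."""
    data, spec = fit_result.data, fit_result.spec
    Xa, Xd, _, _, _ = _designs(data, spec)
    n_a, n_d = fit_result.n_abundance, fit_result.n_detection
    beta = fit_result.params[:n_a]
    alpha = fit_result.params[n_a:n_a + n_d]
    lam = np.exp(Xa @ beta)
    if spec.family == "zip":
        lam = lam * (1.0 - expit(fit_result.params[-1]))
    p = expit(np.tensordot(Xd, alpha, axes=([2], [0])))
    return lam, p


def simulate_from_fit(fit_result: NMixtureFit, rng: np.random.Generator) -> np.ndarray:
    """Draw one replicate count matrix from the fitted model (parametric bootstrap).

    Latent abundance is drawn from the fitted family, counts are binomial
    thinnings; the missing-data pattern of the original counts is preserved.
    """
    data, spec = fit_result.data, fit_result.spec
    Xa, Xd, _, _, _ = _designs(data, spec)
    n_a, n_d = fit_result.n_abundance, fit_result.n_detection
    lam = np.exp(Xa @ fit_result.params[:n_a])
    p = expit(np.tensordot(Xd, fit_result.params[n_a:n_a + n_d], axes=([2], [0])))
    N = draw_latent_abundance(lam, spec.family, fit_result.extra_param(), rng)
    y = rng.binomial(N[:, None], p).astype(float)
    y[np.isnan(data.counts)] = np.nan
    return y


def draw_latent_abundance(lam: np.ndarray, family: str, extra_link: float | None,
                          rng: np.random.Generator) -> np.ndarray:
    """Draw per-site latent abundance N_i from the stated family.

    extra_link is log(size) for negbin and logit(psi) for zip.
    """
    lam = np.asarray(lam, dtype=float)
    if family == "poisson":
        return rng.poisson(lam)
    if family == "negbin":
        k = np.exp(extra_link)
        return rng.negative_binomial(k, k / (k + lam))
    if family == "zip":
        psi = expit(extra_link)
        N = rng.poisson(lam)
        N[rng.random(lam.shape) < psi] = 0
        return N
    raise ValueError(f"unknown family {family!r}")
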