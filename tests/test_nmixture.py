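"""Unit tests for the integrated N-mixture likelihood, fitting and prediction."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import binom, nbinom, poisson

import nmixsdm as nx
from nmixsdm.nmixture import _designs, draw_latent_abundance


def naive_loglik(y, lam, p, family, K, size=None, psi=None):
    """Brute-force oracle: enumerate the latent abundance with scipy pmfs.

    y: (R, J) counts (NaN = missing); lam: (R,); p: (R, J).
    """
    total = 0.0
    R, J = y.shape
    for i in range(R):
        site = 0.0
        for N in range(K + 1):
            if family == "poisson":
                fN = poisson.pmf(N, lam[i])
            elif family == "negbin":
                fN = nbinom.pmf(N, size, size / (size + lam[i]))
            else:
                fN = (1 - psi) * poisson.pmf(N, lam[i]) + (psi if N == 0 else 0.0)
            prod = fN
            for j in range(J):
                if not np.isnan(y[i, j]):
                    prod *= binom.pmf(y[i, j], N, p[i, j])
            site += prod
        total += np.log(site)
    return total


def random_instance(rng, family):
    R = rng.integers(1, 5)
    J = rng.integers(1, 4)
    y = rng.integers(0, 6, size=(R, J)).astype(float)
    site = pd.DataFrame({"x": rng.normal(size=R)})
    obs = {"w": rng.normal(size=(R, J))}
    data = nx.CountData(counts=y, site_covariates=site, obs_covariates=obs)
    spec = nx.ModelSpec(family=family, abundance_terms=["x"], detection_terms=["w"],
                        truncation_K=40)
    params = np.concatenate([
        rng.normal(0.5, 0.5, 2),      # abundance: intercept + slope
        rng.normal(0.0, 0.7, 2),      # detection: intercept + slope
        rng.normal(0.0, 0.5, 1) if family != "poisson" else [],
    ])
    return data, spec, params


def link_scale_rates(data, spec, params):
    Xa, Xd, _, _, _ = _designs(data, spec)
    na, nd = Xa.shape[1], Xd.shape[2]
    lam = np.exp(Xa @ params[:na])
    p = expit(np.tensordot(Xd, params[na:na + nd], axes=([2], [0])))
    return lam, p


@pytest.mark.parametrize("family", ["poisson", "negbin", "zip"])
def test_loglik_matches_bruteforce_enumeration(family):
    rng = np.random.default_rng(123)
    for _ in range(25):
        data, spec, params = random_instance(rng, family)
        lam, p = link_scale_rates(data, spec, params)
        size = np.exp(params[-1]) if family == "negbin" else None
        psi = expit(params[-1]) if family == "zip" else None
        expected = naive_loglik(data.counts, lam, p, family, 40, size=size, psi=psi)
        got = nx.nmixture_loglik(data, spec, params)
        assert got == pytest.approx(expected, abs=1e-8)


def test_perfect_detection_collapses_to_count_pmf():
    """With p = 1 the binomial mixture reduces to the count distribution of y."""
    data = nx.CountData(counts=np.array([[3.0]]),
                        site_covariates=pd.DataFrame(index=[0]))
    spec = nx.ModelSpec(family="poisson", truncation_K=60)
    ll = nx.nmixture_loglik(data, spec, [np.log(2.0), np.inf])
    assert ll == pytest.approx(poisson.logpmf(3, 2.0), abs=1e-10)


def test_missing_cells_are_dropped():
    y = np.array([[2.0, np.nan], [1.0, 0.0]])
    data = nx.CountData(counts=y, site_covariates=pd.DataFrame(index=range(2)))
    spec = nx.ModelSpec(family="poisson", truncation_K=40)
    params = [np.log(3.0), 0.2]
    lam, p = link_scale_rates(data, spec, params)
    expected = naive_loglik(y, lam, p, "poisson", 40)
    assert nx.nmixture_loglik(data, spec, params) == pytest.approx(expected, abs=1e-8)


def test_zip_at_zero_inflation_reduces_to_poisson(intercept_data):
    spec_p = nx.ModelSpec(family="poisson")
    spec_z = nx.ModelSpec(family="zip")
    params = [np.log(8.0), 0.4]
    ll_p = nx.nmixture_loglik(intercept_data, spec_p, params)
    ll_z = nx.nmixture_loglik(intercept_data, spec_z, params + [-35.0])  # psi -> 0
    assert ll_z == pytest.approx(ll_p, abs=1e-6)


def test_negbin_at_large_size_reduces_to_poisson(intercept_data):
    spec_p = nx.ModelSpec(family="poisson")
    spec_n = nx.ModelSpec(family="negbin")
    params = [np.log(8.0), 0.4]
    ll_p = nx.nmixture_loglik(intercept_data, spec_p, params)
    ll_n = nx.nmixture_loglik(intercept_data, spec_n, params + [np.log(1e6)])
    assert ll_n == pytest.approx(ll_p, abs=1e-3)


def test_truncation_stability(intercept_data):
    """Raising the truncation bound by 50 leaves the likelihood unchanged."""
    f = nx.fit(intercept_data, nx.ModelSpec(family="poisson"))
    spec_hi = nx.ModelSpec(family="poisson", truncation_K=f.truncation_K + 50)
    ll_hi = nx.nmixture_loglik(intercept_data, spec_hi, f.params)
    assert abs(ll_hi - f.log_likelihood) < 1e-6


def test_truncation_below_max_count_rejected(small_counts):
    spec = nx.ModelSpec(family="poisson", truncation_K=2)
    with pytest.raises(ValueError, match="truncation"):
        nx.nmixture_loglik(small_counts, spec, [0.0, 0.0])


def test_adding_covariate_never_decreases_loglik(small_counts):
    base = nx.fit(small_counts, nx.ModelSpec(family="poisson"))
    richer = nx.fit(small_counts, nx.ModelSpec(family="poisson",
                                               abundance_terms=["status"]))
    assert richer.log_likelihood >= base.log_likelihood - 1e-6


def test_recovery_under_perfect_detection():
    """With p = 1 forced, the abundance MLE equals the Poisson regression MLE."""
    rng = np.random.default_rng(5)
    R = 500
    N = rng.poisson(6.0, size=R)
    y = np.repeat(N[:, None], 3, axis=1).astype(float)  # p = 1: y = N each survey
    data = nx.CountData(counts=y, site_covariates=pd.DataFrame(index=range(R)))
    f = nx.fit(data, nx.ModelSpec(family="poisson", truncation_K=int(y.max()) + 30))
    lam_hat = np.exp(f.params[0])
    se_lam = lam_hat * f.se[0]
    assert f.converged
    assert abs(lam_hat - 6.0) < 3 * max(se_lam, np.sqrt(6.0 / R))


def test_all_zero_counts_flagged_boundary():
    data = nx.CountData(counts=np.zeros((10, 3)),
                        site_covariates=pd.DataFrame(index=range(10)))
    f = nx.fit(data, nx.ModelSpec(family="poisson", truncation_K=30))
    assert f.boundary
    assert np.exp(f.params[0]) < 0.1  # lambda driven to the zero boundary


def test_predict_intercept_only_identities(intercept_data):
    f = nx.fit(intercept_data, nx.ModelSpec(family="poisson"))
    pred = nx.predict(f, "abundance", {})
    assert pred.estimate == pytest.approx(np.exp(f.params[0]))
    assert pred.lower >= 0.0
    det = nx.predict(f, "detection", {})
    assert 0.0 <= det.lower <= det.estimate <= det.upper <= 1.0


def test_predict_requires_profile_covariates(small_counts):
    f = nx.fit(small_counts, nx.ModelSpec(family="poisson",
                                          abundance_terms=["status"]))
    with pytest.raises(KeyError, match="status"):
        nx.predict(f, "abundance", {})


@pytest.mark.parametrize("without,with_,expected", [
    (10.0, 10.0, 0.0),
    (10.0, 0.0, 100.0),
    (13.3, 1.6, 87.9699248),
])
def test_percent_decline(without, with_, expected):
    assert nx.percent_decline(without, with_) == pytest.approx(expected, abs=1e-4)


def test_percent_decline_rejects_bad_baseline():
    with pytest.raises(ValueError):
        nx.percent_decline(0.0, 1.0)


@pytest.mark.parametrize("family,extra", [
    ("poisson", None), ("negbin", np.log(2.0)), ("zip", 0.0),
])
def test_latent_abundance_moments(family, extra):
    """Marginal mean/variance of the latent draw match the family's moments."""
    rng = np.random.default_rng(99)
    lam = np.full(20000, 5.0)
    N = draw_latent_abundance(lam, family, extra, rng)
    if family == "poisson":
        mean, var = 5.0, 5.0
    elif family == "negbin":
        mean, var = 5.0, 5.0 + 25.0 / 2.0
        assert N.var() > N.mean()  # over-dispersion relative to Poisson
    else:
        psi = 0.5
        mean = (1 - psi) * 5.0
        var = (1 - psi) * 5.0 + psi * (1 - psi) * 25.0
    assert N.mean() == pytest.approx(mean, abs=3 * np.sqrt(var / 20000))
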