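"""AICc model ranking and parametric-bootstrap goodness of fit.

AICc = -2 loglik + 2K + 2K(K+1)/(n - K - 1), the small-sample correction
recommended when n/K < 40. The likelihood unit for N-mixture models is the
site, so n defaults to the number of sites.

Adequacy is assessed with a Pearson chi-squared statistic compared against
its distribution under the fitted model: datasets are simulated from the
fitted model, refitted, and the statistic recomputed. c_hat (observed /
mean bootstrap statistic) > 1 indicates over-dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nmixture
from .nmixture import CountData, NMixtureFit

CHI2_EPS = 0.5  # guard added to expected counts in the chi-squared denominator


def aicc(log_likelihood: float, n_params: int, n_units: int) -> float:
    """Corrected Akaike Information Criterion."""
    denom = n_units - n_params - 1
    if denom <= 0:
        raise ValueError(f"AICc undefined: n_units={n_units} <= n_params+1={n_params + 1}")
    return -2.0 * log_likelihood + 2.0 * n_params + 2.0 * n_params * (n_params + 1) / denom


def model_table(fits: list[NMixtureFit], n_units: int,
                labels: list[str] | None = None) -> pd.DataFrame:
    """Rank candidates by AICc with Akaike weights.

    Unconverged fits are dropped (with at least one required); rows are sorted
    ascending by AICc, delta is relative to the best model, and weights are
    exp(-delta/2) normalised to sum to 1.
    """
    if labels is None:
        labels = [f.spec.label() for f in fits]
    rows = [(lab, f) for lab, f in zip(labels, fits) if f.converged]
    if not rows:
        raise ValueError("no converged fits to rank")
    tab = pd.DataFrame({
        "model": [lab for lab, _ in rows],
        "K": [f.n_params for _, f in rows],
        "AICc": [aicc(f.log_likelihood, f.n_params, n_units) for _, f in rows],
    })
    tab = tab.sort_values(["AICc", "model"], kind="mergesort").reset_index(drop=True)
    tab["delta_AICc"] = tab["AICc"] - tab["AICc"].iloc[0]
    w = np.exp(-tab["delta_AICc"].to_numpy() / 2.0)
    tab["AICc_weight"] = w / w.sum()
    return tab


@dataclass
class GofResult:
    observed_statistic: float
    bootstrap_statistics: np.ndarray
    p_value: float
    c_hat: float
    n_failed: int

    @property
    def n_boot(self) -> int:
        return len(self.bootstrap_statistics)


def chi_squared_statistic(counts: np.ndarray, expected: np.ndarray,
                          eps: float = CHI2_EPS) -> float:
    """Pearson statistic sum (y - E)^2 / (E + eps) over observed cells."""
    mask = ~np.isnan(counts)
    resid = counts[mask] - expected[mask]
    return float(np.sum(resid ** 2 / (expected[mask] + eps)))


def parametric_bootstrap_gof(data: CountData, fit: NMixtureFit, n_boot: int = 100,
                             seed: int = 0) -> GofResult:
    """Parametric-bootstrap chi-squared goodness of fit for a fitted model.

    Each replicate simulates counts from the fitted model, refits the same
    specification (starting from the original estimates), and recomputes the
    statistic against the refit's expected counts. The p-value is the
    proportion of bootstrap statistics >= the observed one, over successful
    refits; refit failures are counted and excluded.
    """
    if not fit.converged:
        raise ValueError("goodness of fit requires a converged fit")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    t_obs = chi_squared_statistic(data.counts, nmixture.expected_counts(fit))
    rng = np.random.default_rng(seed)
    stats, n_failed = [], 0
    for _ in range(n_boot):
        y_sim = nmixture.simulate_from_fit(fit, rng)
        sim_data = CountData(counts=y_sim, site_covariates=data.site_covariates,
                             obs_covariates=data.obs_covariates)
        try:
            refit = nmixture.fit(sim_data, fit.spec, starts=fit.params, compute_se=False)
        except (ValueError, np.linalg.LinAlgError):
            n_failed += 1
            continue
        if not refit.converged:
            n_failed += 1
            continue
        expected = nmixture.expected_counts(refit)
        if expected.max() > refit.truncation_K:  # degenerate refit
            n_failed += 1
            continue
        stats.append(chi_squared_statistic(y_sim, expected))
    stats = np.asarray(stats)
    if len(stats) == 0:
        raise RuntimeError("all bootstrap refits failed")
    p = float(np.mean(stats >= t_obs))
    c_hat = float(t_obs / stats.mean())
    return GofResult(observed_statistic=t_obs, bootstrap_statistics=stats,
                     p_value=p, c_hat=c_hat, n_failed=n_failed)
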