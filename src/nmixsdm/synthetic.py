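"""Synthetic data with known truth for every downstream stage.

Three generators:

* ``simulate_counts`` — repeated-count survey data from a known N-mixture
  process (latent abundance from Poisson / negative binomial / zero-inflated
  Poisson, binomial thinning by a detection probability driven by covariates).
  The default covariate design mirrors a 21-site, 6-survey field study:
  invader status at roughly half the sites, a 3-level habitat class split
  4/4/13 (building / non-palm / palm), cloud cover uniform on [0, 100] % and
  temperature normal.
* ``simulate_landscape`` — spatially autocorrelated environmental layers
  (Gaussian-filtered white noise, standardized to zero mean and unit variance
  over valid cells).
* ``simulate_occurrences`` — presence points drawn from a known logistic
  suitability surface over the landscape, one point per sampled cell at the
  cell center.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit, logit

from .grids import EnvStack, GridGeometry, OccurrenceSet
from .nmixture import FAMILIES, CountData, draw_latent_abundance
from .design import build_obs_design, build_site_design

HABITAT_LEVELS = ("building", "non-palm", "palm")
STATUS_LEVELS = ("absent", "present")


@dataclass
class SimTruth:
    """Generating parameters of the count process, on the link scales.

    Coefficients are named dicts keyed by design-column names (treatment
    contrasts, reference = first alphabetical level), e.g.
    ``{"(Intercept)": log(13.3), "status[present]": log(1.6/13.3)}``.
    """

    abundance_coefs: dict[str, float]
    detection_coefs: dict[str, float]
    family: str = "poisson"
    dispersion: float | None = None      # negbin size k; var = lam + lam^2/k
    zero_inflation: float | None = None  # zip point mass at zero
    seed: int = 0
    latent_N: np.ndarray | None = None   # filled in by simulate_counts

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "negbin":
            if self.dispersion is None or self.dispersion <= 0:
                raise ValueError("negbin requires a positive dispersion (size)")
        if self.family == "zip":
            if self.zero_inflation is None or not 0 <= self.zero_inflation <= 1:
                raise ValueError("zip requires zero_inflation in [0, 1]")

    def extra_link(self) -> float | None:
        if self.family == "negbin":
            return float(np.log(self.dispersion))
        if self.family == "zip":
            psi = min(max(self.zero_inflation, 1e-12), 1 - 1e-12)
            return float(logit(psi))
        return None


@dataclass
class CovariateDesign:
    """How site- and observation-level covariates are generated.

    Defaults mirror the reference field design: 21 sites surveyed 6 times,
    invader present at 10 of 21 sites, habitats split 4 building / 4 non-palm
    / 13 palm, cloud % uniform, temperature normal (deg C).
    """

    status_prop: float = 10 / 21
    habitat_props: tuple[float, float, float] = (4 / 21, 4 / 21, 13 / 21)
    cloud_range: tuple[float, float] = (0.0, 100.0)
    temp_mean: float = 28.0
    temp_sd: float = 3.0


def _allocate_levels(n: int, props: np.ndarray, levels: tuple[str, ...],
                     rng: np.random.Generator) -> np.ndarray:
    """Largest-remainder allocation of n sites to levels, then a random shuffle."""
    target = np.asarray(props, dtype=float) * n
    counts = np.floor(target).astype(int)
    rem = target - counts
    for idx in np.argsort(-rem)[: n - counts.sum()]:
        counts[idx] += 1
    out = np.repeat(list(levels), counts)
    rng.shuffle(out)
    return out


def default_truth(family: str = "zip") -> SimTruth:
    """Reference generating process: invader suppresses abundance 13.3 -> 1.6;
    detection ~0.53/0.47/0.37 across habitats at 50% cloud, declining in cloud."""
    cloud_slope = -0.01
    p_building, p_palm, p_nonpalm = 0.530, 0.465, 0.374
    b0 = logit(p_building) - cloud_slope * 50.0
    truth = SimTruth(
        abundance_coefs={"(Intercept)": float(np.log(13.3)),
                         "status[present]": float(np.log(1.6 / 13.3))},
        detection_coefs={"(Intercept)": float(b0),
                         "cloud": cloud_slope,
                         "habitat[non-palm]": float(logit(p_nonpalm) - logit(p_building)),
                         "habitat[palm]": float(logit(p_palm) - logit(p_building))},
        family=family,
        dispersion=1.5 if family == "negbin" else None,
        zero_inflation=0.2 if family == "zip" else None,
    )
    return truth


def _coef_terms(coefs: dict[str, float]) -> list[str]:
    """Covariate terms referenced by a named coefficient dict (intercept aside)."""
    terms = []
    for name in coefs:
        if name == "(Intercept)":
            continue
        base = name.split("[")[0]
        if base not in terms:
            terms.append(base)
    return terms


def _align(coefs: dict[str, float], names: list[str]) -> np.ndarray:
    missing = set(coefs) - set(names)
    if missing:
        raise ValueError(f"coefficient names {missing} not in design columns {names}")
    return np.array([coefs.get(n, 0.0) for n in names])


def simulate_counts(truth: SimTruth, n_sites: int = 21, n_surveys: int = 6,
                    covariate_design: CovariateDesign | None = None,
                    seed: int | None = None) -> tuple[CountData, SimTruth]:
    """Simulate a site x survey count matrix from the stated N-mixture process.

    For each site i, latent N_i ~ family(lambda_i) with log lambda_i linear in
    the site design; each count y_ij ~ Binomial(N_i, p_ij) with logit p_ij
    linear in the observation design. The realised latent abundances are
    recorded on the returned truth.
    """
    if n_sites < 1 or n_surveys < 1:
        raise ValueError("n_sites and n_surveys must be >= 1")
    cd = covariate_design or CovariateDesign()
    rng = np.random.default_rng(seed if seed is not None else truth.seed)

    status = _allocate_levels(n_sites, np.array([1 - cd.status_prop, cd.status_prop]),
                              STATUS_LEVELS, rng)
    habitat = _allocate_levels(n_sites, np.array(cd.habitat_props), HABITAT_LEVELS, rng)
    site_cov = pd.DataFrame({"status": status, "habitat": habitat})
    cloud = rng.uniform(*cd.cloud_range, size=(n_sites, n_surveys))
    temp = rng.normal(cd.temp_mean, cd.temp_sd, size=(n_sites, n_surveys))
    obs_cov = {"cloud": cloud, "temperature": temp}

    Xa, a_names, _ = build_site_design(site_cov, _coef_terms(truth.abundance_coefs))
    Xd, d_names, _ = build_obs_design(obs_cov, site_cov,
                                      _coef_terms(truth.detection_coefs), n_surveys)
    log_lam = Xa @ _align(truth.abundance_coefs, a_names)
    p = expit(np.tensordot(Xd, _align(truth.detection_coefs, d_names), axes=([2], [0])))

    N = draw_latent_abundance(np.exp(log_lam), truth.family, truth.extra_link(), rng)
    y = rng.binomial(N[:, None], p).astype(float)

    truth.latent_N = N
    data = CountData(counts=y, site_covariates=site_cov, obs_covariates=obs_cov)
    return data, truth


def simulate_landscape(n_layers: int = 3, n_rows: int = 100, n_cols: int = 100,
                       smoothness: float = 8.0, cell_size: float = 30.0,
                       seed: int = 0) -> EnvStack:
    """Spatially autocorrelated standardized layers from Gaussian-filtered noise.

    smoothness is the filter sigma in cells; 0 gives white noise. Each layer is
    standardized to zero mean and unit variance.
    """
    if n_rows < 2 or n_cols < 2:
        raise ValueError("grid must be at least 2 x 2")
    if n_layers < 1:
        raise ValueError("need at least one layer")
    rng = np.random.default_rng(seed)
    layers = {}
    for k in range(n_layers):
        z = rng.standard_normal((n_rows, n_cols))
        if smoothness > 0:
            z = gaussian_filter(z, sigma=smoothness, mode="reflect")
        z = (z - z.mean()) / z.std()
        layers[f"env_{k + 1}"] = z
    geom = GridGeometry(n_rows=n_rows, n_cols=n_cols, cell_size=cell_size)
    return EnvStack(geometry=geom, layers=layers)


@dataclass
class SuitabilityTruth:
    """Known logistic species-environment relationship behind occurrence draws."""

    layer_coefs: dict[str, float] = field(default_factory=dict)
    intercept: float = 0.0
    seed: int = 0


def suitability_surface(env: EnvStack, truth: SuitabilityTruth) -> np.ndarray:
    """True cell-wise occurrence probability implied by the truth (NaN off-mask)."""
    eta = np.full((env.geometry.n_rows, env.geometry.n_cols), truth.intercept, dtype=float)
    for name, coef in truth.layer_coefs.items():
        if name not in env.layers:
            raise KeyError(f"layer {name!r} not in the stack")
        eta += coef * env.layers[name]
    s = expit(eta)
    s[~env.mask] = np.nan
    return s


def simulate_occurrences(env: EnvStack, truth: SuitabilityTruth, n_presences: int,
                         seed: int | None = None) -> OccurrenceSet:
    """Sample presence cells with probability proportional to suitability.

    Cells are drawn without replacement among valid cells; one point per
    sampled cell, placed at the cell center.
    """
    rng = np.random.default_rng(seed if seed is not None else truth.seed)
    s = suitability_surface(env, truth)
    rows, cols = np.nonzero(env.mask)
    if n_presences > len(rows):
        raise ValueError(f"n_presences={n_presences} exceeds {len(rows)} valid cells")
    w = s[rows, cols]
    if w.sum() <= 0:
        raise ValueError("suitability surface is zero everywhere")
    idx = rng.choice(len(rows), size=n_presences, replace=False, p=w / w.sum())
    x, y = env.geometry.cell_centers(rows[idx], cols[idx])
    return OccurrenceSet(species="synthetic", points=np.column_stack([x, y]),
                         provenance=["simulated"] * n_presences)
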