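"""Design matrices for the abundance (log) and detection (logit) linear predictors.

Categorical covariates use treatment contrasts; the reference level is the
first level in alphabetical order. Numeric covariates enter untransformed.
An intercept column is always included first.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

INTERCEPT = "(Intercept)"


def is_categorical(series: pd.Series) -> bool:
    return (
        series.dtype == object
        or isinstance(series.dtype, pd.CategoricalDtype)
        or series.dtype == bool
    )


def term_info(name: str, series: pd.Series) -> dict:
    """Describe how one covariate is encoded (kind + sorted levels)."""
    if is_categorical(series):
        levels = sorted(str(v) for v in pd.unique(series))
        if len(levels) < 2:
            raise ValueError(f"categorical covariate {name!r} has a single level")
        return {"term": name, "kind": "categorical", "levels": levels}
    return {"term": name, "kind": "numeric"}


def _encode(info: dict, values: np.ndarray) -> tuple[np.ndarray, list[str]]:
    """Encode a 1-D covariate vector into design columns."""
    if info["kind"] == "numeric":
        return np.asarray(values, dtype=float)[:, None], [info["term"]]
    levels = info["levels"]
    vals = np.asarray([str(v) for v in values])
    unknown = set(vals) - set(levels)
    if unknown:
        raise ValueError(f"unknown level(s) {unknown} for covariate {info['term']!r}")
    cols = np.column_stack([(vals == lvl).astype(float) for lvl in levels[1:]])
    names = [f"{info['term']}[{lvl}]" for lvl in levels[1:]]
    return cols, names


def build_site_design(
    site_covariates: pd.DataFrame, terms: list[str]
) -> tuple[np.ndarray, list[str], list[dict]]:
    """Site-level design matrix (R x P) with intercept first."""
    n = len(site_covariates)
    cols = [np.ones((n, 1))]
    names = [INTERCEPT]
    infos = []
    for term in terms:
        if term not in site_covariates.columns:
            raise KeyError(f"site covariate {term!r} not found")
        info = term_info(term, site_covariates[term])
        c, nm = _encode(info, site_covariates[term].to_numpy())
        cols.append(c)
        names.extend(nm)
        infos.append(info)
    return np.concatenate(cols, axis=1), names, infos


def build_obs_design(
    obs_covariates: dict[str, np.ndarray],
    site_covariates: pd.DataFrame,
    terms: list[str],
    n_surveys: int,
) -> tuple[np.ndarray, list[str], list[dict]]:
    """Observation-level design array (R x J x P) with intercept first.

    A term may be an observation covariate (an R x J numeric array) or a
    site covariate, which is broadcast across surveys.
    """
    n_sites = len(site_covariates)
    shape = (n_sites, n_surveys)
    cols = [np.ones(shape + (1,))]
    names = [INTERCEPT]
    infos = []
    for term in terms:
        if term in obs_covariates:
            arr = np.asarray(obs_covariates[term], dtype=float)
            if arr.shape != shape:
                raise ValueError(
                    f"observation covariate {term!r} has shape {arr.shape}, expected {shape}"
                )
            info = {"term": term, "kind": "numeric"}
            cols.append(arr[:, :, None])
            names.append(term)
        elif term in site_covariates.columns:
            info = term_info(term, site_covariates[term])
            c, nm = _encode(info, site_covariates[term].to_numpy())
            cols.append(np.broadcast_to(c[:, None, :], shape + (c.shape[1],)))
            names.extend(nm)
        else:
            raise KeyError(f"covariate {term!r} not found in observation or site tables")
        infos.append(info)
    return np.concatenate(cols, axis=2), names, infos


def profile_row(infos: list[dict], profile: dict) -> np.ndarray:
    """Build one design row from a named covariate profile (for prediction)."""
    row = [1.0]
    for info in infos:
        term = info["term"]
        if term not in profile:
            raise KeyError(f"profile is missing covariate {term!r}")
        if info["kind"] == "numeric":
            row.append(float(profile[term]))
        else:
            val = str(profile[term])
            if val not in info["levels"]:
                raise ValueError(f"unknown level {val!r} for covariate {term!r}")
            row.extend(float(val == lvl) for lvl in info["levels"][1:])
    return np.asarray(row)
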