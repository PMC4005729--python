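"""Configuration and end-to-end orchestration: simulation -> N-mixture fits ->
AICc ranking and goodness of fit -> ensemble SDMs -> range metrics.

A run is fully determined by its config (seeds included); the manifest it
writes records package and library versions, the seed, and SHA-256 digests of
every output, so two runs of one config are byte-identical.
"""

from __future__ import annotations

import hashlib
import logging
from importlib import metadata
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import io, metrics, nmixture, rasters, sdm, selection, synthetic
from .learners import DEFAULT_LEARNERS

log = logging.getLogger("nmixsdm")


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CountsConfig(_Model):
    n_sites: int = 21
    n_surveys: int = 6
    family: str = "zip"
    counts_csv: str | None = None          # load instead of simulate
    site_covariates_csv: str | None = None
    obs_covariates_csv: str | None = None


class CandidatePair(_Model):
    detection: list[str] = Field(default_factory=list)
    abundance: list[str] = Field(default_factory=list)


def default_candidates() -> list[CandidatePair]:
    """The 19-candidate detection x abundance set used by the reference study."""
    pairs = [
        (["cloud", "habitat"], ["status"]),
        (["cloud", "status"], ["status"]),
        (["cloud", "habitat", "status"], ["status"]),
        (["habitat", "status"], ["status"]),
        ([], ["status"]),
        (["status"], ["status"]),
        (["habitat", "status", "temperature"], ["status"]),
        (["cloud", "habitat", "status", "temperature"], ["status"]),
        (["cloud", "habitat", "status", "temperature"], ["habitat", "status"]),
        (["cloud"], ["habitat"]),
        (["habitat"], ["habitat"]),
        (["cloud", "temperature"], ["habitat"]),
        (["cloud", "habitat", "temperature"], ["habitat"]),
        (["habitat", "status"], ["habitat"]),
        (["cloud", "habitat"], []),
        (["status"], ["habitat"]),
        (["habitat"], []),
        ([], []),
        (["status"], []),
    ]
    return [CandidatePair(detection=d, abundance=a) for d, a in pairs]


class AbundanceConfig(_Model):
    family: str = "zip"
    candidates: list[CandidatePair] = Field(default_factory=default_candidates)
    gof_bootstrap: int = 30
    truncation_K: int | None = None


class SpeciesConfig(_Model):
    name: str
    intercept: float = 0.0
    layer_coefs: dict[str, float] = Field(default_factory=dict)
    n_presences: int = 150


class SdmConfig(_Model):
    n_rows: int = 100
    n_cols: int = 100
    n_layers: int = 3
    smoothness: float = 8.0
    cell_size: float = 30.0
    species: list[SpeciesConfig] = Field(default_factory=lambda: [
        SpeciesConfig(name="invader", intercept=-2.0,
                      layer_coefs={"env_1": 3.0, "env_2": -2.0}),
        SpeciesConfig(name="endemic", intercept=-2.0,
                      layer_coefs={"env_1": 2.5, "env_3": 2.0}),
    ])
    learners: list[str] = Field(default_factory=lambda: list(DEFAULT_LEARNERS))
    n_reps: int = 10
    train_frac: float = 0.8
    auc_min: float = 0.7
    pa_ratio: int = 10
    r_max: float = 0.7


class RunConfig(_Model):
    seed: int = 0
    counts: CountsConfig = Field(default_factory=CountsConfig)
    abundance: AbundanceConfig = Field(default_factory=AbundanceConfig)
    sdm: SdmConfig = Field(default_factory=SdmConfig)
    distance_bins: list[float] = Field(default_factory=lambda: [50, 200, 500, 1000, 1500])


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def _sub_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0]) % (2 ** 31)
            for s in np.random.SeedSequence(seed).spawn(n)]


def _stage(name: str):
    log.info("stage: %s", name)


PREDICT_DEFAULTS = {"status": "absent", "habitat": "palm", "cloud": 50.0,
                    "temperature": 28.0}


def _profile(overrides: dict) -> dict:
    prof = dict(PREDICT_DEFAULTS)
    prof.update(overrides)
    return prof


def _safe_predict(fit, target: str, profile: dict) -> dict:
    """Prediction with CI, falling back to the point estimate when the
    covariance block is unavailable (boundary fits)."""
    try:
        p = nmixture.predict(fit, target, profile)
        return {"estimate": p.estimate, "lower": p.lower, "upper": p.upper}
    except ValueError:
        from scipy.special import expit

        from .design import profile_row
        if target == "abundance":
            x = profile_row(fit.abundance_infos, profile)
            est = float(np.exp(x @ fit.params[:fit.n_abundance]))
        else:
            x = profile_row(fit.detection_infos, profile)
            est = float(expit(x @ fit.params[fit.n_abundance:
                                             fit.n_abundance + fit.n_detection]))
        return {"estimate": est, "lower": None, "upper": None}


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run every stage and write reports, maps and a manifest to outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _sub_seeds(config.seed, 6)
    outputs: list[Path] = []

    # --- counts: simulate (or load) ----------------------------------------
    _stage("counts")
    try:
        if config.counts.counts_csv is not None:
            data = io.read_count_data(config.counts.counts_csv,
                                      config.counts.site_covariates_csv,
                                      config.counts.obs_covariates_csv)
            truth = None
        else:
            truth = synthetic.default_truth(config.counts.family)
            data, truth = synthetic.simulate_counts(
                truth, n_sites=config.counts.n_sites,
                n_surveys=config.counts.n_surveys, seed=seeds[0])
            paths = io.write_count_data(data, outdir)
            outputs.extend(paths.values())
            io.write_json({
                "abundance_coefs": truth.abundance_coefs,
                "detection_coefs": truth.detection_coefs,
                "family": truth.family,
                "zero_inflation": truth.zero_inflation,
                "dispersion": truth.dispersion,
                "latent_N": truth.latent_N.tolist(),
            }, outdir / "truth.json")
            outputs.append(outdir / "truth.json")
    except Exception as exc:
        raise RuntimeError(f"stage 'counts' failed: {exc}") from exc

    # --- candidate fits + model table ---------------------------------------
    _stage("model selection")
    try:
        fits, labels = [], []
        for cand in config.abundance.candidates:
            spec = nmixture.ModelSpec(
                family=config.abundance.family,
                abundance_terms=list(cand.abundance),
                detection_terms=list(cand.detection),
                truncation_K=config.abundance.truncation_K)
            fits.append(nmixture.fit(data, spec, seed=seeds[1]))
            labels.append(f"p({'+'.join(cand.detection) or '.'}) "
                          f"lam({'+'.join(cand.abundance) or '.'})")
        table = selection.model_table(fits, n_units=data.n_sites, labels=labels)
        table.to_csv(outdir / "model_table.csv", index=False,
                     float_format="%.6f")
        outputs.append(outdir / "model_table.csv")
    except Exception as exc:
        raise RuntimeError(f"stage 'model selection' failed: {exc}") from exc

    # --- goodness of fit of the global model --------------------------------
    _stage("goodness of fit")
    try:
        global_fit = max((f for f in fits if f.converged), key=lambda f: f.n_params)
        gof = selection.parametric_bootstrap_gof(
            data, global_fit, n_boot=config.abundance.gof_bootstrap, seed=seeds[2])
        io.write_json({
            "observed_statistic": gof.observed_statistic,
            "p_value": gof.p_value, "c_hat": gof.c_hat,
            "n_boot": gof.n_boot, "n_failed": gof.n_failed,
        }, outdir / "gof.json")
        outputs.append(outdir / "gof.json")
    except Exception as exc:
        raise RuntimeError(f"stage 'goodness of fit' failed: {exc}") from exc

    # --- predictions from the top model -------------------------------------
    _stage("predictions")
    try:
        best_label = table["model"].iloc[0]
        best_fit = fits[labels.index(best_label)]
        preds = {}
        lam = {}
        for status in ("absent", "present"):
            p = _safe_predict(best_fit, "abundance", _profile({"status": status}))
            lam[status] = p["estimate"]
            preds[f"abundance_status_{status}"] = p
        for habitat in ("building", "non-palm", "palm"):
            preds[f"detection_{habitat}"] = _safe_predict(
                best_fit, "detection", _profile({"habitat": habitat}))
        preds["percent_decline"] = nmixture.percent_decline(lam["absent"], lam["present"])
        preds["top_model"] = best_label
        io.write_json(preds, outdir / "predictions.json")
        outputs.append(outdir / "predictions.json")
    except Exception as exc:
        raise RuntimeError(f"stage 'predictions' failed: {exc}") from exc

    # --- landscape, occurrences, ensembles ----------------------------------
    _stage("sdm")
    try:
        env = synthetic.simulate_landscape(
            n_layers=config.sdm.n_layers, n_rows=config.sdm.n_rows,
            n_cols=config.sdm.n_cols, smoothness=config.sdm.smoothness,
            cell_size=config.sdm.cell_size, seed=seeds[3])
        retained = sdm.screen_collinearity(env, r_max=config.sdm.r_max)
        sp_seeds = _sub_seeds(seeds[4], 2 * max(len(config.sdm.species), 1))
        ensembles, occs = {}, {}
        report = {"retained_layers": retained, "species": {}}
        for k, sp in enumerate(config.sdm.species):
            truth_sp = synthetic.SuitabilityTruth(
                layer_coefs=sp.layer_coefs, intercept=sp.intercept)
            occ = synthetic.simulate_occurrences(env, truth_sp, sp.n_presences,
                                                 seed=sp_seeds[2 * k])
            occ.species = sp.name
            occ = sdm.deduplicate(occ, env)
            ens = sdm.run_ensemble(
                occ, env, learners=list(config.sdm.learners),
                n_reps=config.sdm.n_reps, train_frac=config.sdm.train_frac,
                auc_min=config.sdm.auc_min, seed=sp_seeds[2 * k + 1],
                layer_names=retained, pa_ratio=config.sdm.pa_ratio)
            ensembles[sp.name] = ens
            occs[sp.name] = occ
            io.write_occurrences(occ, outdir / f"occurrences_{sp.name}.csv")
            rasters.write_ascii_grid(outdir / f"suitability_{sp.name}.asc",
                                     ens.suitability, env.geometry, env.mask)
            rasters.write_ascii_grid(outdir / f"range_{sp.name}.asc",
                                     ens.binary_map.presence.astype(float),
                                     env.geometry, env.mask)
            outputs += [outdir / f"occurrences_{sp.name}.csv",
                        outdir / f"suitability_{sp.name}.asc",
                        outdir / f"range_{sp.name}.asc"]
            report["species"][sp.name] = {
                "n_presences": len(occ),
                "member_aucs": {f"{m.learner_id}/rep{m.repetition}":
                                round(m.auc, 6) for m in ens.members},
                "n_included": ens.n_included,
                "ensemble_auc": ens.auc, "threshold": ens.threshold,
                "sensitivity": ens.sensitivity, "specificity": ens.specificity,
            }
        io.write_json(report, outdir / "ensemble_report.json")
        outputs.append(outdir / "ensemble_report.json")
    except Exception as exc:
        raise RuntimeError(f"stage 'sdm' failed: {exc}") from exc

    # --- range metrics -------------------------------------------------------
    _stage("metrics")
    try:
        met = {"range_area_km2": {}, "levins_breadth": {}}
        names = list(ensembles)
        for name, ens in ensembles.items():
            met["range_area_km2"][name] = metrics.range_area(ens.binary_map)
            met["levins_breadth"][name] = metrics.levins_breadth(
                ens.binary_map.presence.astype(float), ens.binary_map.mask)
        if len(names) >= 2:
            a, b = names[0], names[1]
            ov = metrics.overlap(ensembles[a].binary_map, ensembles[b].binary_map)
            met["overlap"] = {f"pct_{a}_in_{b}": ov.pct_a_in_b,
                              f"pct_{b}_in_{a}": ov.pct_b_in_a,
                              "overlap_area_km2": ov.overlap_area_km2}
            union = metrics.union_range([ensembles[n].binary_map for n in names[1:]])
            ovu = metrics.overlap(ensembles[a].binary_map, union)
            met["overlap_with_combined"] = {
                f"pct_{a}_in_combined": ovu.pct_a_in_b,
                f"pct_combined_in_{a}": ovu.pct_b_in_a}
            dist = metrics.distance_to_range(occs[b], ensembles[a].binary_map,
                                             tuple(config.distance_bins))
            met["distance_bins"] = dist.bin_counts
        io.write_json(met, outdir / "metrics.json")
        outputs.append(outdir / "metrics.json")
    except Exception as exc:
        raise RuntimeError(f"stage 'metrics' failed: {exc}") from exc

    # --- manifest ------------------------------------------------------------
    _stage("manifest")
    manifest = {
        "package": {"name": "nmixsdm", "version": _pkg_version()},
        "libraries": {m: _lib_version(m) for m in
                      ("numpy", "scipy", "pandas", "scikit-learn", "statsmodels")},
        "seed": config.seed,
        "config": config.model_dump(),
        "outputs": {p.name: _sha256(p) for p in sorted(set(outputs))},
    }
    io.write_json(manifest, outdir / "manifest.json")
    return manifest


def _pkg_version() -> str:
    try:
        return metadata.version("nmixsdm")
    except metadata.PackageNotFoundError:
        return "unknown"


def _lib_version(name: str) -> str:
    try:
        return metadata.version(name)
    except metadata.PackageNotFoundError:
        return "unknown"


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()
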