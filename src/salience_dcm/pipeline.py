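"""End-to-end study pipeline: simulate -> prep -> subject fits -> PEB ->
metabolite model -> report, plus the replicated recovery experiment."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dcm_invert, dcm_model, metabolite_bayes, peb, prep, synthetic
from .synthetic import StudyConfig, substream

REPORTED_EFFECTS = (
    ("glu_by_group", "ie_dacc"),
    ("gsh_by_group", "ie_dacc"),
    ("gsh_by_group", "ie_ai"),
)


def config_hash(config: StudyConfig) -> str:
    payload = {
        "n_hc": config.n_hc, "n_fes": config.n_fes,
        "metabolite_means": config.metabolite_means,
        "metabolite_sds": config.metabolite_sds,
        "beta_true": config.beta_true.matrix.tolist(),
        "subject_param_sd": config.subject_param_sd,
        "n_vol": config.n_vol, "tr": config.tr, "seed": config.seed,
    }
    blob = yaml.safe_dump(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    master_seed: int
    outputs: dict = field(default_factory=dict)
    stage_seconds: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"config_hash": self.config_hash,
                "master_seed": self.master_seed,
                "outputs": self.outputs,
                "stage_seconds": self.stage_seconds}


def fit_subjects(bold: np.ndarray, tr: float,
                 freqs: np.ndarray | None = None,
                 settings: dcm_invert.InversionSettings | None = None):
    """Prep, spectral estimation and variational-Laplace inversion per subject."""
    if freqs is None:
        freqs = dcm_model.default_freq_grid()
    posteriors = []
    for i in range(bold.shape[0]):
        ts = prep.TimeseriesPair(tr=tr, data=bold[i])
        clean = prep.remove_confounds(ts)
        csd = dcm_model.estimate_csd(clean.data, tr, freqs)
        posteriors.append(dcm_invert.variational_laplace(csd, settings=settings))
    return posteriors


def _two_model_comparison(posteriors, design):
    full = peb.fit_peb(posteriors, design)
    group_only = peb.bayesian_model_reduction(
        full, keep_columns=("group", "constant"), name="only_group")
    comparison = peb.compare_models({
        "two_metabolite": full.free_energy,
        "only_group": group_only.free_energy,
    })
    return full, group_only, comparison


def run_study(config: StudyConfig, out_dir=None,
              mcmc_samples: int = 11000,
              settings: dcm_invert.InversionSettings | None = None):
    """Execute the full pipeline; returns (manifest, report dict).

    If ``out_dir`` is given, all stage artifacts and the report are written
    beneath it and recorded in the manifest.
    """
    manifest = RunManifest(config_hash=config_hash(config),
                           master_seed=config.seed)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def stage(name):
        return _StageTimer(manifest, name)

    with stage("simulate_metabolites"):
        table = synthetic.simulate_metabolites(config)
        if out is not None:
            synthetic.write_metabolites_csv(table, out / "metabolites.csv")
            manifest.outputs["metabolites"] = str(out / "metabolites.csv")

    met_report = {}
    with stage("metabolite_bayes"):
        for met in ("glu", "gsh"):
            mcmc_seed = int(substream(config.seed, "mcmc", met).integers(2**31))
            post = metabolite_bayes.fit_group_model(
                table, met, n_samples=mcmc_samples, seed=mcmc_seed)
            diff = post.difference
            met_report[met] = {
                "parameters": {k: v for k, v in
                               metabolite_bayes.summary_table(post)
                               .T.to_dict().items()},
                "difference": metabolite_bayes.summarize(diff).as_dict(),
                "difference_pp": metabolite_bayes.posterior_proportion(diff),
                "effect_size": metabolite_bayes.summarize(
                    post.effect_size).as_dict(),
            }

    with stage("simulate_bold"):
        params_list, bold = synthetic.simulate_cohort(table, config)
        if out is not None:
            ts_dir = out / "timeseries"
            ts_dir.mkdir(exist_ok=True)
            for sid, series in zip(table["subject_id"], bold):
                synthetic.write_timeseries_csv(series, config.tr,
                                               ts_dir / f"{sid}.csv")
            manifest.outputs["timeseries_dir"] = str(ts_dir)

    with stage("subject_dcm"):
        posteriors = fit_subjects(bold, config.tr, settings=settings)
        subject_fits = {
            sid: {"free_energy": float(p.free_energy),
                  "converged": bool(p.converged),
                  "theta_mean": [float(x) for x in p.mean[:4]]}
            for sid, p in zip(table["subject_id"], posteriors)
        }

    with stage("peb"):
        design = peb.build_peb_design(table)
        full, group_only, comparison = _two_model_comparison(posteriors, design)
        effects = {}
        for cov, conn in REPORTED_EFFECTS:
            e = peb.parameter_posterior_probability(full, cov, conn)
            effects[f"{cov}:{conn}"] = {
                "mean": e.mean, "sd": e.sd, "sign": e.sign, "pp": e.pp,
            }

    report = {
        "config_hash": manifest.config_hash,
        "master_seed": config.seed,
        "n_subjects": int(len(table)),
        "metabolites": met_report,
        "subject_fits": subject_fits,
        "peb": {
            "beta": {c: {k: float(v) for k, v in full.beta[c].items()}
                     for c in full.beta.columns},
            "between_subject_log_precision": float(full.gamma),
            "free_energy": float(full.free_energy),
            "effects": effects,
        },
        "model_comparison": comparison.as_dict(),
    }
    validate_report(report)
    if out is not None:
        report_path = out / "report.json"
        with open(report_path, "w") as fh:
            json.dump(report, fh, indent=2)
        manifest.outputs["report"] = str(report_path)
        manifest_path = out / "manifest.json"
        with open(manifest_path, "w") as fh:
            json.dump(manifest.as_dict(), fh, indent=2)
    return manifest, report


class _StageTimer:
    def __init__(self, manifest: RunManifest, name: str):
        self.manifest, self.name = manifest, name

    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        self.manifest.stage_seconds[self.name] = round(
            time.perf_counter() - self.t0, 3)
        return False


def recovery_experiment(config: StudyConfig, n_replicates: int,
                        settings: dcm_invert.InversionSettings | None = None,
                        fit_metabolites: bool = False) -> pd.DataFrame:
    """Replicated simulate-and-recover runs of the DCM/PEB chain.

    Each replicate re-draws the cohort under ``config`` with a derived seed,
    fits all subjects, runs the two-model comparison and records the winning
    model plus the sign and posterior probability of each reported effect.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    records = []
    for rep in range(n_replicates):
        rep_seed = int(substream(config.seed, "replicate", rep).integers(2**31))
        rep_config = StudyConfig(
            n_hc=config.n_hc, n_fes=config.n_fes,
            metabolite_means=config.metabolite_means,
            metabolite_sds=config.metabolite_sds,
            beta_true=config.beta_true,
            subject_param_sd=config.subject_param_sd,
            n_vol=config.n_vol, tr=config.tr, seed=rep_seed)
        table = synthetic.simulate_metabolites(rep_config)
        _, bold = synthetic.simulate_cohort(table, rep_config)
        posteriors = fit_subjects(bold, rep_config.tr, settings=settings)
        design = peb.build_peb_design(table)
        full, _, comparison = _two_model_comparison(posteriors, design)
        rec = {"replicate": rep, "seed": rep_seed,
               "winner": comparison.winner,
               "pp_two_metabolite": float(
                   comparison.posterior_probs[
                       comparison.names.index("two_metabolite")])}
        for cov, conn in REPORTED_EFFECTS:
            e = peb.parameter_posterior_probability(full, cov, conn)
            rec[f"sign_{cov}:{conn}"] = e.sign
            rec[f"pp_{cov}:{conn}"] = e.pp
        if fit_metabolites:
            mcmc_seed = int(substream(rep_seed, "mcmc", "gsh").integers(2**31))
            post = metabolite_bayes.fit_group_model(table, "gsh",
                                                    seed=mcmc_seed)
            lo, hi = metabolite_bayes.hdi(post.effect_size)
            rec["gsh_es_hdi_low"], rec["gsh_es_hdi_high"] = lo, hi
        records.append(rec)
    return pd.DataFrame.from_records(records)


def summarize_recovery(table: pd.DataFrame) -> dict:
    """Aggregate selection and sign-recovery rates over replicates."""
    out = {
        "n_replicates": int(len(table)),
        "two_metabolite_selection_rate": float(
            np.mean(table["winner"] == "two_metabolite")),
        "only_group_selection_rate": float(
            np.mean(table["winner"] == "only_group")),
    }
    expected_signs = {"glu_by_group:ie_dacc": -1,
                      "gsh_by_group:ie_dacc": 1,
                      "gsh_by_group:ie_ai": 1}
    for key, sign in expected_signs.items():
        out[f"sign_rate_{key}"] = float(np.mean(table[f"sign_{key}"] == sign))
    return out


def validate_report(report: dict) -> None:
    """Check the report against the bundled JSON schema (required keys and
    primitive types only)."""
    schema = json.loads(resources.files("salience_dcm")
                        .joinpath("report_schema.json").read_text())
    _check_schema(report, schema, path="report")


_TYPES = {"object": dict, "array": list, "string": str,
          "number": (int, float), "integer": int, "boolean": bool}


def _check_schema(value, schema: dict, path: str) -> None:
    expected = schema.get("type")
    if expected and not isinstance(value, _TYPES[expected]):
        raise ValueError(f"{path}: expected {expected}, got {type(value).__name__}")
    for key, sub in schema.get("properties", {}).items():
        if key in schema.get("required", []) and key not in value:
            raise ValueError(f"{path}: missing required key '{key}'")
        if key in value:
            _check_schema(value[key], sub, f"{path}.{key}")
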