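"""End-to-end orchestration: design -> simulate -> filter -> diagnose -> fit -> report.

Every stage writes plain CSV/YAML artifacts into a run directory and logs
its wall time and seed; a manifest records config, stage seeds, package
versions and a SHA-256 per artifact so a re-run with the same config can be
verified bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import (
    default_attributes,
    default_priors,
    design_to_frame,
    generate_design,
)
from .estimate import (
    DrawConfig,
    EstimationResult,
    fit_hcm,
    fit_mixed_logit,
    wtp,
)
from .preprocess import (
    SCALES,
    descriptives,
    filter_dataset,
    scale_diagnostics,
)
from .simulate import (
    CONSTRUCTS,
    INDICATOR_NAMES,
    STRUCTURAL_COVARIATES,
    HCMParameterSet,
    SurveyDataset,
    default_true_params,
    simulate_survey,
)

log = logging.getLogger("huimin_hcm")

DEFAULT_CONFIG = {
    "seed": 20230901,
    "n_respondents": 1203,
    "inattentive_fraction": 67 / 1203,
    "design": {"n_sets": 24, "n_blocks": 4, "n_restarts": 5},
    "draws": {"scheme": "scrambled-halton", "n_draws": 300},
    "fit": {
        "model": "hcm",
        "interactions": "true",   # "true" = data-generating nonzero terms; "all" = 63
        "compute_se": True,
        "maxiter": 1000,
    },
    "params_file": None,
}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        _deep_update(cfg, user)
    if overrides:
        _deep_update(cfg, overrides)
    return cfg


def _deep_update(base: dict, other: dict) -> None:
    for k, v in other.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v


def _stage_seeds(master: int) -> dict:
    ss = np.random.SeedSequence(master)
    names = ["design", "simulate", "draws"]
    return {n: int(s.generate_state(1)[0] % (2**31)) for n, s in zip(names, ss.spawn(len(names)))}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _timed(name, seed=None):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s started%s", name, f" (seed {seed})" if seed is not None else "")
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc_type is None:
                log.info("stage %s finished in %.1fs", name, dt)
            else:
                log.error("stage %s failed after %.1fs: %s", name, dt, exc)
            return False
    return _Ctx()


# ---------------------------------------------------------------------------
# Dataset persistence
# ---------------------------------------------------------------------------

def save_dataset(ds: SurveyDataset, outdir: Path) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in (("respondents", ds.respondents), ("indicators", ds.indicators),
                     ("choices", ds.choices)):
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        written.append(p)
    p = outdir / "dataset_manifest.yaml"
    with open(p, "w") as fh:
        yaml.safe_dump(ds.meta, fh, sort_keys=True)
    written.append(p)
    return written


def load_dataset(outdir: Path, design) -> SurveyDataset:
    outdir = Path(outdir)
    meta = {}
    mpath = outdir / "dataset_manifest.yaml"
    if mpath.exists():
        meta = yaml.safe_load(mpath.read_text()) or {}
    return SurveyDataset(
        respondents=pd.read_csv(outdir / "respondents.csv"),
        indicators=pd.read_csv(outdir / "indicators.csv"),
        choices=pd.read_csv(outdir / "choices.csv"),
        design=design,
        meta=meta,
    )


def load_params(path: str | Path | None) -> HCMParameterSet:
    if path is None:
        return default_true_params()
    text = Path(path).read_text()
    data = yaml.safe_load(text) if str(path).endswith((".yaml", ".yml")) else json.loads(text)
    return HCMParameterSet.from_dict(data)


# ---------------------------------------------------------------------------
# Table rendering
# ---------------------------------------------------------------------------

def render_tables(result: EstimationResult) -> dict:
    """Structural/measurement and choice blocks with estimates, robust SEs,
    p-values and stars; reference levels printed as 'ref'."""
    base = result.table().set_index("parameter")
    have_se = "p_value" in base.columns

    def row(label, pname):
        if pname is None:
            return {"term": label, "estimate": "ref", "robust_se": "", "p_value": "", "stars": ""}
        r = base.loc[pname]
        out = {"term": label, "estimate": round(float(r["estimate"]), 4)}
        if have_se:
            out.update(robust_se=round(float(r["robust_se"]), 4),
                       p_value=round(float(r["p_value"]), 4), stars=r["stars"])
        else:
            out.update(robust_se="", p_value="", stars="")
        return out

    latent_rows = []
    if result.spec.latent:
        for g, label in (("HR", "Health risk perceptions"),
                         ("AW", "Awareness of the scheme"),
                         ("VAL", "Perceptions of its value")):
            latent_rows.append({"term": f"-- structural: {label} --", "estimate": "",
                                "robust_se": "", "p_value": "", "stars": ""})
            for zc in STRUCTURAL_COVARIATES:
                latent_rows.append(row(zc, f"gamma_{g}:{zc}"))
            if g == "AW":
                latent_rows.append(row("Health risk perceptions", "lam_hr_aw"))
            if g == "VAL":
                latent_rows.append(row("Health risk perceptions", "lam_hr_val"))
                latent_rows.append(row("Awareness of the scheme", "lam_aw_val"))
        latent_rows.append({"term": "-- measurement loadings --", "estimate": "",
                            "robust_se": "", "p_value": "", "stars": ""})
        for iname in INDICATOR_NAMES:
            latent_rows.append(row(iname, f"zeta:{iname}"))

    choice_rows = []
    ref_lines = {"government:moderate": ("Purely commercially operated", None),
                 "value_added:expanded1": ("Basic value-added services", None)}
    for c in result.spec.coded_cols:
        if c in ref_lines:
            choice_rows.append(row(*ref_lines[c]))
        choice_rows.append(row(c, f"b:{c}"))
    choice_rows.append(row("Opt-out (ASC)", "optout_asc"))
    for s in result.spec.random_slots:
        choice_rows.append(row(f"SD {s}", f"sd:{s}"))
    if result.spec.latent:
        for c in CONSTRUCTS:
            choice_rows.append(row(f"{c} x opt-out", f"phi:{c}"))
    for s, v in result.spec.interactions:
        choice_rows.append(row(f"{v} x {s}", f"theta:{s}*{v}"))

    return {
        "latent_component": pd.DataFrame(latent_rows),
        "choice_component": pd.DataFrame(choice_rows),
    }


def tables_to_text(tables: dict) -> str:
    chunks = []
    for name, df in tables.items():
        chunks.append(f"== {name.replace('_', ' ')} ==")
        chunks.append(df.to_string(index=False))
        chunks.append("")
    return "\n".join(chunks)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Run all stages; returns the manifest (also written to manifest.yaml)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(int(config["seed"]))
    attrs = default_attributes()
    params = load_params(config.get("params_file"))
    artifacts: list[Path] = []

    with _timed("design", seeds["design"]):
        design = generate_design(
            attrs,
            n_sets=config["design"]["n_sets"],
            n_blocks=config["design"]["n_blocks"],
            priors=default_priors(attrs),
            seed=seeds["design"],
            n_restarts=config["design"]["n_restarts"],
        )
        p = outdir / "design.csv"
        design_to_frame(design).to_csv(p, index=False)
        artifacts.append(p)

    with _timed("simulate", seeds["simulate"]):
        ds = simulate_survey(
            design, params, n=int(config["n_respondents"]),
            inattentive_fraction=float(config["inattentive_fraction"]),
            seed=seeds["simulate"],
        )
        artifacts += save_dataset(ds, outdir)

    with _timed("filter"):
        filtered, qc = filter_dataset(ds)
        qc_report = pd.DataFrame(
            [{"n_completed": len(ds.respondents), "n_excluded": qc.n_excluded,
              "n_retained": qc.n_retained}]
        )
        p = outdir / "qc_report.csv"
        qc_report.to_csv(p, index=False)
        artifacts.append(p)

    with _timed("diagnose"):
        desc = descriptives(filtered)
        p = outdir / "descriptives.csv"
        desc.to_csv(p, index=False)
        artifacts.append(p)
        p = outdir / "descriptives_scales.csv"
        desc.attrs["scales"].to_csv(p, index=False)
        artifacts.append(p)
        diag = scale_diagnostics(filtered)
        p = outdir / "scale_diagnostics.csv"
        diag.to_csv(p, index=False)
        artifacts.append(p)

    with _timed("fit", seeds["draws"]):
        draws = DrawConfig(scheme=config["draws"]["scheme"],
                           n_draws=int(config["draws"]["n_draws"]),
                           seed=seeds["draws"])
        interactions = config["fit"].get("interactions", "true")
        if interactions == "true":
            interactions = sorted(params.theta.keys())
        elif interactions == "all":
            interactions = None
        model = config["fit"].get("model", "hcm")
        if model == "hcm":
            result = fit_hcm(ds if config["fit"].get("skip_qc_filter") else filtered,
                             interactions=interactions, draws=draws,
                             maxiter=int(config["fit"].get("maxiter", 1000)),
                             compute_se=bool(config["fit"].get("compute_se", True)))
        elif model == "mixed_logit":
            result = fit_mixed_logit(filtered, draws=draws,
                                     maxiter=int(config["fit"].get("maxiter", 1000)),
                                     compute_se=bool(config["fit"].get("compute_se", True)))
        else:
            raise ValueError(f"unknown fit model {model!r}")
        p = outdir / "estimates.csv"
        result.table().to_csv(p, index=False)
        artifacts.append(p)

    with _timed("report"):
        tables = render_tables(result)
        for name, df in tables.items():
            p = outdir / f"table_{name}.csv"
            df.to_csv(p, index=False)
            artifacts.append(p)
        # scale diagnostics completed with CR/AVE from the estimated loadings
        if result.spec.latent:
            zeta_hat = {key: [result.get(f"zeta:{i}") for i in items]
                        for key, items in SCALES.items()}
            diag2 = scale_diagnostics(filtered, zeta_by_scale=zeta_hat)
            p = outdir / "scale_diagnostics_fitted.csv"
            diag2.to_csv(p, index=False)
            artifacts.append(p)
        try:
            wtp_df = wtp(result)
            p = outdir / "wtp.csv"
            wtp_df.to_csv(p, index=False)
            artifacts.append(p)
        except ValueError as exc:
            log.warning("WTP skipped: %s", exc)
        p = outdir / "report.txt"
        p.write_text(tables_to_text(tables))
        artifacts.append(p)

    manifest = {
        "package_version": __version__,
        "config": config,
        "stage_seeds": seeds,
        "d_error": float(design.d_error),
        "n_retained": int(qc.n_retained),
        "loglik": float(result.loglik),
        "converged": bool(result.converged),
        "gradient_norm": float(result.gradient_norm),
        "artifacts": {str(a.name): _sha256(a) for a in artifacts},
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest
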