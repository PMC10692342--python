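"""Stage orchestration: simulate → covariates → edit → fits → parameters.

Every stage reads and writes plain-text files in one output directory, so a
partially failed run can be resumed: with ``resume=True`` a stage whose
outputs already exist is skipped.  A ``manifest.json`` records the effective
configuration, its hash, the seed, per-stage wall times and SHA-256 digests
of the outputs; reruns with an identical manifest input reproduce identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import climate, editing, kinship, simulate
from .gradient import Model2Components, gradient_table, parameter_ses
from .models import ALL_COVARIATES, MaternalReactionNormModel, run_model1_battery

log = logging.getLogger("heatnorm")

DEFAULT_CONFIG = {
    "seed": 1,
    "covariate": "s_pc1",          # gradient for the reaction-norm model
    "model1_covariates": ALL_COVARIATES,
    "regime": "reference",          # "reference" solves the published regime
    "scale": {},                    # SimConfig overrides (n_dams, n_herds, ...)
    "blend_w": 0.95,
    "hwe_alpha": 1e-6,
    "include_hym_in_denominator": True,
    "fit": {"max_iter": 200, "tol_param": 1e-8, "tol_logl": 1e-6},
}


def effective_config(config: dict | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for k, v in (config or {}).items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def _sim_config(cfg: dict) -> simulate.SimConfig:
    overrides = dict(cfg.get("scale") or {})
    if cfg.get("regime") == "reference":
        return simulate.reference_regime_config(covariate=cfg["covariate"], **overrides)
    return simulate.SimConfig(sim_covariate=cfg["covariate"], **overrides)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, msg: str):
        super().__init__(f"stage {stage!r} failed: {msg}")
        self.stage = stage


def stage_simulate(cfg: dict, outdir: Path) -> None:
    sc = _sim_config(cfg)
    rng = np.random.default_rng(cfg["seed"])
    pop = simulate.simulate_population(sc, rng)
    weather = simulate.simulate_weather(sc, rng)
    cov = climate.build_covariates(weather, pop.stations, pop.herds, pop.calves)
    calves, truth = simulate.simulate_phenotypes(pop, cov, sc, rng)
    _write_csv(weather, outdir / "weather.csv")
    _write_csv(pop.stations, outdir / "stations.csv")
    _write_csv(pop.herds, outdir / "herds.csv")
    _write_csv(pop.pedigree, outdir / "pedigree.csv")
    _write_csv(calves, outdir / "calves.csv")
    geno = pd.DataFrame(pop.genotypes, columns=pop.snp_map["snp"])
    geno.insert(0, "id", pop.geno_ids)
    geno.to_csv(outdir / "genotypes.tsv", sep="\t", index=False, na_rep="NA")
    pop.snp_map.to_csv(outdir / "snp_map.tsv", sep="\t", index=False)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth.to_dict(), fh)


def stage_covariates(cfg: dict, outdir: Path, weather=None, stations=None,
                     herds=None, calves=None) -> None:
    weather = weather if weather is not None else pd.read_csv(outdir / "weather.csv")
    stations = stations if stations is not None else pd.read_csv(outdir / "stations.csv")
    herds = herds if herds is not None else pd.read_csv(outdir / "herds.csv")
    calves = calves if calves is not None else pd.read_csv(outdir / "calves.csv")
    cov = climate.build_covariates(weather, stations, herds, calves)
    _write_csv(cov, outdir / "covariates.csv")


def stage_edit(cfg: dict, outdir: Path) -> None:
    calves = pd.read_csv(outdir / "calves.csv")
    edited, log_counts = editing.edit_phenotypes(calves)
    edited = editing.assign_classes(edited)
    cov = pd.read_csv(outdir / "covariates.csv")
    edited = edited.merge(cov, on="calf_id", how="left")
    _write_csv(edited, outdir / "edited.csv")
    with open(outdir / "edits.json", "w") as fh:
        json.dump(log_counts, fh, indent=2)


def _load_relationship(cfg: dict, outdir: Path):
    ped = pd.read_csv(outdir / "pedigree.csv")
    geno = pd.read_csv(outdir / "genotypes.tsv", sep="\t", na_values="NA")
    snp_map = pd.read_csv(outdir / "snp_map.tsv", sep="\t")
    ids = geno["id"].tolist()
    g = geno.drop(columns="id").to_numpy(dtype=float)
    keep, report = kinship.snp_qc(g, snp_map["chrom"].to_numpy(), hwe_alpha=cfg["hwe_alpha"])
    G = kinship.build_G(g[:, keep])
    retained = kinship.prune_high_relationship(G, ids)
    ridx = [ids.index(i) for i in retained]
    G = G[np.ix_(ridx, ridx)]
    A, a_ids = kinship.build_A(ped)
    gpos = [a_ids.index(i) for i in retained]
    A22 = A[np.ix_(gpos, gpos)]
    Gw = cfg["blend_w"] * G + (1.0 - cfg["blend_w"]) * A22
    H = kinship.build_H(A, Gw, gpos)
    with open(outdir / "snp_qc.json", "w") as fh:
        json.dump({**report, "n_pruned": len(ids) - len(retained)}, fh, indent=2)
    return H, a_ids


def stage_fit_model1(cfg: dict, outdir: Path) -> None:
    data = pd.read_csv(outdir / "edited.csv")
    battery = run_model1_battery(data, cfg["model1_covariates"], **cfg["fit"])
    _write_csv(battery, outdir / "model1_battery.csv")


def stage_fit_model2(cfg: dict, outdir: Path) -> None:
    data = pd.read_csv(outdir / "edited.csv")
    H, ids = _load_relationship(cfg, outdir)
    m = MaternalReactionNormModel(
        covariate=cfg["covariate"], relationship=H, relationship_ids=ids, **cfg["fit"]
    ).fit(data)
    res = m.result_
    out = {
        "covariate": cfg["covariate"],
        "coef": m.coef_, "coef_se": m.coef_se_, "p_value": m.p_value_,
        "loglik": m.loglik_, "n_iter": m.n_iter_,
        "components": dict(zip(res.param_names, map(float, res.theta))),
        "ai_matrix": res.ai.tolist(),
        "param_names": res.param_names,
        "trace": [{"iter": t["iter"], "loglik": t["loglik"]} for t in res.trace],
    }
    with open(outdir / "model2_fit.json", "w") as fh:
        json.dump(out, fh, indent=2)
    fe = pd.DataFrame({
        "term": m.x_names_, "estimate": res.beta,
        "se": np.sqrt(np.diag(res.beta_cov)),
    })
    _write_csv(fe, outdir / "model2_fixed_effects.csv")


def stage_params(cfg: dict, outdir: Path) -> None:
    with open(outdir / "model2_fit.json") as fh:
        fit = json.load(fh)
    c = fit["components"]
    comp = Model2Components(
        v_d=c["v_d"],
        K_m=_cf(c, "m"), K_pe=_cf(c, "pe"),
        v_hym=c["v_hym"], v_e=c["v_e"],
    )
    include = cfg["include_hym_in_denominator"]
    table = gradient_table(comp, include_hym=include)
    # delta-method SEs from the stored AI matrix
    from .reml import REMLResult

    res = REMLResult(
        theta=np.array([c[k] for k in fit["param_names"]]),
        param_names=fit["param_names"], blocks=[], loglik=fit["loglik"],
        beta=np.zeros(0), beta_cov=np.zeros((0, 0)),
        ai=np.array(fit["ai_matrix"]), gradient=np.zeros(0),
        n_iter=fit["n_iter"], converged=True,
    )
    try:
        ses = parameter_ses(res, include_hym=include)
        table = table.merge(ses, on="x")
    except np.linalg.LinAlgError:
        log.warning("singular AI matrix: gradient-parameter SEs reported missing")
    _write_csv(table, outdir / "params.csv")
    grid = table["x"].to_numpy()
    for key, name in (("K_m", "corr_mg"), ("K_pe", "corr_mpe")):
        K = getattr(comp, key)
        from .gradient import correlation_between_envs

        M = np.array([[correlation_between_envs(K, a, b) for b in grid] for a in grid])
        pd.DataFrame(M, index=grid, columns=grid).to_csv(outdir / f"{name}.csv")


def _cf(c: dict, prefix: str):
    from .gradient import CovarianceFunction2x2

    return CovarianceFunction2x2(
        c[f"{prefix}_v_int"], c[f"{prefix}_c_is"], c[f"{prefix}_v_slope"]
    )


def stage_report(cfg: dict, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = pd.read_csv(outdir / "params.csv")
    fig, ax = plt.subplots(1, 2, figsize=(10, 4))
    ax[0].plot(table["x"], table["h2_d"], label="direct h²")
    ax[0].plot(table["x"], table["h2_m"], label="maternal h²")
    ax[0].set_xlabel("scaled heat-load gradient")
    ax[0].set_ylabel("heritability")
    ax[0].legend()
    ax[1].plot(table["x"], table["r_mg_max"], label="r maternal genetic (vs x=1)")
    ax[1].plot(table["x"], table["r_mpe_max"], label="r maternal pe (vs x=1)")
    ax[1].set_xlabel("scaled heat-load gradient")
    ax[1].set_ylabel("correlation with x = 1")
    ax[1].legend()
    fig.tight_layout()
    fig.savefig(outdir / "gradient_parameters.png", dpi=120)
    plt.close(fig)


STAGES = [
    ("simulate", stage_simulate, ["weather.csv", "calves.csv", "pedigree.csv", "truth.json"]),
    ("covariates", stage_covariates, ["covariates.csv"]),
    ("edit", stage_edit, ["edited.csv", "edits.json"]),
    ("fit_model1", stage_fit_model1, ["model1_battery.csv"]),
    ("fit_model2", stage_fit_model2, ["model2_fit.json"]),
    ("params", stage_params, ["params.csv"]),
    ("report", stage_report, ["gradient_parameters.png"]),
]


def run_pipeline(config: dict | None, outdir, resume: bool = False) -> dict:
    """Run all stages; returns the manifest (also written to manifest.json)."""
    cfg = effective_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "tool": "heatnorm", "version": __import__("heatnorm").__version__,
        "seed": cfg["seed"],
        "config": cfg,
        "config_hash": hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest(),
        "stages": {},
        "outputs": {},
    }
    for name, fn, outputs in STAGES:
        if resume and all((outdir / o).exists() for o in outputs):
            log.info("stage %s: outputs present, skipped (resume)", name)
            manifest["stages"][name] = {"skipped": True}
            continue
        t0 = time.time()
        log.info("stage %s: start (seed %s)", name, cfg["seed"])
        try:
            fn(cfg, outdir)
        except Exception as err:
            manifest["stages"][name] = {"error": str(err)}
            with open(outdir / "manifest.json", "w") as fh:
                json.dump(manifest, fh, indent=2)
            raise PipelineError(name, str(err)) from err
        manifest["stages"][name] = {"seconds": round(time.time() - t0, 3)}
        log.info("stage %s: done in %.1fs", name, time.time() - t0)
    for path in sorted(outdir.iterdir()):
        if path.name != "manifest.json" and path.is_file():
            manifest["outputs"][path.name] = _sha256(path)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
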