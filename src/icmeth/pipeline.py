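"""End-to-end pipeline on synthetic data: simulate -> score -> trends ->
train -> predict -> accelerate -> deconvolve -> associate -> survive ->
health, with per-stage CSV outputs and a deterministic JSON manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import association, clock, deconvolution, health, score, simulate, survival, trends

log = logging.getLogger("icmeth.pipeline")

_FLOAT_FMT = "%.10g"


def _write(df: pd.DataFrame, path: Path, index_label: str) -> None:
    df.to_csv(path, index_label=index_label, float_format=_FLOAT_FMT)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _sim_config(block: dict, seed: int) -> simulate.SimulationConfig:
    block = dict(block or {})
    domains = block.pop("domains", None)
    cfg = simulate.default_config(seed=seed, **block)
    if domains:
        dom = {k: simulate.DomainTrajectory(**v) for k, v in domains.items()}
        cfg = simulate.SimulationConfig(
            **{**cfg.__dict__, "domains": dom}
        )
    return cfg


def run_pipeline(config: dict, outdir) -> dict:
    """Execute every configured stage; returns the run manifest.

    ``config`` is a plain mapping (typically from YAML) with optional
    blocks ``simulate``, ``clock``, ``associate``, ``survival``,
    ``health`` and a global ``seed``. Stages whose block is set to null
    are skipped and noted in the manifest. Outputs are byte-reproducible
    from config + seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest: dict = {
        "package_version": __version__,
        "seed": seed,
        "parameters": config,
        "stages": {},
        "checksums": {},
        "metrics": {},
    }

    def record(stage: str, path: Path) -> None:
        manifest["checksums"][path.name] = _sha256(path)
        manifest["stages"].setdefault(stage, []).append(path.name)

    # ---- simulate + score -------------------------------------------------
    log.info("stage=simulate")
    sim_cfg = _sim_config(config.get("simulate", {}), seed)
    cohort = simulate.simulate_cohort(sim_cfg)
    scored = score.score_cohort(cohort)
    ic = scored.table["overall_ic"]
    p = outdir / "cohort.csv"
    _write(cohort, p, "participant_id")
    record("simulate", p)
    p = outdir / "ic_scores.csv"
    _write(scored.table, p, "participant_id")
    record("score", p)

    # ---- trends -----------------------------------------------------------
    log.info("stage=trends")
    rows = []
    age = cohort["age"]
    for dom in score.DOMAINS + ["overall_ic"]:
        y = scored.table[dom] if dom != "overall_ic" else ic
        rho, pv = trends.spearman_with_p(age, y)
        w, pw = trends.sex_difference_test(y, cohort["sex"])
        fit = trends.two_phase_fit(age.to_numpy(), y.to_numpy())
        rows.append((dom, rho, pv, w, pw, fit.breakpoint, fit.slope1, fit.slope2, fit.rss))
    trend_df = pd.DataFrame(
        rows,
        columns=["domain", "rho_age", "p_age", "wilcoxon_w", "p_sex",
                 "breakpoint", "slope1", "slope2", "rss"],
    ).set_index("domain")
    p = outdir / "trends.csv"
    _write(trend_df, p, "domain")
    record("trends", p)

    # ---- methylome + clock training --------------------------------------
    log.info("stage=train")
    betas, truth = simulate.simulate_methylome(cohort, ic, sim_cfg)
    p = outdir / "betas.csv"
    _write(betas, p, "cpg")
    record("simulate", p)
    ck = config.get("clock", {}) or {}
    mask, report = clock.bin_filter(
        ic.to_numpy(), ck.get("bin_width", 0.05), ck.get("min_bin_count", 10)
    )
    cv = clock.cv_elastic_net(
        betas.loc[:, mask],
        ic[mask],
        alphas=ck.get("alphas", clock.DEFAULT_ALPHAS),
        folds=ck.get("folds", 10),
        seed=seed,
        n_lambdas=ck.get("n_lambdas", 50),
    )
    model = clock.select_model(cv, betas.loc[:, mask])
    from .io import write_clock_model  # local import avoids a cycle

    p = outdir / "clock_model.csv"
    write_clock_model(model, p)
    record("train", p)
    record("train", p.with_suffix(p.suffix + ".meta.json"))
    manifest["metrics"]["clock"] = {
        "alpha": model.alpha,
        "n_cpgs": model.n_cpgs,
        "cv_mae": model.cv_mae,
        "cv_corr": model.cv_corr,
        "n_bins": int(report.n_bins),
        "excluded_fraction": report.excluded_fraction,
        "causal_recovered": int(
            len(set(model.weights.index) & set(truth["causal_cpgs"].index))
        ),
    }

    # ---- predict + accelerate --------------------------------------------
    log.info("stage=predict")
    dnam_ic = clock.predict_clock(model, betas)
    accel = clock.age_acceleration(dnam_ic, cohort["age"])
    pred = pd.DataFrame({"dnam_ic": dnam_ic, "acceleration": accel})
    pred["quintile_group"] = clock.quintile_groups(accel)
    p = outdir / "predictions.csv"
    _write(pred, p, "participant_id")
    record("predict", p)

    # ---- deconvolve -------------------------------------------------------
    log.info("stage=deconvolve")
    props = deconvolution.estimate_proportions(betas, truth["reference"])
    p = outdir / "cell_proportions.csv"
    _write(props, p, "participant_id")
    record("deconvolve", p)
    cc = deconvolution.cellcount_ic_correlations(props, cohort["age"], dnam_ic)
    p = outdir / "cellcount_correlations.csv"
    _write(cc, p, "cell_type")
    record("deconvolve", p)

    # ---- associate --------------------------------------------------------
    assoc_cfg = config.get("associate", {})
    if assoc_cfg is None:
        manifest["stages"]["associate"] = "skipped"
    else:
        log.info("stage=associate")
        # generate on the standardized predictor so planted effect sizes are
        # on a per-s.d. scale; the DE fit itself is scale-free
        accel_std = (accel - accel.mean()) / accel.std(ddof=1)
        expr, true_coef = simulate.simulate_expression(cohort, accel_std, sim_cfg)
        de = association.linear_de(expr, accel, fdr_level=assoc_cfg.get("fdr", 0.05))
        p = outdir / "differential_expression.csv"
        _write(de, p, "gene")
        record("associate", p)
        sig = de.index[de["significant"]]
        manifest["metrics"]["associate"] = {
            "n_significant": int(len(sig)),
            "true_positive": int((true_coef.loc[sig] != 0).sum()) if len(sig) else 0,
        }
        clock_cpgs = model.weights.index
        if len(sig) and len(clock_cpgs):
            link = association.cpg_gene_linkage(
                betas.loc[clock_cpgs],
                expr.loc[sig],
                n_perm=assoc_cfg.get("n_perm", 1000),
                seed=seed,
            )
            manifest["metrics"]["associate"]["linkage_statistic"] = link.statistic
            manifest["metrics"]["associate"]["linkage_p"] = link.p

    # ---- survive ----------------------------------------------------------
    surv_cfg = config.get("survival", {})
    if surv_cfg is None:
        manifest["stages"]["survive"] = "skipped"
    else:
        log.info("stage=survive")
        std_accel = (accel - accel.mean()) / accel.std(ddof=1)
        surv = simulate.simulate_survival(cohort, std_accel, sim_cfg)
        p = outdir / "survival.csv"
        _write(surv, p, "participant_id")
        record("simulate", p)
        sex_num = (cohort["sex"] == "male").astype(float)
        fit = survival.cox_fit(
            surv["survival_time"],
            surv["event"],
            std_accel,
            covariates=pd.DataFrame({"age": cohort["age"].to_numpy(), "sex": sex_num.to_numpy()}),
        )
        groups = pred["quintile_group"]
        extreme = groups.isin(["lowest20", "highest20"])
        km = survival.kaplan_meier(
            surv.loc[extreme, "survival_time"],
            surv.loc[extreme, "event"],
            groups[extreme],
        )
        chi2, p_lr = survival.logrank_test(
            surv.loc[extreme, "survival_time"],
            surv.loc[extreme, "event"],
            groups[extreme],
        )
        tau = float(surv_cfg.get("tau", min(c.max_time for c in km.values())))
        tau = min(tau, *(c.max_time for c in km.values()))
        # low acceleration = better predicted capacity = the "high IC" group
        rmst = survival.rmst_difference(km["lowest20"], km["highest20"], tau)
        manifest["metrics"]["survive"] = {
            "hr_per_sd": fit.hr,
            "hr_ci": list(fit.ci),
            "wald_p": fit.p,
            "n_events": fit.n_events,
            "logrank_chi2": chi2,
            "logrank_p": p_lr,
            "rmst_difference_years": rmst,
            "tau": tau,
        }

    # ---- health -----------------------------------------------------------
    health_cfg = config.get("health", {})
    if health_cfg is None:
        manifest["stages"]["health"] = "skipped"
    else:
        log.info("stage=health")
        hm = scored.table[score.DOMAINS].copy()
        pc1 = health.overall_health_pc1(hm, anchor=health_cfg.get("anchor", "locomotion"))
        rho_h, p_h = trends.spearman_with_p(pc1, dnam_ic.loc[pc1.index])
        screen = health.lifestyle_screen(dnam_ic.loc[pc1.index], hm.loc[pc1.index])
        p = outdir / "health_screen.csv"
        _write(screen, p, "feature")
        record("health", p)
        manifest["metrics"]["health"] = {
            "pc1_dnam_ic_rho": rho_h,
            "pc1_dnam_ic_p": p_h,
        }

    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True, default=float))
    summary = [
        f"icmeth pipeline (seed={seed})",
        f"participants: {len(cohort)}  cpgs: {betas.shape[0]}",
        f"clock: alpha={model.alpha} n_cpgs={model.n_cpgs} cv_corr={model.cv_corr:.3f}",
    ]
    (outdir / "summary.txt").write_text("\n".join(summary) + "\n")
    return manifest
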