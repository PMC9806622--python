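"""End-to-end orchestration: generators -> stages -> treatment report.

A run executes, in order: gas-exchange reduction and reference-
conductance calibration, leaf trait tables with Mann–Whitney tests,
wood-anatomy metrics with heteroscedastic GLS (log cross-sectional-area
covariate), branch conductivity normalization with Mann–Whitney tests,
Bayesian vulnerability-curve and dry-down calibrations with credible-
interval comparison, and (optionally) the stepwise CO2-drawdown summary
(per-tree gc medians per CO2 level and their paired differences).  The
product is a tidy treatment-comparison table — one row per trait with
group summaries, the test applied, its decision and the percent
contrast — plus a machine-readable JSON of fitted parameters and a run
log of seeds and convergence diagnostics.

Percent contrasts are computed on treatment medians for Bayesian
quantities and on treatment means for trait tables (the two families
are summarized the way each is normally reported).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from pinehydro import anatomy, bayes, chamber, groupstats, hydraulics, morphology, synth
from pinehydro.report import percent_contrast

logger = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass
class RunConfig:
    """Pipeline run settings.

    Either ``input_dir`` (a directory of CSVs as written by
    :func:`pinehydro.synth.generate_all`) or a generator block
    (``effects``/``gen_config``) must be usable; with no inputs the
    generators run at their defaults.
    """

    seed: int = 0
    outdir: str | Path | None = None
    input_dir: str | Path | None = None
    effects: synth.TreatmentEffects | None = None
    gen_config: synth.GeneratorConfig | None = None
    cal_config: bayes.CalibrationConfig | None = None
    include_co2_steps: bool = True
    include_drydown: bool = True
    treatments: tuple = ("aCO2", "eCO2")


def run_pipeline(run_config: RunConfig | None = None) -> dict:
    """Execute the full analysis; returns the report bundle.

    The bundle holds ``report`` (tidy comparison table), ``parameters``
    (all fitted quantities), ``log`` (seeds, R̂, exclusions) and the
    intermediate frames.  With ``outdir`` set, everything is also
    written as CSV/JSON.
    """
    cfg = run_config or RunConfig()
    cal = cfg.cal_config or bayes.CalibrationConfig(seed=cfg.seed)
    run_log: dict = {"seed": cfg.seed, "stages": {}}

    data = _load_inputs(cfg)
    rows: list[dict] = []
    parameters: dict = {}

    # ---- gas exchange -> reference conductance -------------------------
    gas_cfg = chamber.GasExchangeConfig()
    leaf_areas = dict(zip(data["trees"]["tree_id"], data["trees"]["a_leaf_m2"]))
    series = chamber.reduce_gas_exchange(data["chamber_records"], leaf_areas, gas_cfg)
    series = series.merge(
        data["trees"][["tree_id", "treatment"]],
        left_on="chamber_id", right_on="tree_id", how="left",
    )
    run_log["stages"]["gas_exchange"] = {
        "n_visits": int(len(series)),
        "n_undefined_gc": int(series.attrs.get("n_undefined_gc", 0)),
    }
    gc_summary, _, gc_posts = chamber.gc_reference(
        series, gas_cfg, cal_config=_child_cal(cal, 1), seed=cfg.seed
    )
    trt_rows = gc_summary[gc_summary["level"] == "treatment"].set_index("id")
    a, e = (trt_rows.loc[t] for t in cfg.treatments)
    rows.append(_bayes_row(
        "gc_ref", "mol m-2 s-1", a["gc_ref_median"], e["gc_ref_median"],
        (a["ci_lo"], a["ci_hi"]), (e["ci_lo"], e["ci_hi"]),
    ))
    parameters["gc_ref"] = gc_summary.to_dict(orient="records")
    run_log["stages"]["gc_ref"] = {
        "rhat_max": float(gc_summary["rhat_max"].max()),
        "converged": bool(gc_summary["converged"].all()),
    }

    # ---- leaf morphology traits ----------------------------------------
    leaf = morphology.aggregate_cuticle(data["cuticle_counts"])
    leaf = leaf.merge(
        data["cuticle_counts"][["tree_id", "treatment"]].drop_duplicates(), on="tree_id"
    )
    traits = data["traits"].merge(leaf[["tree_id", "sd", "ed", "si"]], on="tree_id")
    trait_units = {
        "sl_um": "um", "sd": "n mm-2", "ed": "n mm-2", "si": "%",
        "d_m_um": "um", "lw_mm": "mm", "aba_ng_g": "ng g-1",
        "la_cm2": "cm2", "sla_cm2_g": "cm2 g-1",
    }
    for trait, unit in trait_units.items():
        rows.append(_mw_row(trait, unit, traits, trait, cfg.treatments))
    parameters["traits"] = traits.to_dict(orient="records")

    # ---- wood anatomy + GLS ---------------------------------------------
    metrics = []
    for branch_id, grp in data["conduits"].groupby("branch_id", sort=True):
        meta = data["sections"].set_index("branch_id").loc[branch_id]
        m = anatomy.cross_section_metrics(grp, float(meta["axylem_m2"])).as_dict()
        m["branch_id"] = branch_id
        m["treatment"] = meta["treatment"]
        metrics.append(m)
    metrics = pd.DataFrame(metrics)
    anatomy_units = {
        "a_lumen_pct": "%", "d_mean_um": "um", "d_h_um": "um",
        "cd_per_mm2": "n mm-2", "k_p": "kg m-1 MPa-1 s-1",
    }
    gls_fits = {}
    for metric, unit in anatomy_units.items():
        fit = groupstats.gls_treatment_effect(
            metrics[metric].to_numpy(),
            metrics["treatment"].to_numpy(),
            metrics["axylem_mm2"].to_numpy(),
        )
        gls_fits[metric] = fit
        # size-adjusted group values: model prediction at the mean log area
        a_adj = fit.coefficients["intercept"]
        e_adj = a_adj + fit.treatment_effect
        rows.append(
            {
                "quantity": metric, "unit": unit,
                "aCO2": float(a_adj),
                "eCO2": float(e_adj),
                "test": "GLS", "p_value": fit.p_value,
                "meaningful": fit.p_value < ALPHA,
                "contrast_pct": percent_contrast(e_adj, a_adj),
            }
        )
    parameters["anatomy"] = metrics.to_dict(orient="records")
    parameters["gls"] = {
        k: {"effect": f.treatment_effect, "se": f.treatment_se, "p": f.p_value,
            "variance_ratio": f.variance_ratio, "converged": f.converged}
        for k, f in gls_fits.items()
    }
    run_log["stages"]["gls"] = {k: bool(f.converged) for k, f in gls_fits.items()}

    # ---- branch conductivity --------------------------------------------
    br = data["branch_samples"].copy()
    br["k_s"] = hydraulics.specific_conductivity(br["k_h"], br["cross_section_area_m2"])
    br["k_l"] = hydraulics.leaf_specific_conductivity(br["k_h"], br["supported_leaf_area_m2"])
    br["al_as"] = hydraulics.leaf_sapwood_ratio(
        br["supported_leaf_area_m2"], br["cross_section_area_m2"]
    )
    for metric, unit in (
        ("k_s", "kg m-1 MPa-1 s-1"), ("k_l", "kg m-1 MPa-1 s-1"), ("al_as", "-"),
    ):
        rows.append(_mw_row(metric, unit, br, metric, cfg.treatments))
    parameters["branch_hydraulics"] = br.to_dict(orient="records")

    # ---- vulnerability curves -------------------------------------------
    vuln_summary, _, _ = hydraulics.fit_vulnerability_curves(
        data["vulnerability_curves"], cal_config=_child_cal(cal, 2)
    )
    vt = vuln_summary[vuln_summary["level"] == "treatment"].set_index("id")
    for p in ("p12", "p50", "p88"):
        a, e = (vt.loc[t] for t in cfg.treatments)
        rows.append(_bayes_row(
            p, "-MPa", a[f"{p}_median"], e[f"{p}_median"],
            (a[f"{p}_lo"], a[f"{p}_hi"]), (e[f"{p}_lo"], e[f"{p}_hi"]),
        ))
    parameters["vulnerability"] = vuln_summary.to_dict(orient="records")
    run_log["stages"]["vulnerability"] = {
        "rhat_max": float(vuln_summary["rhat_max"].max()),
        "converged": bool(vuln_summary["converged"].all()),
    }

    # ---- dry-down: stomatal closure and ABA -----------------------------
    if cfg.include_drydown and data.get("drydown") is not None:
        closure_rows, aba_rows, dry_params, dry_log = _drydown_stage(
            data["drydown"], cfg, _child_cal(cal, 3)
        )
        rows.extend(closure_rows)
        rows.extend(aba_rows)
        parameters["drydown"] = dry_params
        run_log["stages"]["drydown"] = dry_log

    # ---- CO2 drawdown summary -------------------------------------------
    if cfg.include_co2_steps and data.get("co2_step_records") is not None:
        co2_summary = co2_step_summary(data["co2_step_records"], leaf_areas, gas_cfg)
        parameters["co2_steps"] = co2_summary.to_dict(orient="records")
        run_log["stages"]["co2_steps"] = {"n_trees": int(co2_summary["tree_id"].nunique())}

    report = pd.DataFrame(rows)
    bundle = {
        "report": report,
        "parameters": parameters,
        "log": run_log,
        "series": series,
        "anatomy_metrics": metrics,
        "branch_hydraulics": br,
    }
    if cfg.outdir is not None:
        _write_outputs(bundle, cfg)
    return bundle


def co2_step_summary(records, leaf_areas, gas_cfg) -> pd.DataFrame:
    """Per-tree daytime gc medians per CO2 level and paired step differences."""
    series = chamber.reduce_gas_exchange(records, leaf_areas, gas_cfg)
    day = series[series["par"] > gas_cfg.par_threshold].copy()
    day["co2_level"] = day["co2_sample"].round(-2).clip(lower=100)
    med = (
        day.groupby(["chamber_id", "co2_level"])["gc"]
        .median()
        .rename("gc_median")
        .reset_index()
        .rename(columns={"chamber_id": "tree_id"})
    )
    wide = med.pivot(index="tree_id", columns="co2_level", values="gc_median")
    levels = sorted(wide.columns, reverse=True)
    for hi, lo in zip(levels[:-1], levels[1:]):
        med = med.merge(
            (wide[lo] - wide[hi]).rename(f"diff_{int(hi)}_to_{int(lo)}").reset_index(),
            on="tree_id", how="left",
        )
    return med


def _drydown_stage(drydown, cfg, cal):
    closure = bayes.ClosureModel()
    aba_model = bayes.AbaModel()
    psi_posts, aba_posts = {t: [] for t in cfg.treatments}, {t: [] for t in cfg.treatments}
    rhats = []
    for tree, grp in drydown.groupby("tree_id", sort=True):
        trt = grp["treatment"].iloc[0]
        post_c = bayes.calibrate(
            closure, grp["psi_mpa"].to_numpy(), grp["gc_rel"].to_numpy(),
            bayes.default_closure_priors(), cal, provenance=[str(tree)],
        )
        post_a = bayes.calibrate(
            aba_model, grp["psi_mpa"].to_numpy(), grp["aba_ng_g"].to_numpy(),
            bayes.default_aba_priors(), cal, provenance=[str(tree)],
        )
        psi_posts[trt].append(post_c)
        aba_posts[trt].append(post_a)
        rhats.extend([float(np.max(post_c.rhat)), float(np.max(post_a.rhat))])

    closure_summaries, aba_summaries, params = {}, {}, {}
    for trt in cfg.treatments:
        merged_c = bayes.merge_posteriors(psi_posts[trt])
        flat = merged_c.flat_samples()
        psi_close = closure.psi_close(flat[:, :2])
        closure_summaries[trt] = (
            float(np.median(psi_close)), bayes.credible_interval(psi_close)
        )
        merged_a = bayes.merge_posteriors(aba_posts[trt])
        slope = merged_a._col("r")
        aba_summaries[trt] = (float(np.median(slope)), bayes.credible_interval(slope))
        params[trt] = {
            "psi_gc_close_median": closure_summaries[trt][0],
            "psi_gc_close_ci": closure_summaries[trt][1],
            "aba_slope_median": aba_summaries[trt][0],
            "aba_slope_ci": aba_summaries[trt][1],
        }

    a_trt, e_trt = cfg.treatments
    closure_rows = [_bayes_row(
        "psi_gc_close", "MPa",
        closure_summaries[a_trt][0], closure_summaries[e_trt][0],
        closure_summaries[a_trt][1], closure_summaries[e_trt][1],
    )]
    aba_rows = [_bayes_row(
        "aba_slope", "ng g-1 MPa-1",
        aba_summaries[a_trt][0], aba_summaries[e_trt][0],
        aba_summaries[a_trt][1], aba_summaries[e_trt][1],
    )]
    log = {"rhat_max": float(np.max(rhats)), "converged": bool(np.max(rhats) <= cal.rhat_threshold)}
    return closure_rows, aba_rows, params, log


def _mw_row(name, unit, frame, col, treatments):
    a = frame.loc[frame["treatment"] == treatments[0], col].to_numpy(dtype=float)
    e = frame.loc[frame["treatment"] == treatments[1], col].to_numpy(dtype=float)
    u, p = groupstats.mann_whitney_u(a, e)
    return {
        "quantity": name, "unit": unit,
        "aCO2": float(np.mean(a)), "eCO2": float(np.mean(e)),
        "test": "MW", "p_value": p, "meaningful": p < ALPHA,
        "contrast_pct": percent_contrast(np.mean(e), np.mean(a)),
    }


def _bayes_row(name, unit, a_med, e_med, a_ci, e_ci):
    return {
        "quantity": name, "unit": unit,
        "aCO2": float(a_med), "eCO2": float(e_med),
        "aCO2_ci_lo": float(a_ci[0]), "aCO2_ci_hi": float(a_ci[1]),
        "eCO2_ci_lo": float(e_ci[0]), "eCO2_ci_hi": float(e_ci[1]),
        "test": "CI-overlap", "p_value": np.nan,
        "meaningful": bayes.ci_overlap_decision(tuple(a_ci), tuple(e_ci)),
        "contrast_pct": percent_contrast(e_med, a_med),
    }


def _child_cal(cal: bayes.CalibrationConfig, k: int) -> bayes.CalibrationConfig:
    child_seed = int(np.random.SeedSequence(cal.seed).generate_state(k + 1)[k] % (2**31))
    return bayes.CalibrationConfig(
        iterations=cal.iterations, burn_in=cal.burn_in, n_chains=cal.n_chains,
        seed=child_seed, rhat_threshold=cal.rhat_threshold,
        snooker_probability=cal.snooker_probability,
        gamma_jump_probability=cal.gamma_jump_probability,
        predictive_draws=cal.predictive_draws, ci_level=cal.ci_level,
        memory_thin=cal.memory_thin,
    )


def _load_inputs(cfg: RunConfig) -> dict:
    if cfg.input_dir is not None:
        d = Path(cfg.input_dir)
        data = {}
        for name in (
            "chamber_records", "co2_step_records", "conduits", "sections",
            "vulnerability_curves", "branch_samples", "traits",
            "cuticle_counts", "drydown", "trees",
        ):
            path = d / f"{name}.csv"
            data[name] = pd.read_csv(path) if path.exists() else None
        for key in ("chamber_records", "conduits", "sections", "trees"):
            if data[key] is None:
                raise FileNotFoundError(f"pipeline input missing: {key}.csv in {d}")
        return data
    bundle = synth.generate_all(
        effects=cfg.effects, config=cfg.gen_config, seed=cfg.seed,
        include_co2_steps=cfg.include_co2_steps,
    )
    bundle["trees"] = bundle["chamber_truth"]["tree_params"][
        ["tree_id", "treatment", "a_leaf_m2"]
    ]
    return bundle


def _write_outputs(bundle: dict, cfg: RunConfig) -> None:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle["report"].to_csv(outdir / "report.csv", index=False)
    bundle["series"].to_csv(outdir / "gas_exchange_series.csv", index=False)
    bundle["anatomy_metrics"].to_csv(outdir / "anatomy_metrics.csv", index=False)
    (outdir / "parameters.json").write_text(
        json.dumps(bundle["parameters"], indent=2, default=_jsonify)
    )
    (outdir / "run_log.json").write_text(
        json.dumps(bundle["log"], indent=2, default=_jsonify)
    )


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return str(obj)
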