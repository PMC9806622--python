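"""Synthetic study data with the measurement structure the pipeline assumes.

Every input the analysis consumes can be generated here: multiplexed
chamber records (plants plus two empty reference chambers, 10-s records,
120-s switching, diurnal PAR/VPD/temperature forcing), per-conduit
particle tables, flow-centrifuge vulnerability series, cuticle count
tables, leaf/branch trait tables and dry-down (Ψ, relative gc, ABA)
trajectories.  Treatment contrasts default to the elevated-CO2 study
effects (:class:`TreatmentEffects`); every generator is a pure function
of (effects, config, seed).

Chamber records are produced by *inverting* the analysis equations: a
true conductance is drawn from the log-VPD response model, converted to
transpiration and then to supply/sample H2O mole fractions, so that the
noise-free pipeline recovers the injected truth exactly.  Forcings are
held constant within each 120-s multiplexer slot (chamber control
discretization), which makes the round trip exact rather than
quadrature-limited.  Analyzer noise and a slow empty-chamber drift are
added downstream of the inversion.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from pinehydro import chamber as ch
from pinehydro.hydraulics import WeibullParams, weibull_plc

DAY_S = 86_400.0

#: Slope-to-intercept ratio of the log-VPD conductance model; this value
#: makes gc drop by 60% between VPD = 1 and 2 kPa.
VPD_SLOPE_RATIO = 0.6 / np.log(2.0)


@dataclass
class TreatmentEffects:
    """Multiplicative eCO2/aCO2 contrasts applied by the generators."""

    gc_ref: float = 0.45       # -55% reference conductance
    sd_density: float = 1.23   # +23% stomatal density
    ed_density: float = 1.25   # +25% epidermal cell density
    d_m: float = 1.67          # +67% vein-to-epidermis distance
    lw: float = 1.40           # +40% leaf width
    la: float = 1.18           # +18% individual needle area
    sla: float = 0.92          # -8% specific leaf area
    conduit_d: float = 0.92    # -8% conduit diameter
    a_lumen: float = 0.89      # -11% lumen fraction
    k_s: float = 0.81          # -19% specific conductivity
    al_as: float = 1.24        # +24% leaf-to-sapwood ratio
    sl: float = 1.0            # stomata length unchanged
    si: float = 1.0            # stomatal index unchanged
    aba: float = 1.0           # foliar ABA unchanged
    vuln_scale: float = 1.0    # Weibull scale unchanged
    vuln_shape: float = 1.0    # Weibull shape unchanged

    def __post_init__(self) -> None:
        if any(v <= 0 for v in asdict(self).values()):
            raise ValueError("TreatmentEffects: all contrasts must be > 0")

    @property
    def conduit_density(self) -> float:
        """CD factor implied by the lumen-fraction and diameter effects.

        A_lumen ∝ CD · D²  =>  CD factor = a_lumen / conduit_d²
        (≈ +5% at the defaults, matching the observed CD tendency).
        """
        return self.a_lumen / self.conduit_d**2


@dataclass
class ChamberProtocol:
    """Timing and forcing of the multiplexed chamber system."""

    days: float = 3.0
    record_cadence: float = 10.0
    switch_period: float = 120.0
    n_empty: int = 2
    flow_lpm: float = 10.0
    pressure_kpa: float = 94.0      # ~730 m a.s.l.
    day_start_h: float = 6.0
    day_hours: float = 16.0
    t_day_c: float = 24.0
    t_night_c: float = 19.7
    par_mean: float = 450.0
    par_amplitude: float = 50.0
    vpd_day_min: float = 0.9
    vpd_day_max: float = 2.1
    vpd_night: float = 0.45
    co2_levels_ppm: tuple = (900.0, 400.0, 200.0)  # drawdown protocol
    days_per_co2_level: float = 2.0
    empty_w_supply: float = 0.008


@dataclass
class GeneratorConfig:
    """Study-scale configuration for all generators."""

    n_trees: int = 6                       # per treatment (chambers, traits)
    n_branches_anatomy: dict = field(default_factory=lambda: {"aCO2": 12, "eCO2": 13})
    n_branches_vuln: dict = field(default_factory=lambda: {"aCO2": 5, "eCO2": 6})
    n_branches_conductivity: int = 6       # per treatment
    chamber: ChamberProtocol = field(default_factory=ChamberProtocol)

    # leaf-level baselines (ambient treatment)
    gc_ref_mean: float = 0.20              # mol m^-2 s^-1 at VPD = 1 kPa
    gc_ref_cv: float = 0.06
    gc_night_fraction: float = 0.10
    a_leaf_mean_m2: float = 0.022
    a_leaf_cv: float = 0.06
    a_leaf_eco2_factor: float = 1.2        # larger canopies under eCO2

    # measurement noise and physiological scatter
    w_noise_sd: float = 1e-4               # mol mol^-1 per 10-s record
    t_noise_sd: float = 0.05               # degC per record
    drift_offset: float = 3e-5             # mol mol^-1 empty-chamber offset
    drift_amplitude: float = 2e-4          # mol mol^-1, 1-day period
    gc_process_sd: float = 0.01            # slot-to-slot conductance fluctuation,
                                           # mol m^-2 s^-1 (additive)

    # trait baselines (ambient means; tree-level CVs)
    trait_means: dict = field(default_factory=lambda: {
        "sl_um": 51.87, "d_m_um": 150.97, "lw_mm": 0.85,
        "la_cm2": 0.74, "sla_cm2_g": 55.48, "aba_ng_g": 250.0,
    })
    trait_cvs: dict = field(default_factory=lambda: {
        "sl_um": 0.11, "d_m_um": 0.06, "lw_mm": 0.06,
        "la_cm2": 0.05, "sla_cm2_g": 0.03, "aba_ng_g": 0.30,
    })
    sd_mean: float = 28.92                 # stomata mm^-2
    ed_mean: float = 133.20                # pavement cells mm^-2
    cell_density_cv: float = 0.06          # tree-level, SD and ED jointly
    sd_ed_correlation: float = 0.8
    n_images: int = 5
    image_area_mm2: float = 2.0

    # wood anatomy
    conduit_b_median_um: float = 7.0       # minor semi-axis, lognormal median
    conduit_b_sigma: float = 0.25          # lognormal sigma of semi-axes
    eccentricity_range: tuple = (1.0, 1.6)
    cd_base_per_mm2: float = 1400.0
    section_area_mean_mm2: float = 1.25
    section_area_sigma: float = 0.25
    section_area_eco2_factor: float = 1.15
    size_area_exponent: float = 0.15       # conduit size ~ area^phi
    branch_size_cv: float = 0.03
    branch_count_cv: float = 0.03

    # branch conductivity samples
    ks_mean: float = 1.0                   # kg m^-1 MPa^-1 s^-1 (ambient)
    ks_cv: float = 0.08
    al_as_mean: float = 2500.0
    al_as_cv: float = 0.08
    branch_diameter_mean_mm: float = 7.33
    branch_diameter_sd_mm: float = 0.44

    # vulnerability protocol
    vuln_scale_mpa: float = 5.5
    vuln_shape: float = 6.0
    vuln_first_pressure: float = -0.84
    vuln_pressure_step: float = -0.82
    vuln_max_steps: int = 12
    vuln_kmax: float = 1.5e-4
    vuln_kmax_cv: float = 0.2
    plc_noise_sd: float = 5.0              # PLC points

    # dry-down
    drydown_n_obs: int = 25
    drydown_psi_range: tuple = (-0.5, -3.0)
    closure_psi50: float = -1.119          # with s = 3 -> closure at -2.1 MPa
    closure_s: float = 3.0
    gc_rel_noise_sd: float = 0.05
    aba0: float = 100.0                    # ng g^-1 at Psi = 0
    aba_slope: float = 150.0               # ng g^-1 MPa^-1
    aba_noise_sd: float = 30.0

    treatments: tuple = ("aCO2", "eCO2")


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _effect(effects: TreatmentEffects, name: str, treatment: str) -> float:
    return getattr(effects, name) if treatment == "eCO2" else 1.0


# ---------------------------------------------------------------------------
# chamber gas exchange
# ---------------------------------------------------------------------------

def _slot_forcing(t_mid: np.ndarray, proto: ChamberProtocol):
    """Diurnal (VPD, T, PAR) forcing, constant within each multiplexer slot."""
    hour = (t_mid % DAY_S) / 3600.0
    phase = (hour - proto.day_start_h) / proto.day_hours
    is_day = (phase >= 0) & (phase < 1)
    shape = np.where(is_day, np.sin(np.pi * np.clip(phase, 0, 1)), 0.0)
    vpd = np.where(
        is_day, proto.vpd_day_min + (proto.vpd_day_max - proto.vpd_day_min) * shape,
        proto.vpd_night,
    )
    t_air = np.where(is_day, proto.t_day_c, proto.t_night_c)
    par = np.where(
        is_day,
        proto.par_mean + proto.par_amplitude * np.sin(6.0 * np.pi * np.clip(phase, 0, 1) + 1.3),
        0.0,
    )
    return vpd, t_air, par, is_day


def generate_chamber_timeseries(
    effects: TreatmentEffects,
    config: GeneratorConfig,
    seed: int,
    protocol: str = "vpd",
):
    """Raw multiplexed chamber records for both treatments.

    ``protocol="vpd"`` runs the diurnal-VPD campaign for both treatments;
    ``protocol="co2_steps"`` runs the stepwise CO2 drawdown
    (900/400/200 ppm, 2 days each, constant day VPD) on the eCO2 trees
    only — conductance is generated without any CO2 response, which is
    the null the drawdown test probes.

    Returns ``(records, truth)``: the long-format record table and a
    dict with per-tree true parameters and the per-visit true series.
    """
    proto = config.chamber
    rng_pop, rng_noise, rng_proc = _rngs(seed, 3)

    treatments = ("eCO2",) if protocol == "co2_steps" else tuple(config.treatments)
    trees = []
    for trt in treatments:
        gfac = _effect(effects, "gc_ref", trt)
        afac = config.a_leaf_eco2_factor if trt == "eCO2" else 1.0
        for i in range(config.n_trees):
            gc_ref = config.gc_ref_mean * gfac * _lognorm(rng_pop, config.gc_ref_cv)
            trees.append(
                {
                    "tree_id": f"{trt[0]}{i + 1}",
                    "treatment": trt,
                    "gc_ref": gc_ref,
                    "m": VPD_SLOPE_RATIO * gc_ref,
                    "a_leaf_m2": config.a_leaf_mean_m2 * afac * _lognorm(rng_pop, config.a_leaf_cv),
                }
            )
    tree_params = pd.DataFrame(trees)

    if protocol == "co2_steps":
        total_days = proto.days_per_co2_level * len(proto.co2_levels_ppm)
    else:
        total_days = proto.days

    rec_frames, truth_frames = [], []
    for trt in treatments:
        sub = tree_params[tree_params["treatment"] == trt].reset_index(drop=True)
        chambers = list(sub["tree_id"]) + [f"{trt[0]}_empty{k + 1}" for k in range(proto.n_empty)]
        n_ch = len(chambers)
        n_slots = int(total_days * DAY_S // proto.switch_period)
        slot_idx = np.arange(n_slots)
        slot_start = slot_idx * proto.switch_period
        t_mid = slot_start + proto.switch_period / 2.0
        ch_of_slot = slot_idx % n_ch

        vpd, t_air, par, is_day = _slot_forcing(t_mid, proto)
        if protocol == "co2_steps":
            vpd = np.where(is_day, 1.34, proto.vpd_night)
            t_air = np.where(is_day, 24.2, proto.t_night_c)
            level = np.minimum(
                (t_mid // (proto.days_per_co2_level * DAY_S)).astype(int),
                len(proto.co2_levels_ppm) - 1,
            )
            co2_supply = np.asarray(proto.co2_levels_ppm, dtype=float)[level]
        else:
            co2_supply = np.full(n_slots, 860.0 if trt == "eCO2" else 410.0)

        drift = config.drift_offset + config.drift_amplitude * np.sin(2 * np.pi * t_mid / DAY_S)
        f_m = ch.molar_flow(proto.flow_lpm, t_air, proto.pressure_kpa)
        w_leaf = ch.saturation_mole_fraction(t_air, proto.pressure_kpa)
        e_sat = ch.saturation_vapor_pressure(t_air)

        n_per_slot = int(round(proto.switch_period / proto.record_cadence))
        rows, truths = [], []
        for ci, cid in enumerate(chambers):
            mask = ch_of_slot == ci
            tmid_c, vpd_c, tair_c = t_mid[mask], vpd[mask], t_air[mask]
            par_c, fm_c, wl_c = par[mask], f_m[mask], w_leaf[mask]
            esat_c, drift_c = e_sat[mask], drift[mask]
            co2_c = co2_supply[mask]
            start_c = slot_start[mask]
            is_empty = ci >= len(sub)
            if is_empty:
                w_supply = np.full(tmid_c.shape, proto.empty_w_supply)
                w_sample = w_supply + drift_c
                gc_true = np.full(tmid_c.shape, np.nan)
                e_true = np.zeros_like(tmid_c)
            else:
                row = sub.iloc[ci]
                day_c = par_c > 0
                gc_true = np.where(
                    day_c,
                    row["gc_ref"] - row["m"] * np.log(np.maximum(vpd_c, 1e-6)),
                    config.gc_night_fraction * row["gc_ref"],
                )
                if config.gc_process_sd > 0:
                    # physiological slot-to-slot fluctuation around the curve
                    gc_true = gc_true + rng_proc.normal(
                        0.0, config.gc_process_sd, gc_true.shape
                    )
                w_sample = (esat_c - vpd_c) / proto.pressure_kpa
                if np.any(w_sample >= wl_c):
                    raise ValueError("chamber generator: w_sample >= w_leaf (check VPD forcing)")
                e_true = gc_true * (wl_c - w_sample) / (1.0 - (wl_c + w_sample) / 2.0)
                dw = e_true * row["a_leaf_m2"] * (1.0 - w_sample) / fm_c
                w_supply = w_sample - dw
                if np.any(w_supply <= 1e-4):
                    raise ValueError(
                        "chamber generator: supply air would be drier than 0.1 ppt "
                        "H2O; reduce leaf area or conductance, or raise the flow"
                    )
                # systematic drift contaminates the sample stream
                w_sample = w_sample + drift_c
                truths.append(
                    pd.DataFrame(
                        {
                            "tree_id": cid,
                            "treatment": trt,
                            "time_s": tmid_c,
                            "gc_true": gc_true,
                            "e_true": e_true,
                            "vpd_true": vpd_c,
                            "par": par_c,
                        }
                    )
                )
            k = np.arange(1, n_per_slot + 1)
            rec_t = (start_c[:, None] + k[None, :] * proto.record_cadence).ravel()
            n_rec = rec_t.size

            def _tile(a):
                return np.repeat(a, n_per_slot)

            rows.append(
                pd.DataFrame(
                    {
                        "chamber_id": cid,
                        "time_s": rec_t,
                        "w_supply": _tile(w_supply) + rng_noise.normal(0, config.w_noise_sd, n_rec),
                        "w_sample": _tile(w_sample) + rng_noise.normal(0, config.w_noise_sd, n_rec),
                        "co2_supply": _tile(co2_c),
                        "co2_sample": _tile(co2_c) - np.where(_tile(par_c) > 0, 20.0, 2.0),
                        "flow_lpm": proto.flow_lpm,
                        "t_air_c": _tile(tair_c) + rng_noise.normal(0, config.t_noise_sd, n_rec),
                        "pressure_kpa": proto.pressure_kpa,
                        "par": np.maximum(_tile(par_c), 0.0),
                        "is_empty": is_empty,
                    }
                )
            )
        rec_frames.append(pd.concat(rows, ignore_index=True))
        truth_frames.append(pd.concat(truths, ignore_index=True))

    records = pd.concat(rec_frames, ignore_index=True)
    records = records.sort_values(["time_s", "chamber_id"], kind="stable").reset_index(drop=True)
    records["w_supply"] = records["w_supply"].clip(lower=0.0)
    records["w_sample"] = records["w_sample"].clip(lower=0.0)
    truth = {
        "tree_params": tree_params,
        "series": pd.concat(truth_frames, ignore_index=True),
        "protocol": protocol,
    }
    return records, truth


def _lognorm(rng: np.random.Generator, cv: float) -> float:
    """Unit-median lognormal multiplier with the given coefficient of variation."""
    if cv <= 0:
        return 1.0
    sigma = np.sqrt(np.log(1.0 + cv**2))
    return float(np.exp(rng.normal(0.0, sigma)))


# ---------------------------------------------------------------------------
# wood anatomy
# ---------------------------------------------------------------------------

def generate_conduit_table(effects: TreatmentEffects, config: GeneratorConfig, seed: int):
    """Per-conduit particle tables plus section metadata.

    Minor semi-axes are lognormal, eccentricity uniform in
    ``eccentricity_range``; branch cross-sectional area is lognormal and
    conduit size scales with area^``size_area_exponent`` so the log-area
    covariate in the GLS stage has something to do.  The eCO2 treatment
    multiplies conduit radii by ``conduit_d`` and conduit density by the
    implied CD factor, and its branches are systematically thicker.

    Returns ``(conduits, sections, truth)`` — long-format conduit rows,
    one metadata row per section, and the true effect factors.
    """
    rng = np.random.default_rng(seed)
    conduit_rows, section_rows = [], []
    for trt in config.treatments:
        d_fac = _effect(effects, "conduit_d", trt)
        cd_fac = effects.conduit_density if trt == "eCO2" else 1.0
        area_fac = config.section_area_eco2_factor if trt == "eCO2" else 1.0
        for b in range(int(config.n_branches_anatomy[trt])):
            branch_id = f"{trt[0]}B{b + 1}"
            area_mm2 = (
                config.section_area_mean_mm2
                * area_fac
                * float(np.exp(rng.normal(0.0, config.section_area_sigma)))
            )
            size_mult = (area_mm2 / config.section_area_mean_mm2) ** config.size_area_exponent
            b_med = (
                config.conduit_b_median_um
                * d_fac
                * size_mult
                * _lognorm(rng, config.branch_size_cv)
            )
            n_cond = int(
                round(
                    config.cd_base_per_mm2 * cd_fac * area_mm2 * _lognorm(rng, config.branch_count_cv)
                )
            )
            b_um = b_med * np.exp(rng.normal(0.0, config.conduit_b_sigma, n_cond))
            ecc = rng.uniform(*config.eccentricity_range, n_cond)
            a_um = ecc * b_um
            conduit_rows.append(
                pd.DataFrame(
                    {"branch_id": branch_id, "treatment": trt, "a_um": a_um, "b_um": b_um}
                )
            )
            section_rows.append(
                {
                    "branch_id": branch_id,
                    "treatment": trt,
                    "axylem_m2": area_mm2 * 1e-6,
                    "n_conduits": n_cond,
                }
            )
    conduits = pd.concat(conduit_rows, ignore_index=True)
    sections = pd.DataFrame(section_rows)
    truth = {"conduit_d_factor": effects.conduit_d, "a_lumen_factor": effects.a_lumen}
    return conduits, sections, truth


# ---------------------------------------------------------------------------
# vulnerability curves
# ---------------------------------------------------------------------------

def generate_vulnerability_data(effects: TreatmentEffects, config: GeneratorConfig, seed: int):
    """Flow-centrifuge pressure–conductivity series per branch.

    Pressure steps start at the protocol's first spin (−0.84 MPa) and
    continue in fixed decrements until the true PLC reaches 90%, which
    point is included (so every branch's final PLC is ≥ 90).
    Conductivities are k_max (1 − PLC/100) plus Gaussian noise scaled so
    the PLC noise is ``plc_noise_sd`` points.

    Returns ``(curves, truth)``: long-format series and the true
    per-treatment Weibull parameters.
    """
    rng = np.random.default_rng(seed)
    rows = []
    truth = {}
    for trt in config.treatments:
        params = WeibullParams(
            scale=config.vuln_scale_mpa * _effect(effects, "vuln_scale", trt),
            shape=config.vuln_shape * _effect(effects, "vuln_shape", trt),
        )
        truth[trt] = {"scale": params.scale, "shape": params.shape, "p50": params.p50}
        pressures = [config.vuln_first_pressure]
        while (
            weibull_plc(pressures[-1], params) < 90.0
            and len(pressures) < config.vuln_max_steps
        ):
            pressures.append(pressures[-1] + config.vuln_pressure_step)
        pressures = np.array(pressures)
        plc_true = weibull_plc(pressures, params)
        for b in range(int(config.n_branches_vuln[trt])):
            k_max = config.vuln_kmax * _lognorm(rng, config.vuln_kmax_cv)
            noise = rng.normal(0.0, config.plc_noise_sd / 100.0 * k_max, pressures.size)
            k = k_max * (1.0 - plc_true / 100.0) + noise
            rows.append(
                pd.DataFrame(
                    {
                        "branch_id": f"{trt[0]}V{b + 1}",
                        "treatment": trt,
                        "pressure_mpa": pressures,
                        "conductivity": k,
                        "plc_true": plc_true,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True), truth


# ---------------------------------------------------------------------------
# branch conductivity samples
# ---------------------------------------------------------------------------

def generate_branch_samples(effects: TreatmentEffects, config: GeneratorConfig, seed: int):
    """Bench conductivity samples: K_h, cross-sectional and supported leaf area."""
    rng = np.random.default_rng(seed)
    rows = []
    for trt in config.treatments:
        ks_fac = _effect(effects, "k_s", trt)
        alas_fac = _effect(effects, "al_as", trt)
        for b in range(config.n_branches_conductivity):
            diam_mm = rng.normal(config.branch_diameter_mean_mm, config.branch_diameter_sd_mm)
            area_m2 = np.pi * (diam_mm / 2.0) ** 2 * 1e-6
            k_s = config.ks_mean * ks_fac * _lognorm(rng, config.ks_cv)
            al_as = config.al_as_mean * alas_fac * _lognorm(rng, config.al_as_cv)
            rows.append(
                {
                    "branch_id": f"{trt[0]}H{b + 1}",
                    "treatment": trt,
                    "diameter_mm": diam_mm,
                    "cross_section_area_m2": area_m2,
                    "supported_leaf_area_m2": al_as * area_m2,
                    "k_h": k_s * area_m2,
                    "segment_length_mm": rng.normal(73.91, 3.2),
                }
            )
    truth = {"k_s_factor": effects.k_s, "al_as_factor": effects.al_as}
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# traits and cuticles
# ---------------------------------------------------------------------------

def generate_trait_tables(effects: TreatmentEffects, config: GeneratorConfig, seed: int):
    """Per-tree leaf morphology traits and per-image cuticle counts.

    Tree-level stomatal and epidermal densities are drawn jointly
    (correlation ``sd_ed_correlation``): both densities reflect the same
    epidermal cell packing, which is also why the stomatal index varies
    much less between trees than either density.  Image counts are
    Poisson with the tree density times the image area.
    """
    rng = np.random.default_rng(seed)
    effect_of = {
        "sl_um": "sl", "d_m_um": "d_m", "lw_mm": "lw",
        "la_cm2": "la", "sla_cm2_g": "sla", "aba_ng_g": "aba",
    }
    trait_rows, count_rows = [], []
    sig = np.sqrt(np.log(1.0 + config.cell_density_cv**2))
    rho = config.sd_ed_correlation
    for trt in config.treatments:
        for i in range(config.n_trees):
            tree_id = f"{trt[0]}{i + 1}"
            row = {"tree_id": tree_id, "treatment": trt}
            for trait, eff_name in effect_of.items():
                mean = config.trait_means[trait] * _effect(effects, eff_name, trt)
                row[trait] = mean * _lognorm(rng, config.trait_cvs[trait])
            trait_rows.append(row)

            z0, z1, z2 = rng.normal(0.0, 1.0, 3)
            sd_tree = (
                config.sd_mean
                * _effect(effects, "sd_density", trt)
                * np.exp(sig * (rho * z0 + np.sqrt(1 - rho**2) * z1))
            )
            ed_tree = (
                config.ed_mean
                * _effect(effects, "ed_density", trt)
                * np.exp(sig * (rho * z0 + np.sqrt(1 - rho**2) * z2))
            )
            for img in range(config.n_images):
                count_rows.append(
                    {
                        "tree_id": tree_id,
                        "treatment": trt,
                        "image_id": f"{tree_id}_img{img + 1}",
                        "stomata_count": int(rng.poisson(sd_tree * config.image_area_mm2)),
                        "epidermal_count": int(rng.poisson(ed_tree * config.image_area_mm2)),
                        "image_area_mm2": config.image_area_mm2,
                    }
                )
    return pd.DataFrame(trait_rows), pd.DataFrame(count_rows)


# ---------------------------------------------------------------------------
# dry-down
# ---------------------------------------------------------------------------

def generate_drydown(effects: TreatmentEffects, config: GeneratorConfig, seed: int):
    """Per-tree (Ψ, relative gc, ABA) dry-down trajectories.

    Relative conductance follows the logistic closure model with the
    water potential at stomatal closure near −2.1 MPa in both
    treatments; ABA rises linearly with tension at a common slope
    (the default effects encode "no treatment difference" for both).
    """
    rng = np.random.default_rng(seed)
    psi_hi, psi_lo = config.drydown_psi_range
    frames = []
    truth_rows = []
    for trt in config.treatments:
        aba_fac = _effect(effects, "aba", trt)
        for i in range(config.n_trees):
            tree_id = f"{trt[0]}{i + 1}"
            frac = np.linspace(0.0, 1.0, config.drydown_n_obs)
            psi = psi_hi + (psi_lo - psi_hi) * frac**1.2
            psi = psi + rng.normal(0.0, 0.03, psi.size)
            psi = np.minimum(psi, -0.05)
            z = config.closure_s * (config.closure_psi50 - psi)
            gc_rel = 1.0 / (1.0 + np.exp(z))
            gc_rel_obs = gc_rel + rng.normal(0.0, config.gc_rel_noise_sd, psi.size)
            aba = config.aba0 + config.aba_slope * aba_fac * (-psi)
            aba_obs = aba + rng.normal(0.0, config.aba_noise_sd, psi.size)
            frames.append(
                pd.DataFrame(
                    {
                        "tree_id": tree_id,
                        "treatment": trt,
                        "psi_mpa": psi,
                        "gc_rel": gc_rel_obs,
                        "aba_ng_g": aba_obs,
                    }
                )
            )
            truth_rows.append(
                {
                    "tree_id": tree_id,
                    "treatment": trt,
                    "psi50": config.closure_psi50,
                    "s": config.closure_s,
                    "psi_close": config.closure_psi50
                    - np.log(0.95 / 0.05) / config.closure_s,
                    "aba0": config.aba0,
                    "aba_slope": config.aba_slope * aba_fac,
                }
            )
    return pd.concat(frames, ignore_index=True), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------

def generate_all(
    effects: TreatmentEffects | None = None,
    config: GeneratorConfig | None = None,
    seed: int = 0,
    outdir: str | Path | None = None,
    include_co2_steps: bool = True,
):
    """Generate every pipeline input; optionally write CSVs + truth manifest.

    Sub-generators get independent child seeds spawned from ``seed``, so
    the bundle is a pure function of (effects, config, seed).
    """
    effects = effects or TreatmentEffects()
    config = config or GeneratorConfig()
    seeds = np.random.SeedSequence(seed).generate_state(7) % (2**31)

    records, chamber_truth = generate_chamber_timeseries(effects, config, int(seeds[0]))
    conduits, sections, anat_truth = generate_conduit_table(effects, config, int(seeds[1]))
    curves, vuln_truth = generate_vulnerability_data(effects, config, int(seeds[2]))
    branches, branch_truth = generate_branch_samples(effects, config, int(seeds[3]))
    traits, cuticles = generate_trait_tables(effects, config, int(seeds[4]))
    drydown, drydown_truth = generate_drydown(effects, config, int(seeds[5]))
    co2_records = None
    if include_co2_steps:
        co2_records, _ = generate_chamber_timeseries(
            effects, config, int(seeds[6]), protocol="co2_steps"
        )

    bundle = {
        "chamber_records": records,
        "chamber_truth": chamber_truth,
        "co2_step_records": co2_records,
        "conduits": conduits,
        "sections": sections,
        "anatomy_truth": anat_truth,
        "vulnerability_curves": curves,
        "vulnerability_truth": vuln_truth,
        "branch_samples": branches,
        "branch_truth": branch_truth,
        "traits": traits,
        "cuticle_counts": cuticles,
        "drydown": drydown,
        "drydown_truth": drydown_truth,
        "effects": effects,
        "config": config,
        "seed": seed,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in (
            "chamber_records", "co2_step_records", "conduits", "sections",
            "vulnerability_curves", "branch_samples", "traits",
            "cuticle_counts", "drydown",
        ):
            if bundle[name] is not None:
                bundle[name].to_csv(outdir / f"{name}.csv", index=False)
        chamber_truth["tree_params"][["tree_id", "treatment", "a_leaf_m2"]].to_csv(
            outdir / "trees.csv", index=False
        )
        manifest = {
            "seed": seed,
            "effects": asdict(effects),
            "tree_params": chamber_truth["tree_params"].to_dict(orient="records"),
            "vulnerability_truth": vuln_truth,
            "anatomy_truth": anat_truth,
            "branch_truth": branch_truth,
            "drydown_truth": drydown_truth.to_dict(orient="records"),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return bundle
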