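"""Reduction of multiplexed whole-canopy chamber records to leaf-level fluxes.

The measurement system cycles a single pair of infrared gas analyzers
(absolute + differential) over several canopy chambers plus two empty
reference chambers, visiting each chamber for ``switch_period`` seconds
and logging every ``record_cadence`` seconds.  Only the last ``window``
seconds of each visit — after the tubing has flushed — carry usable
concentrations.  This module turns that raw stream into per-visit
leaf-level transpiration ``E`` and canopy stomatal conductance ``gc``:

    E  = F_m (W_sample - W_supply) / (A_leaf (1 - W_sample))
    gc = E (1 - (W_leaf + W_sample)/2) / (W_leaf - W_sample)

with ``F_m`` the molar flow of the supply air stream, ``W_*`` water
vapor mole fractions and ``W_leaf`` the saturation mole fraction at
chamber air temperature (leaf temperature is taken equal to air
temperature; boundary-layer conductance is neglected — the chambers are
fan-mixed at high flow).  The sign convention is chosen so that a
transpiring plant has positive ``E``.

Empty-chamber H2O differentials track slow analyzer/system drift and are
subtracted from the plant-chamber differentials (baseline correction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Universal gas constant, J mol^-1 K^-1.
GAS_CONSTANT = 8.314462618

#: Columns expected in a raw chamber-record table (long format, one row
#: per logged record).
CHAMBER_RECORD_COLUMNS = [
    "chamber_id",
    "time_s",
    "w_supply",
    "w_sample",
    "co2_supply",
    "co2_sample",
    "flow_lpm",
    "t_air_c",
    "pressure_kpa",
    "par",
    "is_empty",
]


@dataclass
class GasExchangeConfig:
    """Reduction settings for the multiplexed chamber stream.

    Parameters
    ----------
    switch_period
        Seconds each chamber is visited by the multiplexer (default 120).
    window
        Seconds at the end of each visit that are averaged (default 40).
    record_cadence
        Logging interval of the analyzers, s (default 10).
    par_threshold
        Daytime filter for conductance analysis, µmol m⁻² s⁻¹ (default 200).
    reference_vpd
        VPD at which reference conductance is reported, kPa (default 1.0).
    esat_formula
        ``"buck"`` (Buck 1981, default) or ``"tetens"`` saturation
        vapor-pressure formula.
    baseline_correction
        Subtract the mean empty-chamber H2O differential (default True).
    """

    switch_period: float = 120.0
    window: float = 40.0
    record_cadence: float = 10.0
    par_threshold: float = 200.0
    reference_vpd: float = 1.0
    esat_formula: str = "buck"
    baseline_correction: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.window <= self.switch_period:
            raise ValueError("require 0 < window <= switch_period")
        if self.par_threshold < 0:
            raise ValueError("par_threshold must be >= 0")


def molar_flow(flow_volumetric, t_air, pressure):
    """Convert a volumetric supply flow to molar flow via the ideal gas law.

    Parameters
    ----------
    flow_volumetric : array_like
        Supply flow, L min⁻¹.
    t_air : array_like
        Air temperature, °C.
    pressure : array_like
        Atmospheric pressure, kPa.

    Returns
    -------
    ndarray or float
        Molar flow F_m, mol s⁻¹:  n = P V̇ / (R T).
    """
    flow_volumetric = np.asarray(flow_volumetric, dtype=float)
    t_air = np.asarray(t_air, dtype=float)
    pressure = np.asarray(pressure, dtype=float)
    if not (
        np.all(np.isfinite(flow_volumetric))
        and np.all(np.isfinite(t_air))
        and np.all(np.isfinite(pressure))
    ):
        raise ValueError("molar_flow: non-finite input")
    if np.any(flow_volumetric < 0):
        raise ValueError("molar_flow: flow must be >= 0")
    if np.any(t_air <= -273.15):
        raise ValueError("molar_flow: temperature at or below absolute zero")
    if np.any(pressure <= 0):
        raise ValueError("molar_flow: pressure must be > 0")
    vdot = flow_volumetric * 1e-3 / 60.0  # L/min -> m^3/s
    out = pressure * 1e3 * vdot / (GAS_CONSTANT * (t_air + 273.15))
    return out if out.ndim else float(out)


def saturation_vapor_pressure(t_air, formula: str = "buck"):
    """Saturation vapor pressure over liquid water, kPa.

    Buck (1981): e_s = 0.61121 exp(17.502 T / (240.97 + T)); the Tetens
    form is available as an alternative.  ``t_air`` in °C.
    """
    t = np.asarray(t_air, dtype=float)
    if formula == "buck":
        es = 0.61121 * np.exp(17.502 * t / (240.97 + t))
    elif formula == "tetens":
        es = 0.61078 * np.exp(17.27 * t / (237.3 + t))
    else:
        raise ValueError(f"unknown saturation formula: {formula!r}")
    return es if es.ndim else float(es)


def saturation_mole_fraction(t_air, pressure, formula: str = "buck"):
    """Saturated H2O mole fraction W_leaf = e_sat(T) / P (mol mol⁻¹)."""
    pressure = np.asarray(pressure, dtype=float)
    if np.any(pressure <= 0):
        raise ValueError("saturation_mole_fraction: pressure must be > 0")
    out = saturation_vapor_pressure(t_air, formula) / pressure
    return out if np.ndim(out) else float(out)


def transpiration(f_m, w_supply, w_sample, a_leaf):
    """Leaf-level transpiration E, mol m⁻² s⁻¹.

    E = F_m (W_sample − W_supply) / (A_leaf (1 − W_sample)); positive
    when the plant adds water to the air stream.
    """
    f_m = np.asarray(f_m, dtype=float)
    w_supply = np.asarray(w_supply, dtype=float)
    w_sample = np.asarray(w_sample, dtype=float)
    a_leaf = np.asarray(a_leaf, dtype=float)
    if np.any(a_leaf <= 0):
        raise ValueError("transpiration: a_leaf must be > 0")
    if np.any(w_sample >= 1):
        raise ValueError("transpiration: w_sample must be < 1 mol mol^-1")
    out = f_m * (w_sample - w_supply) / (a_leaf * (1.0 - w_sample))
    return out if out.ndim else float(out)


def canopy_conductance(e, w_leaf, w_sample):
    """Canopy stomatal conductance gc, mol H2O m⁻² s⁻¹.

    gc = E (1 − (W_leaf + W_sample)/2) / (W_leaf − W_sample).  Where the
    air is at or above leaf saturation (W_leaf <= W_sample) the
    conductance is undefined; those entries come back as NaN and are
    meant to be excluded (and counted) by the caller, not raised.
    """
    e = np.asarray(e, dtype=float)
    w_leaf = np.asarray(w_leaf, dtype=float)
    w_sample = np.asarray(w_sample, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = e * (1.0 - (w_leaf + w_sample) / 2.0) / (w_leaf - w_sample)
    out = np.where(w_leaf > w_sample, out, np.nan)
    return out if out.ndim else float(out)


def vapor_pressure_deficit(t_air, w_sample, pressure, formula: str = "buck"):
    """Air VPD, kPa: e_sat(T_air) − W_sample · P (chamber air as boundary)."""
    es = saturation_vapor_pressure(t_air, formula)
    out = es - np.asarray(w_sample, dtype=float) * np.asarray(pressure, dtype=float)
    return out if np.ndim(out) else float(out)


def cycle_reduce(records: pd.DataFrame, config: GasExchangeConfig | None = None) -> pd.DataFrame:
    """Collapse a raw multiplexed record stream to one row per chamber visit.

    Contiguous runs of records for a chamber (gaps <= 1.5 x the record
    cadence) form a visit; the mean over the last ``config.window``
    seconds of each visit is emitted.  Visits shorter than the window
    are averaged over whatever records exist, with a warning.
    """
    if config is None:
        config = GasExchangeConfig()
    if records.empty:
        return records.copy()
    df = records.sort_values(["chamber_id", "time_s"], kind="stable").reset_index(drop=True)
    t = df["time_s"].to_numpy(dtype=float)
    new_chamber = df["chamber_id"].ne(df["chamber_id"].shift()).to_numpy()
    dt = np.diff(t, prepend=t[0])
    if np.any((dt <= 0) & ~new_chamber):
        bad = df.loc[(dt <= 0) & ~new_chamber, "chamber_id"].iloc[0]
        raise ValueError(f"chamber {bad}: time not strictly increasing")
    visit_break = new_chamber | (dt > 1.5 * config.record_cadence)
    df["visit_key"] = np.cumsum(visit_break)

    grp = df.groupby("visit_key")
    t_start = grp["time_s"].transform("min").to_numpy()
    t_end = grp["time_s"].transform("max").to_numpy()
    span = t_end - t_start + config.record_cadence
    n_short = int(df.loc[span < config.window, "visit_key"].nunique())
    if n_short:
        logger.warning(
            "%d visits shorter than the %.0f s window; using all their records",
            n_short, config.window,
        )
    win = df[t > t_end - config.window]  # short visits are fully included
    keep_empty = "is_empty" in df.columns
    agg = win.groupby("visit_key").mean(numeric_only=True)
    agg["n_records"] = win.groupby("visit_key").size()
    firsts = df.groupby("visit_key").first()
    agg["chamber_id"] = firsts["chamber_id"]
    if keep_empty:
        agg["is_empty"] = firsts["is_empty"].astype(bool)
    per_chamber_visit = firsts.groupby("chamber_id").cumcount()
    agg["visit_id"] = per_chamber_visit
    out = agg.reset_index(drop=True).sort_values(
        ["time_s", "chamber_id"], kind="stable"
    )
    return out.reset_index(drop=True)


def baseline_correct(
    plant_time: np.ndarray,
    plant_dw: np.ndarray,
    empty_series: Sequence[tuple[np.ndarray, np.ndarray]],
) -> np.ndarray:
    """Subtract the time-interpolated mean empty-chamber H2O differential.

    ``empty_series`` is a sequence of ``(time, dw)`` arrays, one per
    reference chamber.  Each is linearly interpolated onto the plant
    timestamps (held constant beyond its ends) and their mean offset is
    removed from ``plant_dw``.
    """
    plant_time = np.asarray(plant_time, dtype=float)
    plant_dw = np.asarray(plant_dw, dtype=float)
    if not empty_series:
        raise ValueError(
            "baseline_correct: no empty-chamber data in window; pass "
            "baseline_correction=False explicitly to skip the correction"
        )
    offsets = []
    for t_e, dw_e in empty_series:
        t_e = np.asarray(t_e, dtype=float)
        dw_e = np.asarray(dw_e, dtype=float)
        if t_e.size == 0:
            raise ValueError(
                "baseline_correct: an empty-chamber series is empty; pass "
                "baseline_correction=False explicitly to skip the correction"
            )
        offsets.append(np.interp(plant_time, t_e, dw_e))
    return plant_dw - np.mean(offsets, axis=0)


def reduce_gas_exchange(
    records: pd.DataFrame,
    leaf_areas: Mapping[str, float],
    config: GasExchangeConfig | None = None,
) -> pd.DataFrame:
    """Full reduction: raw stream -> per-visit gas-exchange series.

    Steps: visit detection and window averaging (:func:`cycle_reduce`),
    empty-chamber baseline correction of the H2O differential, molar
    flow, transpiration, leaf saturation mole fraction, canopy
    conductance and VPD.  Rows where conductance is undefined
    (``w_leaf <= w_sample``) are excluded and counted in the returned
    frame's ``attrs["n_undefined_gc"]``.

    Parameters
    ----------
    records
        Long-format raw records (:data:`CHAMBER_RECORD_COLUMNS`).
    leaf_areas
        Mapping chamber_id -> two-dimensional shoot leaf area, m²
        (plant chambers only).
    """
    if config is None:
        config = GasExchangeConfig()
    _validate_records(records)
    visits = cycle_reduce(records, config)
    visits["dw"] = visits["w_sample"] - visits["w_supply"]

    empties = visits[visits["is_empty"].astype(bool)]
    plants = visits[~visits["is_empty"].astype(bool)].copy()
    if config.baseline_correction:
        empty_series = [
            (g["time_s"].to_numpy(), g["dw"].to_numpy())
            for _, g in empties.groupby("chamber_id")
        ]
        if not empty_series:
            raise ValueError(
                "reduce_gas_exchange: baseline correction requested but the "
                "stream contains no empty reference chambers; pass a config "
                "with baseline_correction=False to proceed uncorrected"
            )
        corrected = []
        for _, g in plants.groupby("chamber_id", sort=False):
            dw_c = baseline_correct(
                g["time_s"].to_numpy(), g["dw"].to_numpy(), empty_series
            )
            corrected.append(pd.Series(dw_c, index=g.index))
        plants["dw"] = pd.concat(corrected).reindex(plants.index)
    # the corrected differential defines an effective sample mole fraction
    plants["w_sample_corr"] = plants["w_supply"] + plants["dw"]

    missing = set(plants["chamber_id"]) - set(leaf_areas)
    if missing:
        raise ValueError(f"reduce_gas_exchange: no leaf area for chambers {sorted(missing)}")
    a_leaf = plants["chamber_id"].map(leaf_areas).to_numpy(dtype=float)
    if np.any(a_leaf <= 0):
        raise ValueError("reduce_gas_exchange: leaf areas must be > 0")

    f_m = molar_flow(
        plants["flow_lpm"].to_numpy(),
        plants["t_air_c"].to_numpy(),
        plants["pressure_kpa"].to_numpy(),
    )
    w_sample = plants["w_sample_corr"].to_numpy()
    e = transpiration(f_m, plants["w_supply"].to_numpy(), w_sample, a_leaf)
    w_leaf = saturation_mole_fraction(
        plants["t_air_c"].to_numpy(), plants["pressure_kpa"].to_numpy(), config.esat_formula
    )
    gc = canopy_conductance(e, w_leaf, w_sample)
    vpd = vapor_pressure_deficit(
        plants["t_air_c"].to_numpy(), w_sample, plants["pressure_kpa"].to_numpy(),
        config.esat_formula,
    )

    out = pd.DataFrame(
        {
            "chamber_id": plants["chamber_id"].to_numpy(),
            "time_s": plants["time_s"].to_numpy(),
            "e": e,
            "gc": gc,
            "vpd": vpd,
            "par": plants["par"].to_numpy(),
            "t_air_c": plants["t_air_c"].to_numpy(),
            "a_leaf_m2": a_leaf,
            "f_m": f_m,
            "w_leaf": w_leaf,
            "w_sample": w_sample,
            "co2_sample": plants["co2_sample"].to_numpy(),
        }
    )
    n_undef = int(out["gc"].isna().sum())
    if n_undef:
        logger.info("excluded %d visits with undefined gc (w_leaf <= w_sample)", n_undef)
    out = out[out["gc"].notna()].reset_index(drop=True)
    out.attrs["n_undefined_gc"] = n_undef
    return out


def _validate_records(records: pd.DataFrame) -> None:
    missing = [c for c in CHAMBER_RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"chamber records missing columns: {missing}")
    w = records[["w_supply", "w_sample"]].to_numpy(dtype=float)
    if np.any(w < 0) or np.any(w >= 1):
        raise ValueError("H2O mole fractions must lie in [0, 1)")
    if np.any(records["flow_lpm"].to_numpy(dtype=float) < 0):
        raise ValueError("flow must be >= 0")
    if np.any(records["par"].to_numpy(dtype=float) < 0):
        raise ValueError("PAR must be >= 0")


def gc_reference(
    series: pd.DataFrame,
    config: GasExchangeConfig | None = None,
    cal_config=None,
    priors=None,
    tree_col: str = "tree_id",
    treatment_col: str = "treatment",
    seed: int | None = None,
    min_rows: int = 20,
):
    """Reference canopy conductance (gc at VPD = 1 kPa) per tree and treatment.

    Calibrates the log-VPD response model gc = gc_ref − m·ln(VPD/VPD_ref)
    per tree on daytime rows (par > par_threshold) with the DE-MCzs
    sampler, merges the per-tree posteriors into one posterior per
    treatment, and summarizes the gc_ref parameter (median, 95% CI).

    Returns
    -------
    (summary, tree_posteriors, treatment_posteriors)
        ``summary`` is a tidy frame with one row per tree and per
        treatment; non-convergent trees (R̂ > threshold) are flagged in
        its ``converged`` column, never silently accepted.
    """
    from pinehydro import bayes

    if config is None:
        config = GasExchangeConfig()
    if cal_config is None:
        cal_config = bayes.CalibrationConfig(seed=0 if seed is None else seed)
    if priors is None:
        priors = bayes.default_vpd_priors()
    model = bayes.VpdModel(reference_vpd=config.reference_vpd)

    day = series[series["par"] > config.par_threshold]
    tree_posteriors: dict[str, bayes.PosteriorSet] = {}
    rows = []
    for tree, grp in day.groupby(tree_col, sort=True):
        if len(grp) < min_rows:
            raise ValueError(
                f"gc_reference: tree {tree} has {len(grp)} daytime rows; need >= {min_rows}"
            )
        post = bayes.calibrate(
            model, grp["vpd"].to_numpy(), grp["gc"].to_numpy(), priors, cal_config,
            provenance=[str(tree)],
        )
        tree_posteriors[str(tree)] = post
        lo, hi = post.credible_interval("gc_ref", cal_config.ci_level)
        rows.append(
            {
                "level": "tree",
                "id": str(tree),
                "treatment": grp[treatment_col].iloc[0] if treatment_col in grp else "",
                "gc_ref_median": post.median("gc_ref"),
                "ci_lo": lo,
                "ci_hi": hi,
                "rhat_max": float(np.max(post.rhat)),
                "converged": bool(post.converged),
                "n_obs": len(grp),
            }
        )
    tree_frame = pd.DataFrame(rows)
    treatment_posteriors: dict[str, bayes.PosteriorSet] = {}
    for trt, sub in tree_frame.groupby("treatment", sort=True):
        merged = bayes.merge_posteriors([tree_posteriors[i] for i in sub["id"]])
        treatment_posteriors[str(trt)] = merged
        lo, hi = merged.credible_interval("gc_ref", cal_config.ci_level)
        rows.append(
            {
                "level": "treatment",
                "id": str(trt),
                "treatment": str(trt),
                "gc_ref_median": merged.median("gc_ref"),
                "ci_lo": lo,
                "ci_hi": hi,
                "rhat_max": float(sub["rhat_max"].max()),
                "converged": bool(sub["converged"].all()),
                "n_obs": int(sub["n_obs"].sum()),
            }
        )
    summary = pd.DataFrame(rows)
    return summary, tree_posteriors, treatment_posteriors
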