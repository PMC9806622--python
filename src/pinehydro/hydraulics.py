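"""Branch hydraulic conductivity normalization and xylem vulnerability curves.

Measured maximal branch conductivity K_h (kg m MPa⁻¹ s⁻¹) is normalized
by sapwood cross-sectional area (specific conductivity K_s) or by the
leaf area the branch supports (leaf-specific conductivity K_l).  Flow-
centrifuge series of conductivity at increasingly negative xylem
pressure Ψ give percent loss of conductivity

    PLC_i = 100 (1 − k_i / k_ref),

with k_ref the conductivity at the first (least negative) spin,
−0.84 MPa by protocol.  The PLC(Ψ) relationship is modelled as a
two-parameter Weibull in tension magnitude,

    PLC(Ψ) = 100 (1 − exp(−(|Ψ|/scale)^shape)),

where ``scale`` (MPa) is the tension at ~63.2% loss and ``shape``
controls steepness.  P12/P50/P88 tensions follow in closed form:
|P_x| = scale · (−ln(1 − x/100))^(1/shape).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class WeibullParams:
    """Weibull vulnerability-curve parameters on tension magnitude."""

    scale: float  # MPa, tension at 100(1-1/e) ~ 63.2% PLC
    shape: float  # dimensionless steepness

    def __post_init__(self) -> None:
        if self.scale <= 0 or self.shape <= 0:
            raise ValueError("WeibullParams: scale and shape must be > 0")

    @property
    def p12(self) -> float:
        return px(self, 12.0)

    @property
    def p50(self) -> float:
        return px(self, 50.0)

    @property
    def p88(self) -> float:
        return px(self, 88.0)


def specific_conductivity(k_h, cross_section_area):
    """K_s = K_h / sapwood cross-sectional area (kg m⁻¹ MPa⁻¹ s⁻¹)."""
    k_h = np.asarray(k_h, dtype=float)
    area = np.asarray(cross_section_area, dtype=float)
    if np.any(area <= 0):
        raise ValueError("specific_conductivity: area must be > 0")
    out = k_h / area
    return out if out.ndim else float(out)


def leaf_specific_conductivity(k_h, supported_leaf_area):
    """K_l = K_h / supported leaf area (kg m⁻¹ MPa⁻¹ s⁻¹)."""
    k_h = np.asarray(k_h, dtype=float)
    area = np.asarray(supported_leaf_area, dtype=float)
    if np.any(area <= 0):
        raise ValueError("leaf_specific_conductivity: leaf area must be > 0")
    out = k_h / area
    return out if out.ndim else float(out)


def leaf_sapwood_ratio(supported_leaf_area, cross_section_area):
    """Leaf-to-sapwood area ratio A_l : A_s (dimensionless)."""
    la = np.asarray(supported_leaf_area, dtype=float)
    sa = np.asarray(cross_section_area, dtype=float)
    if np.any(la <= 0) or np.any(sa <= 0):
        raise ValueError("leaf_sapwood_ratio: areas must be > 0")
    out = la / sa
    return out if out.ndim else float(out)


def plc_series(pressures, conductivities, clamp: bool = True):
    """Percent loss of conductivity along a centrifuge series.

    ``pressures`` must be strictly decreasing (increasingly negative);
    the reference conductivity is the value at the first (least
    negative) pressure.  Values are clamped to [0, 100] unless
    ``clamp=False`` (raw values are useful for diagnostics).
    """
    p = np.asarray(pressures, dtype=float)
    k = np.asarray(conductivities, dtype=float)
    if p.size < 2:
        raise ValueError("plc_series: need >= 2 measurements")
    if np.any(np.diff(p) >= 0):
        raise ValueError("plc_series: pressures must be strictly decreasing")
    k_ref = k[0]
    if k_ref <= 0:
        raise ValueError("plc_series: reference conductivity must be > 0")
    plc = 100.0 * (1.0 - k / k_ref)
    if clamp:
        plc = np.clip(plc, 0.0, 100.0)
    return plc


def weibull_plc(psi, params: WeibullParams):
    """PLC (%) at xylem pressure ``psi`` (MPa, negative under tension)."""
    tension = np.abs(np.asarray(psi, dtype=float))
    out = 100.0 * (1.0 - np.exp(-((tension / params.scale) ** params.shape)))
    return out if out.ndim else float(out)


def px(params: WeibullParams, x: float) -> float:
    """Tension magnitude |P_x| (MPa) at which PLC reaches x %."""
    if not 0 < x < 100:
        raise ValueError("px: x must lie in (0, 100)")
    return float(params.scale * (-np.log(1.0 - x / 100.0)) ** (1.0 / params.shape))


def weibull_from_px(p50: float, p88: float) -> WeibullParams:
    """Recover (scale, shape) from the P50 and P88 tensions (magnitudes)."""
    if not 0 < p50 < p88:
        raise ValueError("weibull_from_px: need 0 < |P50| < |P88|")
    l50 = -np.log(0.50)
    l88 = -np.log(0.12)
    shape = np.log(l88 / l50) / np.log(p88 / p50)
    scale = p50 / l50 ** (1.0 / shape)
    return WeibullParams(scale=float(scale), shape=float(shape))


def fit_vulnerability_curves(
    curves: pd.DataFrame,
    cal_config=None,
    priors=None,
    branch_col: str = "branch_id",
    treatment_col: str = "treatment",
    ci_level: float = 0.95,
):
    """Bayesian Weibull fits per branch, merged into treatment posteriors.

    ``curves`` is long format with columns ``branch_id``,
    ``pressure_mpa`` (negative, strictly decreasing per branch),
    ``conductivity`` and optionally ``treatment``.  PLC is computed per
    branch against the first-spin conductivity and the Weibull
    calibrated with the DE-MCzs sampler; per-branch posteriors are
    merged with equal weight into one posterior per treatment.

    Returns ``(summary, branch_posteriors, treatment_posteriors)`` where
    the summary holds medians and credible intervals of scale, shape and
    the derived P12/P50/P88 tensions (as −MPa magnitudes).
    """
    from pinehydro import bayes

    if cal_config is None:
        cal_config = bayes.CalibrationConfig(seed=0)
    if priors is None:
        priors = bayes.default_weibull_priors()
    model = bayes.WeibullPlcModel()

    branch_posteriors: dict[str, "bayes.PosteriorSet"] = {}
    rows = []
    for branch, grp in curves.groupby(branch_col, sort=True):
        grp = grp.sort_values("pressure_mpa", ascending=False)
        # fit on raw PLC: clamping censors the noise at 0/100 and biases the
        # Gaussian likelihood (shape in particular); clamped values are for
        # reporting, not fitting
        plc = plc_series(
            grp["pressure_mpa"].to_numpy(), grp["conductivity"].to_numpy(), clamp=False
        )
        post = bayes.calibrate(
            model, grp["pressure_mpa"].to_numpy(), plc, priors, cal_config,
            provenance=[str(branch)],
        )
        branch_posteriors[str(branch)] = post
        rows.append(
            _vuln_row("branch", str(branch),
                      grp[treatment_col].iloc[0] if treatment_col in grp else "",
                      post, ci_level)
        )
    branch_frame = pd.DataFrame(rows)
    treatment_posteriors = {}
    for trt, sub in branch_frame.groupby("treatment", sort=True):
        merged = bayes.merge_posteriors([branch_posteriors[i] for i in sub["id"]])
        treatment_posteriors[str(trt)] = merged
        row = _vuln_row("treatment", str(trt), str(trt), merged, ci_level)
        row["rhat_max"] = float(sub["rhat_max"].max())
        row["converged"] = bool(sub["converged"].all())
        rows.append(row)
    return pd.DataFrame(rows), branch_posteriors, treatment_posteriors


def _vuln_row(level, ident, treatment, post, ci_level):
    from pinehydro import bayes  # noqa: F401  (posterior helpers)

    flat = post.flat_samples()
    scale_s = flat[:, post.param_names.index("scale")]
    shape_s = flat[:, post.param_names.index("shape")]
    row = {
        "level": level,
        "id": ident,
        "treatment": treatment,
        "rhat_max": float(np.max(post.rhat)) if post.rhat is not None else np.nan,
        "converged": bool(post.converged),
    }
    for name, samples in (("scale", scale_s), ("shape", shape_s)):
        lo, hi = np.quantile(samples, [(1 - ci_level) / 2, (1 + ci_level) / 2])
        row[f"{name}_median"] = float(np.median(samples))
        row[f"{name}_lo"], row[f"{name}_hi"] = float(lo), float(hi)
    for x, name in ((12.0, "p12"), (50.0, "p50"), (88.0, "p88")):
        px_s = scale_s * (-np.log(1.0 - x / 100.0)) ** (1.0 / shape_s)
        lo, hi = np.quantile(px_s, [(1 - ci_level) / 2, (1 + ci_level) / 2])
        row[f"{name}_median"] = float(np.median(px_s))
        row[f"{name}_lo"], row[f"{name}_hi"] = float(lo), float(hi)
    return row
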