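"""Xylem anatomy metrics from per-conduit particle tables.

A cross-section's conduits come as major/minor semi-axes (a, b, µm) of
fitted ellipses.  Per-conduit equivalent diameter

    D = (32 (a b)^3 / (a^2 + b^2))^(1/4)

follows the elliptical-tube conductivity equivalence; summaries over a
section are the hydraulically weighted diameter D_h = ΣD⁵/ΣD⁴, conduit
density CD (n mm⁻²), lumen-to-sapwood area ratio A_lumen (%), and the
potential hydraulic conductivity from Hagen–Poiseuille,

    K_p = π ρ ΣD⁴ / (128 η A_xylem)   [kg m⁻¹ MPa⁻¹ s⁻¹]

with water viscosity η = 1.002e-9 MPa s and density ρ = 998.2 kg m⁻³
(20 °C), D in m and A_xylem the sapwood area in m².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

WATER_VISCOSITY_MPA_S = 1.002e-9  # MPa s, 20 degC
WATER_DENSITY = 998.2  # kg m^-3, 20 degC


@dataclass
class CrossSectionMetrics:
    """Section-level anatomy summary (reporting units as in the field)."""

    axylem_m2: float
    n_conduits: int
    d_mean_um: float
    d_h_um: float
    cd_per_mm2: float
    a_lumen_pct: float
    k_p: float  # kg m^-1 MPa^-1 s^-1

    @property
    def axylem_mm2(self) -> float:
        return self.axylem_m2 * 1e6

    def as_dict(self) -> dict:
        return {
            "axylem_mm2": self.axylem_mm2,
            "n_conduits": self.n_conduits,
            "d_mean_um": self.d_mean_um,
            "d_h_um": self.d_h_um,
            "cd_per_mm2": self.cd_per_mm2,
            "a_lumen_pct": self.a_lumen_pct,
            "k_p": self.k_p,
        }


def conduit_diameter(a, b):
    """Equivalent conduit diameter D (µm) from ellipse semi-axes a >= b (µm)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("conduit_diameter: axes must be > 0")
    out = (32.0 * (a * b) ** 3 / (a**2 + b**2)) ** 0.25
    return out if out.ndim else float(out)


def hydraulic_diameter(diameters):
    """Hydraulically weighted diameter D_h = ΣD⁵/ΣD⁴ (same units as input)."""
    d = np.asarray(diameters, dtype=float)
    if d.size == 0:
        raise ValueError("hydraulic_diameter: empty diameter list")
    if np.any(d <= 0):
        raise ValueError("hydraulic_diameter: diameters must be > 0")
    return float(np.sum(d**5) / np.sum(d**4))


def potential_conductivity(diameters_m, axylem_m2):
    """Hagen–Poiseuille potential conductivity K_p, kg m⁻¹ MPa⁻¹ s⁻¹.

    ``diameters_m`` are per-conduit equivalent diameters in m; an empty
    set gives 0.
    """
    if axylem_m2 <= 0:
        raise ValueError("potential_conductivity: axylem must be > 0")
    d = np.asarray(diameters_m, dtype=float)
    if d.size == 0:
        return 0.0
    return float(
        np.pi * WATER_DENSITY * np.sum(d**4) / (128.0 * WATER_VISCOSITY_MPA_S * axylem_m2)
    )


def read_conduit_table(
    df: pd.DataFrame, axis_convention: str, a_col: str = "a_um", b_col: str = "b_um"
) -> pd.DataFrame:
    """Normalize a particle table to semi-axes in µm.

    ``axis_convention`` must be given explicitly as ``"radius"`` (columns
    already hold semi-axes) or ``"diameter"`` (columns hold full axis
    lengths, halved on ingest) — particle-analysis exports differ and a
    silent factor-two error is the dominant failure mode.
    """
    if axis_convention not in ("radius", "diameter"):
        raise ValueError("axis_convention must be 'radius' or 'diameter'")
    out = df.copy()
    scale = 0.5 if axis_convention == "diameter" else 1.0
    out["a_um"] = out[a_col].to_numpy(dtype=float) * scale
    out["b_um"] = out[b_col].to_numpy(dtype=float) * scale
    if np.any(out["a_um"].to_numpy() < out["b_um"].to_numpy()):
        a = np.maximum(out["a_um"], out["b_um"])
        b = np.minimum(out["a_um"], out["b_um"])
        out["a_um"], out["b_um"] = a, b
    if "lumen_area_um2" not in out.columns:
        out["lumen_area_um2"] = np.pi * out["a_um"] * out["b_um"]
    return out


def cross_section_metrics(conduits: pd.DataFrame, axylem_m2: float) -> CrossSectionMetrics:
    """Assemble all section-level metrics from a normalized conduit table.

    ``conduits`` needs columns ``a_um``/``b_um`` (semi-axes, µm) and
    optionally ``lumen_area_um2`` (defaults to the ellipse area π·a·b).
    """
    if axylem_m2 <= 0:
        raise ValueError("cross_section_metrics: axylem must be > 0")
    a = conduits["a_um"].to_numpy(dtype=float)
    b = conduits["b_um"].to_numpy(dtype=float)
    if "lumen_area_um2" in conduits.columns:
        lumen = conduits["lumen_area_um2"].to_numpy(dtype=float)
    else:
        lumen = np.pi * a * b
    lumen_m2 = float(np.sum(lumen)) * 1e-12
    if lumen_m2 > axylem_m2:
        raise ValueError(
            "cross_section_metrics: total lumen area exceeds sapwood area "
            "(impossible geometry; check axis_convention and units)"
        )
    d_um = conduit_diameter(a, b)
    n = int(d_um.size) if np.ndim(d_um) else 1
    d_um = np.atleast_1d(d_um)
    return CrossSectionMetrics(
        axylem_m2=float(axylem_m2),
        n_conduits=n,
        d_mean_um=float(np.mean(d_um)),
        d_h_um=hydraulic_diameter(d_um),
        cd_per_mm2=n / (axylem_m2 * 1e6),
        a_lumen_pct=100.0 * lumen_m2 / axylem_m2,
        k_p=potential_conductivity(d_um * 1e-6, axylem_m2),
    )
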