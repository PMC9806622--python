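"""Stomatal and leaf-morphology traits from cuticle count tables.

Stomatal density (SD) and epidermal pavement cell density (ED) are cell
counts per mm² of cuticle image; the stomatal index

    SI (%) = 100 · SD / (SD + ED)

is computed per image and then averaged per leaf, matching the field
convention (typically five images per cuticle).  Averaging per-image SI
is not the same as the SI of pooled counts when per-image densities
differ (Jensen gap); the pooled-count variant is provided as a
secondary column.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Columns expected in a cuticle count table (one row per image).
CUTICLE_COLUMNS = ["tree_id", "image_id", "stomata_count", "epidermal_count", "image_area_mm2"]


def stomatal_index(sd, ed):
    """Stomatal index SI = 100·SD/(SD + ED), %.  Inputs are densities or counts."""
    sd = np.asarray(sd, dtype=float)
    ed = np.asarray(ed, dtype=float)
    if np.any(sd < 0) or np.any(ed < 0):
        raise ValueError("stomatal_index: counts/densities must be >= 0")
    tot = sd + ed
    if np.any(tot == 0):
        raise ValueError("stomatal_index: SD + ED must be > 0")
    out = 100.0 * sd / tot
    return out if out.ndim else float(out)


def aggregate_cuticle(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-leaf SD, ED and SI from per-image counts.

    Per-image densities are count/area (n mm⁻²); per-leaf SD and ED are
    means of per-image densities and per-leaf SI is the mean of
    per-image SI values.  ``si_pooled`` gives the SI of the pooled
    counts for comparison.
    """
    missing = [c for c in CUTICLE_COLUMNS if c not in counts.columns]
    if missing:
        raise ValueError(f"cuticle table missing columns: {missing}")
    area = counts["image_area_mm2"].to_numpy(dtype=float)
    if np.any(area <= 0):
        raise ValueError("aggregate_cuticle: image_area must be > 0")
    df = counts.copy()
    df["sd_img"] = df["stomata_count"] / df["image_area_mm2"]
    df["ed_img"] = df["epidermal_count"] / df["image_area_mm2"]
    df["si_img"] = stomatal_index(df["sd_img"].to_numpy(), df["ed_img"].to_numpy())
    out = (
        df.groupby("tree_id")
        .agg(
            sd=("sd_img", "mean"),
            ed=("ed_img", "mean"),
            si=("si_img", "mean"),
            n_images=("image_id", "size"),
            stomata_total=("stomata_count", "sum"),
            epidermal_total=("epidermal_count", "sum"),
        )
        .reset_index()
    )
    out["si_pooled"] = stomatal_index(
        out["stomata_total"].to_numpy(), out["epidermal_total"].to_numpy()
    )
    return out.drop(columns=["stomata_total", "epidermal_total"])


def canopy_leaf_area(leaf_dry_mass, sla):
    """Canopy leaf area (m²) from leaf dry mass (g) and SLA (cm² g⁻¹)."""
    leaf_dry_mass = np.asarray(leaf_dry_mass, dtype=float)
    sla = np.asarray(sla, dtype=float)
    if np.any(leaf_dry_mass <= 0) or np.any(sla <= 0):
        raise ValueError("canopy_leaf_area: inputs must be > 0")
    out = leaf_dry_mass * sla * 1e-4  # cm^2 -> m^2
    return out if out.ndim else float(out)
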