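"""Treatment-comparison report assembly and percent contrasts."""

from __future__ import annotations

import numpy as np


def percent_contrast(treated, reference):
    """Percent contrast 100·(treated/reference − 1).

    The convention used for treatment tables: e.g. reference-VPD
    conductance medians 0.20 vs 0.09 mol m⁻² s⁻¹ give −55%.
    """
    treated = np.asarray(treated, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if np.any(reference == 0):
        raise ValueError("percent_contrast: reference value must be nonzero")
    out = 100.0 * (treated / reference - 1.0)
    return out if out.ndim else float(out)
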