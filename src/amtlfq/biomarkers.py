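"""Biomarker preprocessing conventions for the CSF panel.

HIV RNA values below the 40 copies/mL detection limit (or flagged as below
detection) are assigned a floor of 39 copies/mL and all values are log10
transformed.  NFL values under the older assay's 125 ng/L lower limit are
expressed as 124 ng/L.  A newer NFL assay generation is harmonized onto the
older scale by ordinary least-squares linear regression on paired
calibration measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

RNA_DETECTION_LIMIT = 40.0  # copies/mL
RNA_FLOOR = 39.0  # copies/mL assigned below detection
NFL_LIMIT = 125.0
NFL_FLOOR = 124.0


def preprocess_rna(values, below_detection=None, floor: float = RNA_FLOOR,
                   limit: float = RNA_DETECTION_LIMIT) -> np.ndarray:
    """Floor sub-detection HIV RNA at 39 copies/mL, then log10 transform.

    ``below_detection`` is an optional boolean flag array; values below the
    detection limit are floored whether or not they are flagged.  NaN
    (e.g. uninfected subjects, RNA not measured) propagates.
    """
    v = np.asarray(values, dtype=float)
    flagged = (
        np.zeros(v.shape, dtype=bool)
        if below_detection is None
        else np.asarray(below_detection, dtype=bool)
    )
    if np.any((v < 0) & ~flagged & ~np.isnan(v)):
        raise ValueError("negative unflagged RNA value")
    out = np.where(flagged | (v < limit), floor, v)
    out = np.where(np.isnan(v), np.nan, out)
    return np.log10(out)


def preprocess_nfl(values, floor: float = NFL_FLOOR, limit: float = NFL_LIMIT) -> np.ndarray:
    """Express NFL values below the assay lower limit as the floor value."""
    v = np.asarray(values, dtype=float)
    if np.any(v[~np.isnan(v)] < 0):
        raise ValueError("negative NFL value")
    return np.where(v < limit, floor, v)


@dataclass(frozen=True)
class LinearHarmonization:
    """OLS conversion old = intercept + slope * new between assay generations."""

    intercept: float
    slope: float
    r_squared: float
    n: int

    def convert(self, new_values) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(new_values, dtype=float)


def harmonize_linear(new_assay, old_assay, new_values=None):
    """Fit old ~ new on calibration pairs; optionally convert new values.

    Returns the fit alone, or ``(fit, converted)`` when ``new_values`` is
    given.  Requires >= 3 pairs with non-degenerate spread.
    """
    x = np.asarray(new_assay, dtype=float)
    y = np.asarray(old_assay, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 calibration pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate calibration: zero spread")
    res = stats.linregress(x, y)
    fit = LinearHarmonization(
        intercept=float(res.intercept),
        slope=float(res.slope),
        r_squared=float(res.rvalue**2),
        n=int(x.size),
    )
    if new_values is None:
        return fit
    return fit, fit.convert(new_values)


def preprocess_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Apply the RNA and NFL conventions to a raw per-sample biomarker table.

    Expects columns ``rna_copies_ml``, ``rna_below_detection``, ``neopterin``,
    ``nfl`` plus metadata; returns the table with ``rna_log10`` and floored
    ``nfl``, indexed by ``sample_id``.
    """
    out = panel.copy()
    out["rna_log10"] = preprocess_rna(
        out["rna_copies_ml"], out.get("rna_below_detection")
    )
    out["nfl"] = preprocess_nfl(out["nfl"])
    if (out["neopterin"].dropna() <= 0).any():
        raise ValueError("neopterin must be > 0")
    return out.set_index("sample_id", drop=False)
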