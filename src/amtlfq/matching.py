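"""LC-MS feature to AMT-tag assignment in mass-NET space.

A feature matches the tags whose theoretical mass lies within the ppm
tolerance (default +/-10 ppm) and whose consensus NET lies within the NET
tolerance.  Among multiple candidates the match minimizing the scaled
squared distance (ppm_error/ppm_tol)**2 + (net_error/net_tol)**2 is kept;
exact distance ties go to the lower tag mass so matching is deterministic.
Each feature yields at most one match; multiple features may hit one tag.

The dispersion of matched ppm errors is summarized robustly (MAD * 1.4826)
because the tolerance window truncates the tails and contaminating false
matches bias a plain standard deviation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .library import AmtDatabase

DEFAULT_PPM_TOL = 10.0
DEFAULT_NET_TOL = 0.025

MATCH_COLUMNS = [
    "run_id", "sample_id", "mono_mass_da", "elution_net", "intensity",
    "peptide", "protein_ids", "theoretical_mass", "tag_net",
    "ppm_error", "net_error", "match_distance",
]


def ppm_error(observed_mass: float, theoretical_mass: float) -> float:
    """Signed relative mass error in parts per million."""
    if np.any(np.asarray(theoretical_mass) <= 0):
        raise ValueError("theoretical_mass must be > 0")
    return 1e6 * (observed_mass - theoretical_mass) / theoretical_mass


def _candidate_pairs(obs_mass: np.ndarray, tag_mass_sorted: np.ndarray, ppm_tol: float):
    """Index pairs (feature, tag) within the ppm window, vectorized."""
    lo = np.searchsorted(tag_mass_sorted, obs_mass / (1.0 + ppm_tol * 1e-6), side="left")
    hi = np.searchsorted(tag_mass_sorted, obs_mass / (1.0 - ppm_tol * 1e-6), side="right")
    counts = hi - lo
    feat_idx = np.repeat(np.arange(obs_mass.size), counts)
    # concatenated ranges lo[i]..hi[i] without a Python loop
    offsets = np.concatenate(([0], np.cumsum(counts)))
    tag_idx = np.arange(offsets[-1]) - np.repeat(offsets[:-1] - lo, counts)
    return feat_idx, tag_idx


def match_run(
    features: pd.DataFrame,
    db: AmtDatabase,
    ppm_tol: float = DEFAULT_PPM_TOL,
    net_tol: float = DEFAULT_NET_TOL,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Match features (any number of runs) against the AMT database.

    Returns ``(matches, unmatched)``; ``matches`` carries the feature
    columns plus peptide, errors, and the scaled match distance.
    """
    if ppm_tol <= 0 or net_tol <= 0:
        raise ValueError("tolerances must be > 0")
    if len(db) == 0:
        raise ValueError("empty AMT database")

    tag_mass = db.tags["theoretical_mass"].to_numpy()
    tag_net = db.tags["net"].to_numpy()
    obs_mass = features["mono_mass_da"].to_numpy(dtype=float)
    obs_net = features["elution_net"].to_numpy(dtype=float)

    fi, ti = _candidate_pairs(obs_mass, tag_mass, ppm_tol)
    perr = 1e6 * (obs_mass[fi] - tag_mass[ti]) / tag_mass[ti]
    nerr = obs_net[fi] - tag_net[ti]
    ok = (np.abs(perr) <= ppm_tol) & (np.abs(nerr) <= net_tol)
    fi, ti, perr, nerr = fi[ok], ti[ok], perr[ok], nerr[ok]
    dist = (perr / ppm_tol) ** 2 + (nerr / net_tol) ** 2

    # best candidate per feature: sort by (feature, distance, tag mass)
    order = np.lexsort((tag_mass[ti], dist, fi))
    fi, ti, perr, nerr, dist = fi[order], ti[order], perr[order], nerr[order], dist[order]
    first = np.ones(fi.size, dtype=bool)
    first[1:] = fi[1:] != fi[:-1]
    fi, ti, perr, nerr, dist = fi[first], ti[first], perr[first], nerr[first], dist[first]

    matches = features.iloc[fi].reset_index(drop=True).copy()
    matches["peptide"] = db.tags["peptide"].to_numpy()[ti]
    matches["protein_ids"] = db.tags["protein_ids"].to_numpy()[ti]
    matches["theoretical_mass"] = tag_mass[ti]
    matches["tag_net"] = tag_net[ti]
    matches["ppm_error"] = perr
    matches["net_error"] = nerr
    matches["match_distance"] = dist

    unmatched_mask = np.ones(len(features), dtype=bool)
    unmatched_mask[fi] = False
    unmatched = features[unmatched_mask].reset_index(drop=True)
    return matches, unmatched


def match_run_bruteforce(
    features: pd.DataFrame,
    db: AmtDatabase,
    ppm_tol: float = DEFAULT_PPM_TOL,
    net_tol: float = DEFAULT_NET_TOL,
) -> pd.DataFrame:
    """Exhaustive all-pairs matcher with the identical rule (reference path).

    O(features x tags); used to validate the indexed matcher.
    """
    tag_mass = db.tags["theoretical_mass"].to_numpy()
    tag_net = db.tags["net"].to_numpy()
    rows = []
    for i in range(len(features)):
        m = float(features["mono_mass_da"].iat[i])
        n = float(features["elution_net"].iat[i])
        perr = 1e6 * (m - tag_mass) / tag_mass
        nerr = n - tag_net
        ok = (np.abs(perr) <= ppm_tol) & (np.abs(nerr) <= net_tol)
        if not ok.any():
            continue
        cand = np.flatnonzero(ok)
        dist = (perr[cand] / ppm_tol) ** 2 + (nerr[cand] / net_tol) ** 2
        order = np.lexsort((tag_mass[cand], dist))
        best = cand[order[0]]
        rows.append(
            {
                "feature_index": i,
                "peptide": db.tags["peptide"].iat[best],
                "ppm_error": perr[best],
                "net_error": nerr[best],
                "match_distance": float(dist[order[0]]),
            }
        )
    return pd.DataFrame(rows)


def estimate_sigma_ppm(matches: pd.DataFrame, min_matches: int = 30) -> float:
    """Robust SD of the matched ppm-error distribution (MAD * 1.4826)."""
    err = matches["ppm_error"].to_numpy(dtype=float) if isinstance(matches, pd.DataFrame) else np.asarray(matches, dtype=float)
    if err.size < min_matches:
        raise ValueError(f"need >= {min_matches} matches to estimate sigma, got {err.size}")
    return float(stats.median_abs_deviation(err, scale="normal"))
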