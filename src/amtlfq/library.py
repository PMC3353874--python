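"""Identification filtering and AMT-tag database construction.

The confidence filter keeps a peptide-spectrum record when its posterior
probability is at least 0.5 and its SEQUEST cross-correlation score clears a
charge-dependent threshold (1.9 / 2.2 / 3.5 for 1+ / 2+ / >=3+) for peptides
seen in a single MS/MS spectrum, or the relaxed 1.9 threshold for peptides
observed in two or more spectra.  Passing decoy records estimate the
false-discovery rate of the filter; only target records enter the database.

An AMT tag pairs a peptide's theoretical neutral monoisotopic mass with its
consensus normalized elution time (NET, median over observations) and its
protein mapping; the database indexes tags by mass for window queries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chem import peptide_mass

DEFAULT_PROB_MIN = 0.5
DEFAULT_XCORR_SINGLE = {1: 1.9, 2: 2.2, 3: 3.5}  # charge >= 3 uses 3.5
DEFAULT_XCORR_MULTI = 1.9

ID_COLUMNS = [
    "peptide", "charge", "xcorr", "delta_cn", "spectra_count",
    "prob", "is_decoy", "protein_ids", "elution_net",
]


def _xcorr_threshold(charge: int, table: dict[int, float]) -> float:
    return table[min(int(charge), max(table))]


def passes_filter(
    charge: int,
    xcorr: float,
    spectra_count: int,
    prob: float,
    prob_min: float = DEFAULT_PROB_MIN,
    xcorr_single: dict[int, float] | None = None,
    xcorr_multi: float = DEFAULT_XCORR_MULTI,
    delta_cn: float | None = None,
    delta_cn_min: float | None = None,
) -> bool:
    """Single-record confidence rule; see module docstring."""
    if charge < 1 or spectra_count < 1 or not (0.0 <= prob <= 1.0):
        raise ValueError("malformed identification record")
    xcorr_single = xcorr_single or DEFAULT_XCORR_SINGLE
    if prob < prob_min:
        return False
    if delta_cn_min is not None and (delta_cn is None or delta_cn < delta_cn_min):
        return False
    if spectra_count >= 2:
        return xcorr >= xcorr_multi
    return xcorr >= _xcorr_threshold(charge, xcorr_single)


def filter_identifications(
    records: pd.DataFrame,
    prob_min: float = DEFAULT_PROB_MIN,
    xcorr_single: dict[int, float] | None = None,
    xcorr_multi: float = DEFAULT_XCORR_MULTI,
    delta_cn_min: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the confidence filter; returns (kept targets, kept decoys).

    Decoys are filtered by the identical rule but kept separately for FDR
    estimation and never enter the database.
    """
    xcorr_single = xcorr_single or DEFAULT_XCORR_SINGLE
    df = records
    if (df["charge"] < 1).any() or (df["spectra_count"] < 1).any():
        raise ValueError("malformed identification record: charge/spectra_count < 1")
    if ((df["prob"] < 0) | (df["prob"] > 1)).any():
        raise ValueError("malformed identification record: prob outside [0,1]")
    thr = df["charge"].map(lambda c: _xcorr_threshold(c, xcorr_single))
    single_ok = (df["spectra_count"] == 1) & (df["xcorr"] >= thr)
    multi_ok = (df["spectra_count"] >= 2) & (df["xcorr"] >= xcorr_multi)
    keep = (df["prob"] >= prob_min) & (single_ok | multi_ok)
    if delta_cn_min is not None:
        keep &= df["delta_cn"] >= delta_cn_min
    kept = df[keep]
    return (
        kept[~kept["is_decoy"]].reset_index(drop=True),
        kept[kept["is_decoy"]].reset_index(drop=True),
    )


def decoy_fdr(n_target_kept: int, n_decoy_kept: int) -> float:
    """Decoy-based FDR estimate: decoys / targets, capped at 1."""
    if n_target_kept < 0 or n_decoy_kept < 0:
        raise ValueError("counts must be >= 0")
    if n_target_kept == 0:
        if n_decoy_kept > 0:
            warnings.warn("decoys pass but no targets do; FDR reported as 1.0")
            return 1.0
        return 0.0
    return min(1.0, n_decoy_kept / n_target_kept)


def normalize_elution(times, library_nets=None):
    """Rescale one run's raw elution times to NET in [0, 1].

    Default: affine min-max map (min -> 0, max -> 1).  If ``library_nets``
    (same length, NET of the matching tags) is given, a least-squares linear
    regression of library NET on raw time is used instead — a second-pass
    option for runs with gradient drift.
    """
    t = np.asarray(times, dtype=float)
    if t.size < 2 or np.ptp(t) == 0:
        raise ValueError("need >= 2 distinct elution times to normalize")
    if library_nets is not None:
        b, a = np.polyfit(t, np.asarray(library_nets, dtype=float), 1)
        return np.clip(a + b * t, 0.0, 1.0)
    return (t - t.min()) / np.ptp(t)


@dataclass
class AmtDatabase:
    """AMT tags unique by peptide, mass-sorted for window queries."""

    tags: pd.DataFrame  # peptide, theoretical_mass, net, protein_ids, n_observations

    def __post_init__(self) -> None:
        if self.tags["peptide"].duplicated().any():
            raise ValueError("duplicate peptides in AMT database")
        self.tags = self.tags.sort_values(
            ["theoretical_mass", "peptide"], ignore_index=True
        )
        self._masses = self.tags["theoretical_mass"].to_numpy()

    def __len__(self) -> int:
        return len(self.tags)

    def query_mass_window(self, lo: float, hi: float) -> pd.DataFrame:
        """Tags with theoretical mass in [lo, hi] (inclusive)."""
        i = np.searchsorted(self._masses, lo, side="left")
        j = np.searchsorted(self._masses, hi, side="right")
        return self.tags.iloc[i:j]

    def to_tsv(self, path) -> None:
        out = self.tags.copy()
        out["theoretical_mass"] = out["theoretical_mass"].map(lambda v: f"{v:.6f}")
        out["net"] = out["net"].map(lambda v: f"{v:.6f}")
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "AmtDatabase":
        return cls(pd.read_csv(path, sep="\t"))


def build_database(kept_records: pd.DataFrame) -> AmtDatabase:
    """Collapse kept target records into one AMT tag per distinct peptide.

    Theoretical mass is recomputed from the sequence; NET is the median of
    the peptide's observed normalized elution times; protein ids are the
    union over records.  Peptides lacking any elution observation are
    excluded with a warning.
    """
    if len(kept_records) == 0:
        raise ValueError("no kept records to build a database from")
    if kept_records["is_decoy"].any():
        raise ValueError("decoy records must not enter the AMT database")
    rows = []
    dropped = 0
    for pep, grp in kept_records.groupby("peptide", sort=True):
        nets = grp["elution_net"].dropna()
        if nets.empty:
            dropped += 1
            continue
        pids = sorted({p for s in grp["protein_ids"] for p in str(s).split(";")})
        rows.append(
            {
                "peptide": pep,
                "theoretical_mass": peptide_mass(pep),
                "net": float(nets.median()),
                "protein_ids": ";".join(pids),
                "n_observations": int(len(grp)),
            }
        )
    if dropped:
        warnings.warn(f"{dropped} peptide(s) had no elution observation; excluded")
    return AmtDatabase(pd.DataFrame(rows))
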