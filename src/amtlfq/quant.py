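"""Label-free quantification: peptide abundance matrix and R-rollup.

Abundance matrices are pandas DataFrames (rows = peptides or proteins,
columns = samples) of log2 intensities with missingness encoded as NaN,
never as 0.

R-rollup scales each peptide of a protein onto a reference peptide (the one
observed in the most samples; ties go to the higher median abundance) by the
median log2 offset over their shared samples, then takes the per-sample
median across the scaled peptides.  Proteins are quantified only from a
minimum of two peptides; peptides mapping to more than one protein are, by
default, excluded from rollup to avoid double counting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class RollupMap:
    """Bookkeeping of one rollup: reference peptides, offsets, exclusions."""

    peptides_by_protein: dict[str, list[str]] = field(default_factory=dict)
    reference_peptide: dict[str, str] = field(default_factory=dict)
    offsets: dict[str, dict[str, float]] = field(default_factory=dict)
    excluded_proteins: list[str] = field(default_factory=list)
    shared_peptides: list[str] = field(default_factory=list)

    def report(self) -> pd.DataFrame:
        rows = []
        for prot, peps in self.peptides_by_protein.items():
            for pep in peps:
                rows.append(
                    {
                        "protein_id": prot,
                        "peptide": pep,
                        "is_reference": pep == self.reference_peptide[prot],
                        "log2_offset": self.offsets[prot][pep],
                    }
                )
        return pd.DataFrame(rows)


def assemble_peptide_matrix(
    matches: pd.DataFrame, run_to_sample: dict[str, str] | pd.Series
) -> pd.DataFrame:
    """Peptide x sample log2 matrix from matched features.

    Within a run, intensities of features assigned to the same peptide are
    summed before the log2 transform; across a sample's duplicate runs the
    log2 intensities are averaged over the runs where the peptide was
    observed.  A peptide absent from every duplicate is missing (NaN).
    """
    r2s = dict(run_to_sample) if not isinstance(run_to_sample, dict) else run_to_sample
    unknown = set(matches["run_id"]) - set(r2s)
    if unknown:
        raise ValueError(f"run ids with no sample mapping: {sorted(unknown)[:5]}")
    df = matches[["run_id", "peptide", "intensity"]].copy()
    if (df["intensity"] <= 0).any():
        raise ValueError("intensities must be positive")
    per_run = df.groupby(["run_id", "peptide"], sort=True)["intensity"].sum()
    log2 = np.log2(per_run).reset_index()
    log2["sample_id"] = log2["run_id"].map(r2s)
    mat = (
        log2.groupby(["peptide", "sample_id"])["intensity"]
        .mean()
        .unstack("sample_id")
    )
    # keep every mapped sample as a column, observed or not
    all_samples = sorted(set(r2s.values()))
    return mat.reindex(columns=all_samples)


def _parse_mapping(mapping) -> dict[str, list[str]]:
    """protein -> peptide list from either a dict or a peptide->'A;B' table."""
    if isinstance(mapping, dict):
        return {p: list(v) for p, v in mapping.items()}
    out: dict[str, list[str]] = {}
    for pep, pids in mapping.items():
        for pid in str(pids).split(";"):
            out.setdefault(pid, []).append(pep)
    return out


def rrollup(
    peptides: pd.DataFrame,
    mapping,
    min_peptides: int = 2,
    min_presence: float = 0.25,
    shared_mode: str = "exclude",
) -> tuple[pd.DataFrame, RollupMap]:
    """Roll peptide log2 abundances up to proteins (see module docstring).

    Parameters
    ----------
    peptides : log2 peptide x sample matrix (NaN = missing).
    mapping : dict protein -> peptides, or Series peptide -> "P1;P2".
    min_peptides : minimum peptides required to quantify a protein.
    min_presence : minimum fraction of samples a peptide must be observed in
        to enter rollup (guards offset estimation from 1-2 shared samples).
    shared_mode : "exclude" drops peptides mapping to several proteins;
        "razor" assigns them to the mapped protein with the most unique
        peptides (ties: lexicographically first).
    """
    if shared_mode not in ("exclude", "razor"):
        raise ValueError("shared_mode must be 'exclude' or 'razor'")
    prot2pep = _parse_mapping(mapping)
    pep_owner_count: dict[str, int] = {}
    for peps in prot2pep.values():
        for pep in peps:
            pep_owner_count[pep] = pep_owner_count.get(pep, 0) + 1
    shared = sorted(p for p, c in pep_owner_count.items() if c > 1)

    if shared_mode == "razor":
        uniq_counts = {
            prot: sum(1 for p in peps if pep_owner_count[p] == 1)
            for prot, peps in prot2pep.items()
        }
        winner: dict[str, str] = {}
        for prot in sorted(prot2pep):
            for pep in prot2pep[prot]:
                if pep_owner_count[pep] > 1:
                    best = winner.get(pep)
                    if best is None or uniq_counts[prot] > uniq_counts[best]:
                        winner[pep] = prot
        prot2pep = {
            prot: [p for p in peps if pep_owner_count[p] == 1 or winner[p] == prot]
            for prot, peps in prot2pep.items()
        }
    else:
        prot2pep = {
            prot: [p for p in peps if pep_owner_count[p] == 1]
            for prot, peps in prot2pep.items()
        }

    n_samples = peptides.shape[1]
    min_obs = max(1, int(np.ceil(min_presence * n_samples)))
    rmap = RollupMap(shared_peptides=shared)
    protein_rows = {}

    for prot in sorted(prot2pep):
        peps = [p for p in prot2pep[prot] if p in peptides.index]
        sub = peptides.loc[peps]
        sub = sub[sub.notna().sum(axis=1) >= min_obs]
        if len(sub) < min_peptides:
            rmap.excluded_proteins.append(prot)
            continue
        counts = sub.notna().sum(axis=1)
        medians = sub.median(axis=1)
        ref = sorted(
            sub.index, key=lambda p: (-counts[p], -medians[p], p)
        )[0]
        ref_row = sub.loc[ref]
        offsets: dict[str, float] = {}
        scaled_rows = []
        kept_peps = []
        for pep in sub.index:
            diff = (ref_row - sub.loc[pep]).dropna()
            if diff.empty and pep != ref:
                warnings.warn(
                    f"{prot}: peptide {pep} never co-observed with reference; dropped"
                )
                continue
            off = 0.0 if pep == ref else float(diff.median())
            offsets[pep] = off
            scaled_rows.append(sub.loc[pep] + off)
            kept_peps.append(pep)
        if len(kept_peps) < min_peptides:
            rmap.excluded_proteins.append(prot)
            continue
        scaled = pd.DataFrame(scaled_rows, index=kept_peps)
        protein_rows[prot] = scaled.median(axis=0)
        rmap.peptides_by_protein[prot] = kept_peps
        rmap.reference_peptide[prot] = ref
        rmap.offsets[prot] = offsets

    proteins = pd.DataFrame(protein_rows).T
    proteins = proteins.reindex(columns=peptides.columns)
    proteins.index.name = "protein_id"
    return proteins, rmap


def median_center(matrix: pd.DataFrame) -> pd.DataFrame:
    """Optional cross-sample normalization: subtract each sample's median."""
    return matrix - matrix.median(axis=0)


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", na_rep="NA", float_format="%.6f")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
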