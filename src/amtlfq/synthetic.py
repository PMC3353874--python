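"""Synthetic longitudinal CSF LC-MS cohort generator.

Emulates a label-free AMT-tag study design: uninfected control subjects with
a single lumbar puncture each, infected subjects sampled longitudinally
around the start of combination antiretroviral therapy (cART), duplicate
LC-MS runs per sample, and three orthogonal CSF biomarkers (HIV RNA,
neopterin, NFL) whose trajectories decline after treatment start.  A chosen
subset of proteins is coupled to the biomarkers with a configurable target
correlation; the planted structure is exported as a ground-truth manifest so
downstream screens can be scored for sensitivity and false-positive rate.

The generative model for the true log2 abundance of protein p in sample s is

    x[p, s] = baseline_p
            + group_effect_p * I(s infected)
            + subject_signature[p, subject(s)]
            + sum_b loading[p, b] * z_b(s)
            + eps[p, s]

where z_b is the biomarker standardized over infected samples and the
loading magnitude is calibrated so that the population correlation between a
coupled protein and its biomarker equals ``loading_magnitude``.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .chem import digest, peptide_mass, validate_sequence

__all__ = [
    "ProteinEntry",
    "SimulationConfig",
    "SyntheticGroundTruth",
    "SyntheticStudy",
    "simulate_study",
    "emit_runs",
    "true_net",
    "write_fasta",
    "digest",
    "peptide_mass",
]

# Approximate human proteome residue frequencies; K+R together ~0.11 so the
# average fully tryptic fragment is ~9 residues long.
_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
_RESIDUE_FREQ = np.array(
    [0.070, 0.023, 0.047, 0.071, 0.036, 0.066, 0.026, 0.043, 0.057, 0.100,
     0.021, 0.036, 0.063, 0.048, 0.057, 0.083, 0.054, 0.060, 0.012, 0.027]
)
_RESIDUE_FREQ = _RESIDUE_FREQ / _RESIDUE_FREQ.sum()

_RNA_DETECTION_LIMIT = 40.0  # copies/mL
_RNA_FLOOR = 39.0

XCORR_THRESHOLDS = {1: 1.9, 2: 2.2, 3: 3.5}  # charge >= 3 shares the 3.5 cut


@dataclass(frozen=True)
class ProteinEntry:
    """One protein in the simulated library."""

    protein_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.protein_id}: empty sequence")
        validate_sequence(self.sequence)


@dataclass
class SimulationConfig:
    """Cohort, noise, and planted-effect parameters for a synthetic study.

    Defaults mirror the study design the pipeline targets: 12 uninfected and
    14 infected subjects, 79 infected samples, duplicate runs, mass error
    with a 2.0 ppm SD, and 40 neopterin-coupled proteins out of 300 at a
    target absolute correlation of 0.6.
    """

    n_proteins: int = 300
    n_uninfected_subjects: int = 12
    n_infected_subjects: int = 14
    samples_per_infected_subject: tuple[int, int] = (4, 7)
    total_infected_samples: int | None = 79
    duplicates_per_sample: int = 2
    sigma_ppm: float = 2.0
    sigma_net: float = 0.01
    dropout_rate: float = 0.15
    baseline_log2_mean: float = 20.0
    baseline_log2_sd: float = 1.5
    subject_effect_sd: float = 0.3
    group_effect_sd: float = 0.8
    residual_sd: float = 0.5
    peptide_offset_sd: float = 1.0
    n_neopterin_coupled: int = 40
    n_nfl_coupled: int = 0
    n_rna_coupled: int = 0
    n_overlap: int = 0
    loading_magnitude: float = 0.6
    plant_nonresponder: bool = True
    protein_length_range: tuple[int, int] = (150, 400)
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_proteins": self.n_proteins,
            "n_uninfected_subjects": self.n_uninfected_subjects,
            "n_infected_subjects": self.n_infected_subjects,
            "duplicates_per_sample": self.duplicates_per_sample,
            "n_neopterin_coupled": self.n_neopterin_coupled,
            "n_nfl_coupled": self.n_nfl_coupled,
            "n_rna_coupled": self.n_rna_coupled,
            "n_overlap": self.n_overlap,
        }
        for name, v in counts.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.sigma_ppm < 0:
            raise ValueError("sigma_ppm must be >= 0")
        if self.sigma_net < 0:
            raise ValueError("sigma_net must be >= 0")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        if not (0.0 <= self.loading_magnitude < 1.0):
            raise ValueError("loading_magnitude must be in [0, 1)")
        if self.n_overlap > min(self.n_neopterin_coupled, self.n_nfl_coupled) and self.n_overlap > 0:
            raise ValueError("n_overlap cannot exceed the smaller coupled set")
        n_coupled = (
            self.n_neopterin_coupled
            + self.n_nfl_coupled
            - self.n_overlap
            + self.n_rna_coupled
        )
        if n_coupled > self.n_proteins:
            raise ValueError(
                f"planted couplings ({n_coupled}) exceed n_proteins ({self.n_proteins})"
            )
        lo, hi = self.samples_per_infected_subject
        if lo < 1 or hi < lo:
            raise ValueError("samples_per_infected_subject must be a valid range")


@dataclass
class SyntheticGroundTruth:
    """Planted structure: coupled-set memberships, loadings, latent effects."""

    memberships: dict[str, set[str]]
    loadings: pd.DataFrame  # proteins x (neopterin, nfl, rna_log10), signed
    subject_signatures: pd.DataFrame  # proteins x subjects
    group_effect: pd.Series  # per protein

    def to_manifest(self) -> dict:
        return {
            "memberships": {k: sorted(v) for k, v in self.memberships.items()},
            "loadings": {
                b: self.loadings[b].round(10).to_dict() for b in self.loadings.columns
            },
            "group_effect": self.group_effect.round(10).to_dict(),
        }


@dataclass
class SyntheticStudy:
    config: SimulationConfig
    proteins: list[ProteinEntry]
    peptides: pd.DataFrame  # peptide, protein_ids, mass, net, log2_offset
    samples: pd.DataFrame  # sample_id, subject_id, group, week, on_treatment
    panel: pd.DataFrame  # raw biomarker table (pre-flooring), per sample
    true_log2: pd.DataFrame  # proteins x samples
    ground_truth: SyntheticGroundTruth
    features: pd.DataFrame | None = field(default=None, repr=False)
    identifications: pd.DataFrame | None = field(default=None, repr=False)


def true_net(sequence: str) -> float:
    """Deterministic pseudo-NET in [0.05, 0.95] from a hash of the sequence."""
    h = hashlib.sha1(sequence.encode("ascii")).digest()
    return 0.05 + 0.9 * (int.from_bytes(h[:8], "big") / 2.0**64)


def _random_protein(rng: np.random.Generator, length_range: tuple[int, int]) -> str:
    length = int(rng.integers(length_range[0], length_range[1] + 1))
    idx = rng.choice(len(_RESIDUES), size=length, p=_RESIDUE_FREQ)
    return "".join(_RESIDUES[i] for i in idx)


def _usable_peptides(sequence: str) -> list[str]:
    return [p for p in digest(sequence, max_missed=0) if 6 <= len(p) <= 30]


def _build_library(rng: np.random.Generator, cfg: SimulationConfig):
    proteins: list[ProteinEntry] = []
    rows = []
    pep_owner: dict[str, list[str]] = {}
    for i in range(cfg.n_proteins):
        pid = f"SYN{i + 1:04d}"
        # retry until the protein digests into >= 2 usable tryptic peptides
        for _ in range(100):
            seq = _random_protein(rng, cfg.protein_length_range)
            peps = _usable_peptides(seq)
            if len(peps) >= 2:
                break
        else:  # pragma: no cover - essentially impossible at default lengths
            raise RuntimeError("could not generate a digestible protein")
        proteins.append(ProteinEntry(pid, seq))
        for pep in peps:
            pep_owner.setdefault(pep, []).append(pid)
    for pep, pids in pep_owner.items():
        rows.append(
            {
                "peptide": pep,
                "protein_ids": ";".join(pids),
                "mass": peptide_mass(pep),
                "net": true_net(pep),
            }
        )
    peptides = pd.DataFrame(rows).sort_values("peptide", ignore_index=True)
    peptides["log2_offset"] = rng.normal(0.0, cfg.peptide_offset_sd, len(peptides))
    return proteins, peptides


def _infected_sample_counts(rng: np.random.Generator, cfg: SimulationConfig) -> list[int]:
    lo, hi = cfg.samples_per_infected_subject
    n = cfg.n_infected_subjects
    if cfg.total_infected_samples is None:
        return [int(rng.integers(lo, hi + 1)) for _ in range(n)]
    total = cfg.total_infected_samples
    if not (n * lo <= total <= n * hi):
        raise ValueError(
            f"total_infected_samples={total} infeasible for {n} subjects in range ({lo},{hi})"
        )
    base, rem = divmod(total, n)
    counts = np.full(n, base)
    counts[rng.choice(n, size=rem, replace=False)] += 1
    return counts.tolist()


def _biomarker_trajectories(rng, cfg, subjects_inf, counts):
    """Per-sample biomarker values with post-cART decline (Figure-1 style)."""
    rows = []
    nonresp = subjects_inf[-1] if (cfg.plant_nonresponder and subjects_inf) else None
    for subj, k in zip(subjects_inf, counts):
        weeks = np.concatenate([[0], np.cumsum(rng.integers(4, 25, size=k - 1))])
        rna0 = float(np.clip(rng.normal(4.5, 0.7), 2.5, 6.5))
        rna_rate = float(rng.uniform(0.08, 0.35))
        neo_base = float(rng.lognormal(math.log(40.0), 0.4))
        neo_final = float(rng.lognormal(math.log(8.0), 0.3))
        neo_tau = float(rng.uniform(8.0, 30.0))
        nfl_base = float(rng.lognormal(math.log(700.0), 0.7))
        nfl_final = float(rng.lognormal(math.log(150.0), 0.4))
        nfl_tau = float(rng.uniform(10.0, 40.0))
        if subj == nonresp:
            # one subject fails to suppress: near-flat trajectories
            rna_rate = 0.004
            neo_tau = nfl_tau = 400.0
        for w in weeks:
            rna_log10 = max(math.log10(_RNA_FLOOR), rna0 - rna_rate * w)
            copies = 10.0**rna_log10
            rows.append(
                {
                    "sample_id": f"{subj}_w{int(w):03d}",
                    "subject_id": subj,
                    "group": "infected",
                    "week": int(w),
                    "on_treatment": w > 0,
                    "rna_copies_ml": copies,
                    "rna_below_detection": copies < _RNA_DETECTION_LIMIT
                    or rna_log10 <= math.log10(_RNA_FLOOR) + 1e-12,
                    "neopterin": neo_final + (neo_base - neo_final) * math.exp(-w / neo_tau),
                    "nfl": nfl_final + (nfl_base - nfl_final) * math.exp(-w / nfl_tau),
                }
            )
    return rows, nonresp


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate the latent cohort: library, samples, biomarkers, true matrix.

    Deterministic given ``config.seed``.  LC-MS run tables are produced by
    :func:`emit_runs`.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])

    proteins, peptides = _build_library(rng, config)
    protein_ids = [p.protein_id for p in proteins]

    subjects_uni = [f"C{i + 1:02d}" for i in range(config.n_uninfected_subjects)]
    subjects_inf = [f"P{i + 1:02d}" for i in range(config.n_infected_subjects)]
    counts = _infected_sample_counts(rng, config)

    inf_rows, nonresponder = _biomarker_trajectories(rng, config, subjects_inf, counts)
    uni_rows = [
        {
            "sample_id": f"{subj}_w000",
            "subject_id": subj,
            "group": "uninfected",
            "week": 0,
            "on_treatment": False,
            "rna_copies_ml": np.nan,
            "rna_below_detection": False,
            "neopterin": float(rng.lognormal(math.log(6.0), 0.3)),
            "nfl": float(rng.lognormal(math.log(140.0), 0.35)),
        }
        for subj in subjects_uni
    ]
    panel = pd.DataFrame(inf_rows + uni_rows)
    samples = panel[["sample_id", "subject_id", "group", "week", "on_treatment"]].copy()

    # Screen-scale biomarkers: RNA floored+log10, NFL floored, neopterin as is.
    from .biomarkers import NFL_FLOOR, NFL_LIMIT  # local import avoids a cycle

    rna_log10 = np.where(
        panel["rna_below_detection"] | (panel["rna_copies_ml"] < _RNA_DETECTION_LIMIT),
        math.log10(_RNA_FLOOR),
        np.log10(panel["rna_copies_ml"].to_numpy()),
    )
    rna_log10 = np.where(panel["rna_copies_ml"].isna(), np.nan, rna_log10)
    nfl_scr = np.where(panel["nfl"] < NFL_LIMIT, NFL_FLOOR, panel["nfl"])
    screen_scale = pd.DataFrame(
        {
            "neopterin": panel["neopterin"].to_numpy(),
            "nfl": nfl_scr,
            "rna_log10": rna_log10,
        },
        index=panel["sample_id"].tolist(),
    )

    infected_mask = (panel["group"] == "infected").to_numpy()
    z = pd.DataFrame(index=panel["sample_id"], columns=screen_scale.columns, dtype=float)
    for b in screen_scale.columns:
        vals = screen_scale[b].to_numpy(dtype=float)
        mu = np.nanmean(vals[infected_mask])
        sd = np.nanstd(vals[infected_mask], ddof=1)
        sd = sd if sd > 0 else 1.0
        z[b] = (vals - mu) / sd
    z["rna_log10"] = z["rna_log10"].fillna(0.0)  # uninfected: no RNA contribution

    # Membership assignment
    perm = rng.permutation(protein_ids)
    i = 0
    neo_set = set(perm[i : i + config.n_neopterin_coupled]); i += config.n_neopterin_coupled
    overlap = set(list(neo_set)[: config.n_overlap])
    extra_nfl = config.n_nfl_coupled - config.n_overlap
    nfl_set = overlap | set(perm[i : i + extra_nfl]); i += extra_nfl
    rna_set = set(perm[i : i + config.n_rna_coupled]); i += config.n_rna_coupled
    coupled = neo_set | nfl_set | rna_set
    null_set = set(protein_ids) - coupled

    sigma_noise = math.hypot(config.subject_effect_sd, config.residual_sd)
    m = config.loading_magnitude
    lam = 0.0 if m == 0 else m * sigma_noise / math.sqrt(1.0 - m * m)
    if lam == 0.0 and m > 0:  # noiseless config: any nonzero loading gives |r|=1
        lam = 1.0

    loadings = pd.DataFrame(
        0.0, index=protein_ids, columns=["neopterin", "nfl", "rna_log10"]
    )
    for b, members in (("neopterin", neo_set), ("nfl", nfl_set), ("rna_log10", rna_set)):
        for pid in sorted(members):
            loadings.loc[pid, b] = lam * (1.0 if rng.random() < 0.5 else -1.0)

    n_p, n_s = len(protein_ids), len(panel)
    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n_p)
    group_eff = rng.normal(0.0, config.group_effect_sd, n_p)
    all_subjects = subjects_inf + subjects_uni
    subj_sig = rng.normal(0.0, config.subject_effect_sd, (n_p, len(all_subjects)))
    eps = rng.normal(0.0, config.residual_sd, (n_p, n_s))

    subj_idx = panel["subject_id"].map({s: i for i, s in enumerate(all_subjects)}).to_numpy()
    x = (
        baseline[:, None]
        + np.outer(group_eff, infected_mask.astype(float))
        + subj_sig[:, subj_idx]
        + loadings.to_numpy() @ z.to_numpy().T
        + eps
    )
    true_log2 = pd.DataFrame(x, index=protein_ids, columns=panel["sample_id"].tolist())

    gt = SyntheticGroundTruth(
        memberships={
            "neopterin": neo_set,
            "nfl": nfl_set,
            "rna_log10": rna_set,
            "overlap": overlap,
            "null": null_set,
            "nonresponder_subject": {nonresponder} if nonresponder else set(),
        },
        loadings=loadings,
        subject_signatures=pd.DataFrame(subj_sig, index=protein_ids, columns=all_subjects),
        group_effect=pd.Series(group_eff, index=protein_ids),
    )
    return SyntheticStudy(
        config=config,
        proteins=proteins,
        peptides=peptides,
        samples=samples,
        panel=panel,
        true_log2=true_log2,
        ground_truth=gt,
    )


def emit_runs(study: SyntheticStudy) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit per-run LC-MS feature tables and the MS/MS identification table.

    Each sample yields ``duplicates_per_sample`` runs.  A peptide observed in
    a run contributes one feature: mass = theoretical * (1 + e/1e6) with
    e ~ N(0, sigma_ppm); NET = true NET + N(0, sigma_net) clipped to [0, 1];
    intensity = 2**(protein log2 abundance + peptide offset), summed over the
    peptide's parent proteins.  Peptides drop out independently at
    ``dropout_rate``.  The identification table contains target records plus
    an equal number of reversed-sequence decoys drawn from a shifted score
    null, flagged ``is_decoy``.

    Deterministic given the study's config seed; results are attached to
    ``study.features`` / ``study.identifications`` and returned.
    """
    cfg = study.config
    rng = np.random.default_rng([cfg.seed, 1])

    peps = study.peptides
    n_pep = len(peps)
    pep_mass = peps["mass"].to_numpy()
    pep_net = peps["net"].to_numpy()
    pep_off = peps["log2_offset"].to_numpy()
    prot_index = {p: i for i, p in enumerate(study.true_log2.index)}
    owners = [s.split(";") for s in peps["protein_ids"]]

    sample_ids = study.true_log2.columns.tolist()
    x = study.true_log2.to_numpy()
    # raw-scale peptide intensity per sample, summed over parent proteins
    inten = np.zeros((n_pep, len(sample_ids)))
    for j, pids in enumerate(owners):
        for pid in pids:
            inten[j] += 2.0 ** (x[prot_index[pid]] + pep_off[j])

    frames = []
    for si, sid in enumerate(sample_ids):
        for d in range(cfg.duplicates_per_sample):
            run_id = f"{sid}_r{d + 1}"
            keep = rng.random(n_pep) >= cfg.dropout_rate
            ppm_err = rng.normal(0.0, cfg.sigma_ppm, n_pep)
            net_err = rng.normal(0.0, cfg.sigma_net, n_pep) if cfg.sigma_net > 0 else 0.0
            frames.append(
                pd.DataFrame(
                    {
                        "run_id": run_id,
                        "sample_id": sid,
                        "peptide_truth": peps["peptide"].to_numpy()[keep],
                        "mono_mass_da": (pep_mass * (1.0 + ppm_err / 1e6))[keep],
                        "elution_net": np.clip(pep_net + net_err, 0.0, 1.0)[keep],
                        "intensity": inten[keep, si],
                    }
                )
            )
    features = pd.concat(frames, ignore_index=True)

    # Identification table: 3 pseudo MS/MS runs over the pooled samples.
    id_rows = []
    for pseudo in range(3):
        seen = rng.random(n_pep) < 0.8
        net_obs = pep_net + (
            rng.normal(0.0, cfg.sigma_net, n_pep) if cfg.sigma_net > 0 else 0.0
        )
        charge = rng.choice([1, 2, 3], size=n_pep, p=[0.15, 0.60, 0.25])
        thr = np.vectorize(lambda c: XCORR_THRESHOLDS[min(int(c), 3)])(charge)
        xcorr = np.maximum(0.3, rng.normal(thr + 1.2, 0.8, n_pep))
        for j in np.flatnonzero(seen):
            id_rows.append(
                {
                    "peptide": peps["peptide"].iat[j],
                    "charge": int(charge[j]),
                    "xcorr": round(float(xcorr[j]), 4),
                    "delta_cn": round(float(rng.uniform(0.05, 0.45)), 4),
                    "spectra_count": int(1 + rng.poisson(1.2)),
                    "prob": round(float(rng.beta(8, 2)), 4),
                    "is_decoy": False,
                    "protein_ids": peps["protein_ids"].iat[j],
                    "elution_net": float(np.clip(net_obs[j], 0.0, 1.0)),
                }
            )
    n_targets = len(id_rows)
    # decoys: reversed sequences, scores from a shifted null
    decoy_idx = rng.integers(0, n_pep, size=n_targets)
    for j in decoy_idx:
        pep = peps["peptide"].iat[int(j)][::-1]
        charge = int(rng.choice([1, 2, 3], p=[0.15, 0.60, 0.25]))
        thr = XCORR_THRESHOLDS[min(charge, 3)]
        id_rows.append(
            {
                "peptide": pep,
                "charge": charge,
                "xcorr": round(float(max(0.1, rng.normal(thr - 0.8, 0.5))), 4),
                "delta_cn": round(float(rng.uniform(0.0, 0.2)), 4),
                "spectra_count": int(1 + rng.poisson(0.15)),
                "prob": round(float(rng.beta(2, 8)), 4),
                "is_decoy": True,
                "protein_ids": "XXX_" + peps["protein_ids"].iat[int(j)],
                "elution_net": round(float(rng.uniform(0.0, 1.0)), 5),
            }
        )
    identifications = pd.DataFrame(id_rows)

    study.features = features
    study.identifications = identifications
    return features, identifications


def write_fasta(proteins: list[ProteinEntry], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for p in proteins:
            fh.write(f">{p.protein_id}\n")
            for i in range(0, len(p.sequence), width):
                fh.write(p.sequence[i : i + width] + "\n")


def write_ground_truth(gt: SyntheticGroundTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(gt.to_manifest(), fh, indent=1, sort_keys=True)


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    for key in ("samples_per_infected_subject", "protein_length_range"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    cfg = SimulationConfig(**d)
    cfg.validate()
    return cfg


def config_to_dict(cfg: SimulationConfig) -> dict:
    d = asdict(cfg)
    d["samples_per_infected_subject"] = list(cfg.samples_per_infected_subject)
    d["protein_length_range"] = list(cfg.protein_length_range)
    return d
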