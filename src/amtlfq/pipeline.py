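"""End-to-end orchestration: simulate -> filter -> database -> match ->
quantify -> biomarkers -> screen -> enrich, as one seeded, logged run.

Every stage writes its table under the output directory; the summary JSON
reports tag count, decoy FDR, match rate, the robust sigma-ppm estimate,
protein counts, per-biomarker screen counts, Venn region counts, and —
because the cohort is synthetic — sensitivity and false-positive rate
against the planted ground truth.  Identical config and seed give
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import biomarkers as bm
from . import enrichment as enr
from . import library as lib
from . import matching as mt
from . import quant as qt
from . import screening as scr
from . import synthetic as syn

log = logging.getLogger("amtlfq")

FEATURE_COLUMNS = ["run_id", "sample_id", "mono_mass_da", "elution_net", "intensity"]


@dataclass
class RunConfig:
    """All knobs of one pipeline run; defaults are the documented study
    conventions (prob >= 0.5, Xcorr 1.9/2.2/3.5, +/-10 ppm, min 2 peptides,
    |r| >= 0.3 & p <= 0.05)."""

    simulation: syn.SimulationConfig = field(default_factory=syn.SimulationConfig)
    prob_min: float = lib.DEFAULT_PROB_MIN
    xcorr_single: dict[int, float] = field(default_factory=lambda: dict(lib.DEFAULT_XCORR_SINGLE))
    xcorr_multi: float = lib.DEFAULT_XCORR_MULTI
    ppm_tol: float = mt.DEFAULT_PPM_TOL
    net_tol: float = mt.DEFAULT_NET_TOL
    min_peptides: int = 2
    min_presence: float = 0.25
    r_cut: float = scr.DEFAULT_R_CUT
    p_cut: float = scr.DEFAULT_P_CUT
    min_n: int = scr.DEFAULT_MIN_N
    cluster_k: int = 2
    protein_cluster_k: int = 5
    seed: int | None = None

    def validate(self) -> None:
        if self.ppm_tol <= 0 or self.net_tol <= 0:
            raise ValueError("ppm_tol and net_tol must be > 0")
        if not (0.0 <= self.prob_min <= 1.0):
            raise ValueError("prob_min must be in [0,1]")
        if self.min_peptides < 1 or self.min_n < 3 or self.cluster_k < 2:
            raise ValueError("min_peptides >= 1, min_n >= 3, cluster_k >= 2 required")
        if not (0 < self.r_cut <= 1) or not (0 < self.p_cut <= 1):
            raise ValueError("r_cut and p_cut must be in (0,1]")
        if self.seed is not None:
            self.simulation.seed = int(self.seed)
        self.simulation.validate()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = syn.config_from_dict(raw.pop("simulation", {}))
        if "xcorr_single" in raw:
            raw["xcorr_single"] = {int(k): float(v) for k, v in raw["xcorr_single"].items()}
        cfg = cls(simulation=sim, **raw)
        cfg.validate()
        return cfg


def _screen_scale_panel(panel: pd.DataFrame) -> pd.DataFrame:
    return bm.preprocess_panel(panel)


def _score_screen(selected_ids: set, truth_members: set, universe: set):
    """Sensitivity and false-positive rate of one screen vs ground truth."""
    truth = truth_members & universe
    nulls = universe - truth_members
    tp = len(selected_ids & truth)
    fp = len(selected_ids & nulls)
    return (
        tp / len(truth) if truth else float("nan"),
        fp / len(nulls) if nulls else float("nan"),
    )


def make_gene_sets(study: syn.SyntheticStudy, n_random: int = 3) -> list[enr.GeneSet]:
    """Example functional sets: the planted memberships plus random sets."""
    gt = study.ground_truth
    rng = np.random.default_rng([study.config.seed, 7])
    ids = sorted(p.protein_id for p in study.proteins)
    sets = []
    for key in ("neopterin", "nfl", "rna_log10"):
        members = gt.memberships.get(key, set())
        if members:
            sets.append(enr.GeneSet(f"PLANTED_{key.upper()}", f"{key}-coupled proteins", frozenset(members)))
    hi = min(40, max(3, len(ids) // 3))
    lo = min(10, hi - 1)
    for i in range(n_random):
        size = int(rng.integers(lo, hi))
        sets.append(
            enr.GeneSet(
                f"RANDOM_{i + 1}",
                "random control set",
                frozenset(rng.choice(ids, size=size, replace=False).tolist()),
            )
        )
    return sets


def write_gmt(sets: list[enr.GeneSet], path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.set_id, gs.name, *sorted(gs.members)]) + "\n")


def run(config: RunConfig, outdir) -> dict:
    """Execute all stages; write intermediates and the summary JSON."""
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config_seed": config.simulation.seed}

    # --- simulate -----------------------------------------------------------
    log.info("stage simulate: generating cohort")
    study = syn.simulate_study(config.simulation)
    features, ids = syn.emit_runs(study)
    syn.write_fasta(study.proteins, out / "library.fasta")
    syn.write_ground_truth(study.ground_truth, out / "ground_truth.json")
    study.panel.to_csv(out / "biomarker_panel_raw.tsv", sep="\t", index=False)
    features[FEATURE_COLUMNS].to_csv(
        out / "features.tsv", sep="\t", index=False, float_format="%.6f"
    )
    ids.to_csv(out / "identifications.tsv", sep="\t", index=False)
    summary["n_samples"] = int(study.samples.shape[0])
    summary["n_runs"] = int(features["run_id"].nunique())
    summary["n_features"] = int(len(features))
    log.info("simulate: %d samples, %d runs, %d features",
             summary["n_samples"], summary["n_runs"], summary["n_features"])

    # --- identification filter + AMT database -------------------------------
    kept, decoys = lib.filter_identifications(
        ids, config.prob_min, config.xcorr_single, config.xcorr_multi
    )
    fdr = lib.decoy_fdr(kept["peptide"].nunique(), decoys["peptide"].nunique())
    db = lib.build_database(kept)
    db.to_tsv(out / "amt_database.tsv")
    summary["n_id_records"] = int(len(ids))
    summary["n_kept_target_records"] = int(len(kept))
    summary["n_amt_tags"] = int(len(db))
    summary["decoy_fdr"] = round(float(fdr), 6)
    log.info("database: %d tags, decoy FDR %.4f", len(db), fdr)

    # --- feature matching ---------------------------------------------------
    matches, unmatched = mt.match_run(features, db, config.ppm_tol, config.net_tol)
    matches.to_csv(out / "matches.tsv", sep="\t", index=False, float_format="%.6f")
    unmatched[FEATURE_COLUMNS].to_csv(out / "unmatched_features.tsv", sep="\t", index=False)
    summary["match_rate"] = round(float(len(matches) / max(1, len(features))), 6)
    summary["sigma_ppm_estimate"] = (
        round(mt.estimate_sigma_ppm(matches), 6) if len(matches) >= 30 else None
    )
    log.info("matching: %.1f%% of features matched, sigma = %s ppm",
             100 * summary["match_rate"], summary["sigma_ppm_estimate"])

    # --- quantification -----------------------------------------------------
    run_to_sample = features.drop_duplicates("run_id").set_index("run_id")["sample_id"]
    pep_matrix = qt.assemble_peptide_matrix(matches, run_to_sample)
    prot_matrix, rmap = qt.rrollup(
        pep_matrix,
        db.tags.set_index("peptide")["protein_ids"],
        min_peptides=config.min_peptides,
        min_presence=config.min_presence,
    )
    qt.write_matrix(pep_matrix, out / "peptide_matrix.tsv")
    qt.write_matrix(prot_matrix, out / "protein_matrix.tsv")
    rmap.report().to_csv(out / "rollup_report.tsv", sep="\t", index=False, float_format="%.6f")
    obs_per_sample = pep_matrix.notna().sum(axis=0)
    summary["n_peptides_quantified"] = int(pep_matrix.shape[0])
    summary["mean_peptides_per_sample"] = round(float(obs_per_sample.mean()), 2)
    summary["n_proteins_quantified"] = int(prot_matrix.shape[0])
    summary["n_proteins_excluded_min_peptides"] = int(len(rmap.excluded_proteins))
    log.info("quantification: %d peptides -> %d proteins",
             pep_matrix.shape[0], prot_matrix.shape[0])

    # --- biomarker preprocessing -------------------------------------------
    panel = _screen_scale_panel(study.panel)
    panel.to_csv(out / "biomarker_panel.tsv", sep="\t", index=False, float_format="%.6f")

    # --- sample correlation structure + clustering -------------------------
    corr, corr_summary = scr.sample_corr_summary(prot_matrix, panel, config.min_n)
    corr.to_csv(out / "sample_correlation.tsv", sep="\t", float_format="%.6f")
    clus = scr.cluster_order(corr, n_clusters=config.cluster_k)
    clus.labels.to_csv(out / "sample_clusters.tsv", sep="\t")
    truth_groups = panel.loc[clus.labels.index, "group"]
    summary["sample_corr"] = {k: round(v, 4) for k, v in corr_summary.items()}
    summary["cluster_ari_vs_group"] = round(
        scr.adjusted_rand_index(truth_groups.to_numpy(), clus.labels.to_numpy()), 4
    )

    # --- biomarker screens --------------------------------------------------
    infected = panel.index[panel["group"] == "infected"].tolist()
    inf_matrix = prot_matrix[[c for c in prot_matrix.columns if c in infected]]
    universe = set(prot_matrix.index)
    gt = study.ground_truth.memberships
    screen_sets: dict[str, set] = {}
    summary["screens"] = {}
    for marker in ("neopterin", "nfl", "rna_log10"):
        res = scr.biomarker_screen(
            inf_matrix, panel.loc[infected, marker],
            config.r_cut, config.p_cut, config.min_n, name=marker,
        )
        res.selected.to_csv(out / f"screen_{marker}.tsv", sep="\t", index=False,
                            float_format="%.6g")
        sel = set(res.selected["protein_id"])
        screen_sets[marker] = sel
        sens, fpr = _score_screen(sel, gt.get(marker, set()), universe)
        summary["screens"][marker] = {
            "n_selected": len(sel),
            "n_positive": res.n_positive,
            "n_negative": res.n_negative,
            "sensitivity": None if np.isnan(sens) else round(sens, 4),
            "false_positive_rate": None if np.isnan(fpr) else round(fpr, 4),
        }
        log.info("screen %s: %d selected (%d+/%d-)", marker, len(sel),
                 res.n_positive, res.n_negative)

    venn = scr.venn_partition(
        screen_sets["neopterin"], screen_sets["nfl"], screen_sets["rna_log10"],
        names=("neopterin", "nfl", "rna"),
    )
    pd.DataFrame(
        [{"region": k, "count": len(v), "members": ";".join(sorted(v))} for k, v in venn.items()]
    ).to_csv(out / "venn_regions.tsv", sep="\t", index=False)
    summary["venn_counts"] = {k: len(v) for k, v in venn.items()}

    # --- protein clusters + enrichment -------------------------------------
    if prot_matrix.shape[0] >= config.protein_cluster_k + 1:
        pcorr = prot_matrix.T.corr(min_periods=config.min_n).fillna(0.0)
        np.fill_diagonal(pcorr.values, 1.0)
        pclus = scr.cluster_order(pcorr, n_clusters=config.protein_cluster_k)
        gene_sets = make_gene_sets(study)
        write_gmt(gene_sets, out / "gene_sets.gmt")
        enrich_tbl = enr.enrich(pclus.labels, gene_sets, universe)
        enrich_tbl.to_csv(out / "enrichment.tsv", sep="\t", index=False, float_format="%.6g")
        summary["n_enrichment_tests"] = int(len(enrich_tbl))
        summary["min_enrichment_p"] = round(float(enrich_tbl["p"].min()), 8) if len(enrich_tbl) else None

    # --- fold change over treatment ----------------------------------------
    pre = panel.index[(panel["group"] == "infected") & (~panel["on_treatment"])].tolist()
    post = panel.index[(panel["group"] == "infected") & panel["on_treatment"]].tolist()
    pre = [s for s in pre if s in prot_matrix.columns]
    post = [s for s in post if s in prot_matrix.columns]
    if pre and post:
        fc = scr.protein_fold_change(prot_matrix, post, pre)
        fc.to_csv(out / "fold_change_art.tsv", sep="\t", float_format="%.6f")
        summary["median_abs_log2_fc_art"] = round(float(fc["log2_fc"].abs().median()), 4)

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary


def demo_config(seed: int = 0) -> RunConfig:
    """A scaled-down cohort for quick end-to-end runs: same design, fewer
    proteins so the demo finishes in seconds."""
    sim = syn.SimulationConfig(
        n_proteins=120,
        n_neopterin_coupled=30,
        n_nfl_coupled=20,
        n_rna_coupled=8,
        n_overlap=5,
        seed=seed,
    )
    return RunConfig(simulation=sim, seed=seed)
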