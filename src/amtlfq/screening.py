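"""Correlation structure, clustering, biomarker screening, ANOVA, fold change.

All correlations are computed on pairwise-complete observations with a
minimum-n floor.  Pearson significance uses the t transform
t = r * sqrt((n-2) / (1-r^2)) with n-2 degrees of freedom, two-sided;
Spearman is Pearson on mid-ranks (average ranks for ties) with the same
transform.  The biomarker screen keeps a protein when |r| >= 0.3 and
p <= 0.05 (both configurable), reporting positive and negative correlates
separately.  Sample dendrograms use average linkage on the distance
d = 1 - r.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

DEFAULT_R_CUT = 0.3
DEFAULT_P_CUT = 0.05
DEFAULT_MIN_N = 10


@dataclass(frozen=True)
class CorrelationRecord:
    id_a: str
    id_b: str
    r: float
    p: float
    n_obs: int


@dataclass
class ScreenResult:
    biomarker: str
    selected: pd.DataFrame  # protein_id, r, p, n_obs, direction
    n_positive: int
    n_negative: int
    all_tested: pd.DataFrame = field(repr=False, default=None)


@dataclass
class ClusterResult:
    linkage: np.ndarray  # scipy merge list with heights
    leaf_order: list
    labels: pd.Series  # flat cluster labels at the requested count


def _t_pvalue(r: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Two-sided p for Pearson r via the t transform with n-2 df."""
    r = np.asarray(r, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
        p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    return np.where(np.abs(r) >= 1.0, 0.0, p)


def pearson_r_p(x, y, id_a: str = "x", id_b: str = "y", min_n: int = 3) -> CorrelationRecord:
    """Pearson r and two-sided p on pairwise-complete pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    n = int(ok.sum())
    if n < min_n:
        raise ValueError(f"need >= {min_n} complete pairs, got {n}")
    xs, ys = x[ok], y[ok]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return CorrelationRecord(id_a, id_b, np.nan, np.nan, n)
    r = float(np.corrcoef(xs, ys)[0, 1])
    r = max(-1.0, min(1.0, r))
    return CorrelationRecord(id_a, id_b, r, float(_t_pvalue(r, n)), n)


def spearman_r_p(x, y, id_a: str = "x", id_b: str = "y", min_n: int = 3) -> CorrelationRecord:
    """Spearman rho: Pearson on mid-ranks, p via the same t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < min_n:
        raise ValueError(f"need >= {min_n} complete pairs")
    rx = stats.rankdata(x[ok])
    ry = stats.rankdata(y[ok])
    rec = pearson_r_p(rx, ry, id_a, id_b, min_n)
    return CorrelationRecord(id_a, id_b, rec.r, rec.p, rec.n_obs)


def _rows_vs_vector(m: np.ndarray, v: np.ndarray):
    """Pairwise-complete Pearson of each matrix row against a vector."""
    mask = ~(np.isnan(m) | np.isnan(v)[None, :])
    n = mask.sum(axis=1).astype(float)
    mz = np.where(mask, m, 0.0)
    vz = np.where(mask, v[None, :], 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        sx = mz.sum(1); sy = vz.sum(1)
        sxx = (mz * mz).sum(1); syy = (vz * vz).sum(1); sxy = (mz * vz).sum(1)
        cov = sxy - sx * sy / n
        vx = sxx - sx**2 / n
        vy = syy - sy**2 / n
        r = cov / np.sqrt(vx * vy)
    r[(vx <= 0) | (vy <= 0)] = np.nan
    return np.clip(r, -1.0, 1.0), n


def biomarker_screen(
    matrix: pd.DataFrame,
    biomarker: pd.Series,
    r_cut: float = DEFAULT_R_CUT,
    p_cut: float = DEFAULT_P_CUT,
    min_n: int = DEFAULT_MIN_N,
    method: str = "pearson",
    name: str | None = None,
) -> ScreenResult:
    """Correlate every protein row with one biomarker and apply the filter.

    Samples are aligned on the intersection of matrix columns and biomarker
    index; proteins with fewer than ``min_n`` complete pairs or zero
    variance are excluded from testing.
    """
    name = name or (biomarker.name if biomarker.name else "biomarker")
    common = [c for c in matrix.columns if c in biomarker.index]
    v = biomarker.loc[common].to_numpy(dtype=float)
    if np.nanstd(v) == 0 or np.isnan(v).all():
        raise ValueError(f"biomarker {name!r} is constant or absent; screen aborted")
    m = matrix[common].to_numpy(dtype=float)
    if method == "spearman":
        # exact pairwise-complete ranks: per-row re-ranking on joint samples
        r = np.full(len(m), np.nan)
        n = np.zeros(len(m))
        for i in range(len(m)):
            ok = ~(np.isnan(m[i]) | np.isnan(v))
            n[i] = ok.sum()
            if n[i] >= 3 and np.ptp(m[i][ok]) > 0 and np.ptp(v[ok]) > 0:
                r[i] = np.corrcoef(stats.rankdata(m[i][ok]), stats.rankdata(v[ok]))[0, 1]
    elif method == "pearson":
        r, n = _rows_vs_vector(m, v)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    p = _t_pvalue(r, n)
    tested = pd.DataFrame(
        {"protein_id": matrix.index, "r": r, "p": p, "n_obs": n.astype(int)}
    )
    tested = tested[(tested["n_obs"] >= min_n) & tested["r"].notna()].reset_index(drop=True)
    sel = tested[(tested["r"].abs() >= r_cut) & (tested["p"] <= p_cut)].copy()
    sel["direction"] = np.where(sel["r"] > 0, "positive", "negative")
    sel = sel.sort_values("p", ignore_index=True)
    return ScreenResult(
        biomarker=name,
        selected=sel,
        n_positive=int((sel["direction"] == "positive").sum()),
        n_negative=int((sel["direction"] == "negative").sum()),
        all_tested=tested,
    )


def _rank_with_nan(v: np.ndarray) -> np.ndarray:
    out = np.full(v.shape, np.nan)
    ok = ~np.isnan(v)
    out[ok] = stats.rankdata(v[ok])
    return out


def sample_corr_summary(
    matrix: pd.DataFrame, metadata: pd.DataFrame, min_periods: int = DEFAULT_MIN_N
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Sample-sample Pearson matrix plus within/between averages.

    ``metadata`` is indexed by sample id with ``subject_id`` and ``group``
    columns.  Averages reported: within-subject, between-subject within
    group (per group), and between-group, each over the corresponding
    off-diagonal pairs.
    """
    corr = matrix.corr(method="pearson", min_periods=min_periods)
    meta = metadata.loc[corr.index]
    subj = meta["subject_id"].to_numpy()
    group = meta["group"].to_numpy()
    c = corr.to_numpy()
    iu, ju = np.triu_indices(len(corr), k=1)
    same_subj = subj[iu] == subj[ju]
    same_group = group[iu] == group[ju]
    vals = c[iu, ju]
    summaries: dict[str, float] = {
        "within_subject": float(np.nanmean(vals[same_subj])) if same_subj.any() else np.nan,
        "between_group": float(np.nanmean(vals[~same_group])) if (~same_group).any() else np.nan,
    }
    for g in sorted(set(group)):
        sel = same_group & ~same_subj & (group[iu] == g)
        n_samples = int((group == g).sum())
        if n_samples < 2:
            import warnings

            warnings.warn(f"group {g!r} has < 2 samples; skipped")
            continue
        summaries[f"between_subject_within_{g}"] = (
            float(np.nanmean(vals[sel])) if sel.any() else np.nan
        )
    return corr, summaries


def cluster_order(corr: pd.DataFrame, n_clusters: int = 2) -> ClusterResult:
    """Average-linkage agglomeration on distance 1 - r.

    Requires a square symmetric correlation matrix with unit diagonal.
    """
    c = corr.to_numpy(dtype=float)
    if c.shape[0] != c.shape[1] or not np.allclose(c, c.T, atol=1e-10):
        raise ValueError("correlation matrix must be square and symmetric")
    if not np.allclose(np.diag(c), 1.0, atol=1e-8):
        raise ValueError("correlation matrix must have unit diagonal")
    d = 1.0 - c
    np.fill_diagonal(d, 0.0)
    d = np.maximum(d, 0.0)
    z = hierarchy.linkage(squareform(d, checks=False), method="average")
    leaves = [corr.index[i] for i in hierarchy.leaves_list(z)]
    labels = hierarchy.fcluster(z, t=n_clusters, criterion="maxclust")
    return ClusterResult(
        linkage=z,
        leaf_order=leaves,
        labels=pd.Series(labels, index=corr.index, name="cluster"),
    )


def venn_partition(
    set_a: set, set_b: set, set_c: set, names: tuple[str, str, str] = ("A", "B", "C")
) -> dict[str, set]:
    """Exact 7-region partition of three protein-id sets."""
    a, b, c = set(set_a), set(set_b), set(set_c)
    na, nb, nc = names
    return {
        f"{na}_only": a - b - c,
        f"{nb}_only": b - a - c,
        f"{nc}_only": c - a - b,
        f"{na}_{nb}": (a & b) - c,
        f"{na}_{nc}": (a & c) - b,
        f"{nb}_{nc}": (b & c) - a,
        f"{na}_{nb}_{nc}": a & b & c,
    }


def protein_fold_change(
    matrix: pd.DataFrame, group_a: list, group_b: list
) -> pd.DataFrame:
    """Per-protein log2 fold change: mean(group_a) - mean(group_b).

    Linear fold change is 2**|log2 FC| with the sign reported separately;
    proteins unobserved in either group get NaN and are flagged.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    ma = matrix[list(group_a)].mean(axis=1)
    mb = matrix[list(group_b)].mean(axis=1)
    log2fc = ma - mb
    return pd.DataFrame(
        {
            "log2_fc": log2fc,
            "linear_fc": 2.0 ** log2fc.abs(),
            "direction": np.where(log2fc >= 0, "up", "down"),
            "defined": log2fc.notna(),
        },
        index=matrix.index,
    )


def anova_protein(matrix: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """One-way fixed-effects ANOVA per protein over available values.

    ``groups`` maps sample id -> label; groups need >= 2 observed values per
    protein, proteins failing that are flagged (NaN F/p, ok=False).
    """
    common = [c for c in matrix.columns if c in groups.index]
    g = groups.loc[common]
    labels = sorted(set(g))
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    cols = {lab: [c for c in common if g[c] == lab] for lab in labels}
    sub = matrix[common]
    if not sub.isna().any().any():
        arrays = [sub[cols[lab]].to_numpy() for lab in labels]
        f, p = stats.f_oneway(*arrays, axis=1)
        ok = np.array([min(a.shape[1] for a in arrays) >= 2] * len(sub), dtype=bool)
        return pd.DataFrame({"F": f, "p": p, "ok": ok}, index=sub.index)
    rows = []
    for pid, row in sub.iterrows():
        samples = [row[cols[lab]].dropna().to_numpy() for lab in labels]
        samples = [s for s in samples if s.size > 0]
        if len(samples) < 2 or any(s.size < 2 for s in samples):
            rows.append({"F": np.nan, "p": np.nan, "ok": False})
            continue
        f, p = stats.f_oneway(*samples)
        rows.append({"F": float(f), "p": float(p), "ok": True})
    return pd.DataFrame(rows, index=sub.index)


def adjusted_rand_index(labels_true, labels_pred) -> float:
    """Adjusted Rand index between two flat labelings (pair-counting form)."""
    a = pd.Series(labels_true).astype("category").cat.codes.to_numpy()
    b = pd.Series(labels_pred).astype("category").cat.codes.to_numpy()
    if a.size != b.size:
        raise ValueError("labelings must have equal length")
    cont = pd.crosstab(a, b).to_numpy()

    def comb2(x):
        x = np.asarray(x, dtype=float)
        return x * (x - 1) / 2.0

    sum_ij = comb2(cont).sum()
    sum_a = comb2(cont.sum(axis=1)).sum()
    sum_b = comb2(cont.sum(axis=0)).sum()
    total = comb2(a.size)
    expected = sum_a * sum_b / total if total else 0.0
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (optional; screens are raw-p by default)."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p)
    adj = np.empty(n)
    prev = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = n - rank_from_end
        prev = min(prev, p[idx] * n / rank)
        adj[idx] = prev
    return adj
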