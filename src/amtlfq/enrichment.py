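"""Right-tailed Fisher's exact enrichment against user-supplied gene sets.

For a cluster of n proteins drawn from a universe of N, with K universe
members in a functional set and k of them in the cluster, the enrichment
p-value is the right tail P(X >= k) of Hypergeometric(N, K, n).  The
universe defaults to the quantified proteins, not the genome, so enrichment
is relative to what the experiment could detect.  Raw p-values are reported
(BH adjustment available but off by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .screening import benjamini_hochberg


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    name: str
    members: frozenset

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.set_id} is empty")


def fisher_right(k: int, K: int, n: int, N: int) -> float:
    """Right-tail hypergeometric probability P(X >= k), exact.

    k = overlap, K = set size in universe, n = cluster size, N = universe.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError(f"inconsistent counts k={k} K={K} n={n} N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def read_gmt(path) -> list[GeneSet]:
    """Parse GMT: one set per line, tab-separated (id, description, members...)."""
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets.append(GeneSet(parts[0], parts[1], frozenset(p for p in parts[2:] if p)))
    return sets


def enrich(
    groups: pd.Series | dict,
    gene_sets: list[GeneSet],
    universe: set,
    adjust: bool = False,
) -> pd.DataFrame:
    """One right-tailed Fisher test per (cluster, gene set).

    ``groups`` maps protein id -> cluster label; every member must be in the
    universe.  Sets with no universe overlap are skipped with a warning.
    Returns a table sortable by p (columns cluster, set_id, k, K, n, N, p).
    """
    groups = pd.Series(groups)
    missing = set(groups.index) - set(universe)
    if missing:
        raise ValueError(f"cluster members outside universe: {sorted(missing)[:5]}")
    N = len(universe)
    rows = []
    for label in sorted(groups.unique()):
        cluster = set(groups.index[groups == label])
        if not cluster:
            warnings.warn(f"cluster {label!r} is empty; skipped")
            continue
        for gs in gene_sets:
            in_universe = gs.members & set(universe)
            if not in_universe:
                warnings.warn(f"gene set {gs.set_id} has no universe overlap; skipped")
                continue
            k = len(cluster & in_universe)
            rows.append(
                {
                    "cluster": label,
                    "set_id": gs.set_id,
                    "set_name": gs.name,
                    "k": k,
                    "K": len(in_universe),
                    "n": len(cluster),
                    "N": N,
                    "p": fisher_right(k, len(in_universe), len(cluster), N),
                }
            )
    out = pd.DataFrame(rows)
    if adjust and len(out):
        out["p_adj"] = benjamini_hochberg(out["p"].to_numpy())
    return out.sort_values(["cluster", "p", "set_id"], ignore_index=True) if len(out) else out
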