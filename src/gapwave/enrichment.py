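"""Hypergeometric over-representation analysis of transcript clusters.

Each cluster's gene list is tested against every set of a GMT collection:
with a universe of N genes of which K belong to the set, and a cluster list
of n genes of which k fall in the set, the p-value is the upper
hypergeometric tail P(X >= k).  Reported alongside: percent = 100*k/n, fold
enrichment = (k/n)/(K/N), and the Bonferroni-corrected p-value (multiplied
by the number of sets tested for that list).  The EASE-score variant
(replace k by k-1 in the tail, a conservative dialect popularised by the
DAVID service) is available behind a flag.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import pandas as pd
from scipy import stats

_log = logging.getLogger(__name__)


def _norm(symbol: str) -> str:
    return str(symbol).strip().lower()


@dataclasses.dataclass
class GeneSetCollection:
    """Named gene sets plus the background universe.

    Genes outside the universe are dropped from the sets (logged); sets that
    become empty are removed.
    """

    sets: dict
    universe: frozenset

    def __post_init__(self):
        self.universe = frozenset(_norm(g) for g in self.universe)
        cleaned, n_dropped = {}, 0
        for name, genes in self.sets.items():
            g = frozenset(_norm(x) for x in genes)
            inside = g & self.universe
            n_dropped += len(g) - len(inside)
            if inside:
                cleaned[name] = inside
            else:
                _log.warning("gene set %r has no genes in the universe; dropped", name)
        if n_dropped:
            _log.info("dropped %d set genes outside the universe", n_dropped)
        self.sets = cleaned

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path, universe=None) -> GeneSetCollection:
    """Read a GMT file (set name, description, symbols per tab-separated line).

    If ``universe`` is None, the union of all set genes is used as background.
    """
    sets = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        name, _desc, *genes = parts
        genes = [g for g in genes if g.strip()]
        if not genes:
            raise ValueError(f"empty gene set {name!r}")
        sets[name] = genes
    if universe is None:
        universe = set().union(*[set(map(_norm, g)) for g in sets.values()])
    return GeneSetCollection(sets, frozenset(universe))


def hypergeom_ora(cluster_genes, collection: GeneSetCollection,
                  alpha: float = 0.01, ease: bool = False) -> pd.DataFrame:
    """Over-representation of ``cluster_genes`` in each set of the collection.

    Returns one row per set, sorted by p-value, with columns: set, count (k),
    list_size (n), set_size (K), universe (N), percent, fold_enrichment,
    p_value, bonferroni_p, significant (bonferroni_p <= alpha).
    """
    genes = {_norm(g) for g in cluster_genes}
    outside = genes - collection.universe
    if outside:
        _log.warning("dropping %d cluster genes outside the universe", len(outside))
    genes &= collection.universe
    if not genes:
        _log.warning("empty cluster list after intersecting the universe")
        return pd.DataFrame(
            columns=["set", "count", "list_size", "set_size", "universe",
                     "percent", "fold_enrichment", "p_value", "bonferroni_p",
                     "significant"]
        )

    N = len(collection.universe)
    n = len(genes)
    n_tests = len(collection.sets)
    rows = []
    for name, members in sorted(collection.sets.items()):
        K = len(members)
        k = len(genes & members)
        shift = 2 if ease else 1
        p = 1.0 if (ease and k == 0) else float(stats.hypergeom.sf(k - shift, N, K, n))
        p = min(p, 1.0)
        rows.append(
            {
                "set": name,
                "count": k,
                "list_size": n,
                "set_size": K,
                "universe": N,
                "percent": 100.0 * k / n,
                "fold_enrichment": (k / n) / (K / N),
                "p_value": p,
                "bonferroni_p": min(1.0, p * n_tests),
            }
        )
    df = pd.DataFrame(rows).sort_values(["p_value", "set"], kind="stable")
    df["significant"] = df["bonferroni_p"] <= alpha
    return df.reset_index(drop=True)


def cluster_ora(cluster_members: dict, collection: GeneSetCollection,
                alpha: float = 0.01, ease: bool = False) -> pd.DataFrame:
    """Run the ORA for every cluster; returns the concatenated long table."""
    frames = []
    for cl, genes in sorted(cluster_members.items()):
        df = hypergeom_ora(genes, collection, alpha=alpha, ease=ease)
        df.insert(0, "cluster", cl)
        frames.append(df)
    if not frames:
        raise ValueError("no clusters supplied")
    return pd.concat(frames, ignore_index=True)
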