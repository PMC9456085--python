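"""Target-layer analysis: top-CPM EV-enriched miRNAs, miRNA->target
multiplicity, and hypergeometric pathway over-representation.

miRNA->target maps and pathway gene sets are consumed as GMT files
(set name, description, member genes per line).  Over-representation uses
the hypergeometric upper tail P(X >= k) with Benjamini-Hochberg adjustment
across the tested pathways; the gene universe defaults to the union of all
pathway genes, optionally restricted to an explicit set.  Pathway
name-prefix exclusion (e.g. disease categories) is supported but nothing is
hard-coded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .cargo_dynamics import CompartmentCalls
from .diff_enrichment import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    sets: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        names = list(self.sets)
        if len(set(names)) != len(names):
            raise ValueError("gene-set names must be unique")
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    @classmethod
    def from_sets(cls, sets: dict[str, set[str]]) -> "GeneSetCollection":
        universe = set().union(*sets.values()) if sets else set()
        return cls(sets=dict(sets), universe=universe)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(
                f"{path}:{lineno}: GMT line needs name, description and >=1 gene"
            )
        name = parts[0]
        if name in sets:
            raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
        genes = {g for g in parts[2:] if g}
        if not genes:
            raise ValueError(f"{path}:{lineno}: set {name!r} has no genes")
        sets[name] = genes
    return GeneSetCollection.from_sets(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path,
              description: str = "na") -> None:
    lines = [
        "\t".join([name, description, *sorted(genes)])
        for name, genes in collection.sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def top_enriched_by_cpm(comp: CompartmentCalls, cpm_df: pd.DataFrame,
                        ev_sample_ids: list[str], condition: str,
                        k: int) -> list[str]:
    """Top-k EV-enriched miRNAs of ``condition`` by mean CPM over that
    condition's EV samples (descending; ties broken lexicographically).

    Returns all enriched miRNAs (with a logged notice) when fewer than k
    exist.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    enriched = comp.enriched_set(condition)
    means = cpm_df.loc[sorted(enriched), ev_sample_ids].mean(axis=1)
    ranked = sorted(means.items(), key=lambda kv: (-kv[1], kv[0]))
    names = [name for name, _ in ranked]
    if len(names) < k:
        logger.info(
            "only %d enriched miRNAs in %s (k=%d requested); returning all",
            len(names), condition, k,
        )
        return names
    return names[:k]


def target_multiplicity(mirnas: list[str],
                        targets: GeneSetCollection) -> dict[str, int]:
    """For each gene, the number of query miRNAs that target it.

    ``targets`` is keyed by miRNA (GMT set name = miRNA).  Query miRNAs
    missing from the map are skipped with a warning.
    """
    counts: dict[str, int] = {}
    for mirna in mirnas:
        genes = targets.sets.get(mirna)
        if genes is None:
            logger.warning("miRNA %s has no entry in the target map", mirna)
            continue
        for g in genes:
            counts[g] = counts.get(g, 0) + 1
    return counts


def shared_targets(multiplicity: dict[str, int], min_mirnas: int) -> set[str]:
    """Genes targeted by at least ``min_mirnas`` of the query miRNAs."""
    return {g for g, c in multiplicity.items() if c >= min_mirnas}


def hypergeom_ora(query_genes: set[str], pathways: GeneSetCollection,
                  universe: set[str] | None = None,
                  exclude_prefixes: tuple[str, ...] = ()) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query_genes`` in each pathway.

    Universe defaults to the union of pathway genes; the query is restricted
    to the universe before testing.  For each pathway of size K in a
    universe of size N, with query size n and overlap k, p = P(X >= k) under
    the hypergeometric null; q is BH across tested pathways.  Pathways
    empty after restriction, or matching an excluded name prefix, are
    skipped.
    """
    universe = set(universe) if universe is not None else set(pathways.universe)
    if not universe:
        raise ValueError("empty gene universe")
    query = set(query_genes) & universe
    if not query:
        raise ValueError("query is empty after restriction to the universe")

    rows = []
    n = len(query)
    N = len(universe)
    for name, genes in pathways.sets.items():
        if any(name.startswith(p) for p in exclude_prefixes):
            continue
        in_univ = genes & universe
        K = len(in_univ)
        if K == 0:
            continue
        k = len(in_univ & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"pathway": name, "N": N, "K": K, "n": n, "k": k,
                     "p_value": min(p, 1.0)})
    out = pd.DataFrame(rows,
                       columns=["pathway", "N", "K", "n", "k", "p_value"])
    if len(out):
        out["q_value"] = bh_adjust(out["p_value"].to_numpy())
        out = out.sort_values(["p_value", "pathway"]).reset_index(drop=True)
    else:
        out["q_value"] = pd.Series(dtype=float)
    return out
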