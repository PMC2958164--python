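"""Pathway-level over-representation analysis with BH FDR.

Individual-gene selection in a cross-species experiment is deliberately
liberal and unadjusted; inference happens at the pathway level, where the
collective behaviour of functionally linked genes compensates for noisy or
missing probes. For each pathway the question is whether the differential
list contains more of its genes than a random draw from the detected
transcriptome would — a one-tailed hypergeometric (Fisher-type) test:

    p = P(X >= r),  X ~ Hypergeometric(N, n, R)

with N the universe size, n the pathway's genes in the universe, R the
differential genes, and r the overlap. P-values are BH-adjusted per contrast
across all tested pathways.

The universe is the *detected* transcriptome — genes present on all chips —
not the whole database: cross-species hybridization silences a large part of
the chip, and counting never-measurable genes in the background would be
anti-conservative. Pathway size n is likewise restricted to universe genes.
A ``universe="full"`` mode using every annotated probe on the chip is
available for comparison.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateInputError, FormatError, ParameterError
from .io import ProbeGeneMap

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "collapse_probes_to_genes",
    "hypergeometric_overrep",
    "bh_adjust",
    "enrich",
    "compare_enrichment_across_contrasts",
]


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets: pathway name -> (description, member gene symbols)."""

    sets: dict[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for name, (_, genes) in self.sets.items():
            if not genes:
                raise FormatError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def genes(self, name: str) -> frozenset[str]:
        return self.sets[name][1]


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file (name TAB description TAB gene TAB gene ...).

    Genes are de-duplicated within a set; duplicate pathway names are an
    error. Blank lines are ignored.
    """
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"line {lineno}: expected >= 3 tab-separated fields")
            name, description, *genes = fields
            if name in sets:
                raise FormatError(f"line {lineno}: duplicate pathway name {name!r}")
            members = frozenset(g for g in genes if g)
            if not members:
                raise FormatError(f"line {lineno}: gene set {name!r} has no genes")
            sets[name] = (description, members)
    return GeneSetCollection(sets=sets)


def collapse_probes_to_genes(probes, pmap: ProbeGeneMap) -> set[str]:
    """Collapse probe ids to gene symbols by the any-probe rule.

    A gene is in the output iff at least one of its probes is in the input;
    unmapped probes are dropped (count goes to the log).
    """
    genes: set[str] = set()
    dropped = 0
    for p in probes:
        gene = pmap.entries.get(p)
        if gene is None:
            dropped += 1
        else:
            genes.add(gene)
    if dropped:
        logger.info("collapse: dropped %d unmapped probes", dropped)
    return genes


def _check_margins(r: int, n: int, R: int, N: int) -> None:
    for name, val in (("r", r), ("n", n), ("R", R), ("N", N)):
        if int(val) != val or val < 0:
            raise ParameterError(f"{name} must be a nonnegative integer, got {val}")
    if n > N or R > N:
        raise ParameterError(f"margins exceed universe: n={n}, R={R}, N={N}")
    if r > min(n, R):
        raise ParameterError(f"overlap r={r} exceeds margins n={n}, R={R}")


def hypergeometric_overrep(r: int, n: int, R: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= r).

    Drawing R genes from a universe of N that contains n pathway genes, this
    is the chance of hitting at least the observed overlap r. ``r == 0``
    returns exactly 1.
    """
    _check_margins(r, n, R, N)
    if r == 0:
        return 1.0
    p = float(hypergeom.sf(r - 1, N, n, R))
    return min(max(p, 0.0), 1.0)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order.

    q_(i) = min_{j>=i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ParameterError("p-values must be a 1-D vector")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ParameterError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    de_probes,
    universe_probes,
    pmap: ProbeGeneMap,
    gsc: GeneSetCollection,
    q_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Over-representation table for one differential probe list.

    Probes are collapsed to genes (any-probe rule), margins are computed
    against the universe, and each pathway with at least one universe gene
    gets a row. Columns: pathway, r, n, R, N, p, q, significant; rows sorted
    by p ascending (ties by name).
    """
    de_probes = set(de_probes)
    universe_probes = set(universe_probes)
    if not de_probes <= universe_probes:
        raise ParameterError("differential probes must be a subset of the universe")
    universe_genes = collapse_probes_to_genes(universe_probes, pmap)
    if not universe_genes:
        raise DegenerateInputError("universe collapses to zero genes")
    de_genes = collapse_probes_to_genes(de_probes, pmap)
    N, R = len(universe_genes), len(de_genes)
    rows = []
    for name in gsc.names:
        pathway_in_universe = gsc.genes(name) & universe_genes
        n = len(pathway_in_universe)
        if n == 0:
            continue
        r = len(pathway_in_universe & de_genes)
        rows.append((name, r, n, R, N, hypergeometric_overrep(r, n, R, N)))
    table = pd.DataFrame(rows, columns=["pathway", "r", "n", "R", "N", "p"])
    if len(table):
        table["q"] = bh_adjust(table["p"].to_numpy())
    else:
        table["q"] = pd.Series(dtype=float)
    table["significant"] = table["q"] <= q_cutoff
    table = table.sort_values(["p", "pathway"], kind="stable", ignore_index=True)
    return table


def compare_enrichment_across_contrasts(
    tables: dict[str, pd.DataFrame], top_k: int = 10
) -> pd.DataFrame:
    """Pathway x contrast matrix of -log10 p for the union of top pathways.

    Takes each contrast's ``top_k`` most significant pathways; a pathway
    missing from some contrast's table contributes -log10(1) = 0 there. On
    the assumption that noise has the same technical nature across contrasts,
    the -log10 p profile indicates the relative activity of a pathway across
    the comparisons.
    """
    if len(tables) < 2:
        raise ParameterError("need at least 2 contrasts to compare")
    chosen: dict[str, None] = {}
    for table in tables.values():
        for name in table.nsmallest(top_k, "p", keep="first")["pathway"]:
            chosen.setdefault(name, None)
    pathways = list(chosen)
    data = {}
    for contrast, table in tables.items():
        pmap_ = dict(zip(table["pathway"], table["p"]))
        data[contrast] = [
            -math.log10(max(pmap_.get(name, 1.0), 1e-300)) for name in pathways
        ]
    out = pd.DataFrame(data, index=pd.Index(pathways, name="pathway"))
    # most prominent pathways first
    order = out.max(axis=1).sort_values(ascending=False, kind="stable").index
    return out.loc[order]
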