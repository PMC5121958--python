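"""Flux-covariation clustering and gene-set export.

Reactions that adjust their flux in a coordinated way across nutrient
transitions often belong to the same pathway or share regulation.  From a
reaction x phase flux matrix:

1. reactions with a constant |flux| trend across all phases are removed;
2. each remaining reaction j gets a *flux-difference vector*
   ``d_z = |f_{j,z+1}| - |f_{j,z}|`` over the transitions (nine values for a
   ten-phase window);
3. Pearson correlation is computed for every reaction pair (zero-variance
   vectors are excluded — their correlation is undefined);
4. clusters are the connected components of the graph whose edges join pairs
   with ``r > threshold`` (default 0.7, strictly greater; both the threshold
   and the comparison are configurable), singletons dropped;
5. each cluster maps to the union of genes in its reactions' GPR rules,
   exported as per-cluster gene lists plus a combined GMT file for external
   annotation tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from cobra import Model

from .fba import FluxMatrix
from .model import genes_for_reactions

__all__ = [
    "CovariationResult",
    "flux_diff_vectors",
    "correlate_and_cluster",
    "clusters_to_genes",
    "export_gene_lists",
    "run_covariation",
]

CONSTANT_TOL = 1e-9


def flux_diff_vectors(
    fluxes: FluxMatrix | pd.DataFrame, tol: float = CONSTANT_TOL
) -> tuple[pd.DataFrame, set[str]]:
    """Per-reaction transition difference vectors of absolute fluxes.

    Returns ``(diffs, excluded_constant)``: reactions whose |flux| is the
    same (within ``tol``) in every phase — including the all-zero ones — are
    excluded; the rest get one column per transition.
    """
    mat = fluxes.fluxes if isinstance(fluxes, FluxMatrix) else fluxes
    if mat.shape[1] < 3:
        raise ValueError("need at least three phases to correlate differences")
    absmat = mat.abs()
    spread = absmat.max(axis=1) - absmat.min(axis=1)
    constant = set(absmat.index[spread <= tol])
    kept = absmat.drop(index=constant)
    diffs = kept.diff(axis=1).iloc[:, 1:]
    diffs.columns = [
        f"{a}->{b}" for a, b in zip(mat.columns[:-1], mat.columns[1:])
    ]
    return diffs, constant


def correlate_and_cluster(
    diffs: pd.DataFrame,
    threshold: float = 0.7,
    strict: bool = True,
) -> tuple[pd.DataFrame, list[set[str]], set[str]]:
    """Pearson-correlation graph clustering of difference vectors.

    Edges join reaction pairs with ``r > threshold`` (``>=`` if not strict);
    clusters are connected components with at least two members, ordered by
    decreasing size then lexicographically.  Returns
    ``(correlation matrix, clusters, excluded_zero_variance)``.
    """
    var = diffs.var(axis=1, ddof=0)
    degenerate = set(diffs.index[~(var > 0)])
    kept = diffs.drop(index=degenerate)
    if len(kept) < 2:
        return pd.DataFrame(), [], degenerate
    corr = pd.DataFrame(
        np.corrcoef(kept.to_numpy()), index=kept.index, columns=kept.index
    )
    g = nx.Graph()
    g.add_nodes_from(kept.index)
    r = corr.to_numpy()
    ids = list(kept.index)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if (r[i, j] > threshold) if strict else (r[i, j] >= threshold):
                g.add_edge(ids[i], ids[j])
    comps = [set(c) for c in nx.connected_components(g) if len(c) >= 2]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return corr, comps, degenerate


def clusters_to_genes(
    clusters: list[set[str]], model: Model
) -> tuple[list[set[str]], list[set[str]]]:
    """Per-cluster GPR gene unions; also reports reactions with empty GPRs."""
    gene_sets, no_gpr = [], []
    for cluster in clusters:
        gene_sets.append(genes_for_reactions(model, cluster))
        no_gpr.append(
            {rid for rid in cluster
             if not model.reactions.get_by_id(rid).gene_reaction_rule.strip()}
        )
    return gene_sets, no_gpr


def export_gene_lists(
    gene_sets: list[set[str]], out_dir: str | Path, prefix: str = "cluster"
) -> list[Path]:
    """One plain-text gene list per cluster plus a combined GMT file."""
    if not gene_sets:
        raise ValueError("no gene sets to export")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    gmt_lines = []
    for k, genes in enumerate(gene_sets, start=1):
        name = f"{prefix}_{k}"
        p = out_dir / f"{name}.txt"
        p.write_text("\n".join(sorted(genes)) + "\n")
        written.append(p)
        gmt_lines.append("\t".join([name, "flux-covariation cluster", *sorted(genes)]))
    gmt = out_dir / f"{prefix}s.gmt"
    gmt.write_text("\n".join(gmt_lines) + "\n")
    written.append(gmt)
    return written


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    out = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        name, _desc, *genes = line.split("\t")
        out[name] = set(genes)
    return out


@dataclass
class CovariationResult:
    diffs: pd.DataFrame
    correlation: pd.DataFrame
    clusters: list[set[str]]
    gene_sets: list[set[str]]
    excluded_constant: set[str]
    excluded_zero_variance: set[str]
    reactions_without_gpr: list[set[str]] = field(default_factory=list)

    @property
    def n_clustered_reactions(self) -> int:
        return sum(len(c) for c in self.clusters)

    @property
    def all_genes(self) -> set[str]:
        return set().union(*self.gene_sets) if self.gene_sets else set()


def run_covariation(
    fluxes: FluxMatrix,
    model: Model,
    threshold: float = 0.7,
    strict: bool = True,
) -> CovariationResult:
    """Full covariation pipeline on a flux matrix."""
    diffs, constant = flux_diff_vectors(fluxes)
    corr, clusters, degenerate = correlate_and_cluster(
        diffs, threshold=threshold, strict=strict
    )
    gene_sets, no_gpr = clusters_to_genes(clusters, model)
    return CovariationResult(
        diffs=diffs,
        correlation=corr,
        clusters=clusters,
        gene_sets=gene_sets,
        excluded_constant=constant,
        excluded_zero_variance=degenerate,
        reactions_without_gpr=no_gpr,
    )
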