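"""Perturbation-profile comparison and exon-vs-knockout divergence.

Builds the shared-DEG log2FC matrix across perturbations, clusters
perturbations by Pearson correlation, classifies each exon deletion as
concordant or divergent with its gene's knockout (Pearson r over the union
of their DEGs, concordant iff r > 0.4, strict inequality), and supports
re-running pseudobulk DE restricted to cells of one cell-cycle phase to
separate phase-composition effects from direct transcriptional ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .assignment import CellAssignment
from .library import GuideLibrary
from .pseudobulk import DEResult, aggregate, de_test

CONCORDANCE_R = 0.4


@dataclass
class DivergenceResult:
    r_exon_vs_ko: float
    n_union_degs: int
    n_degs_exon_vs_ko: int
    concordant: bool
    divergent_genes: pd.Index


def shared_deg_matrix(de_results: dict[str, DEResult],
                      min_perturbations: int = 30) -> pd.DataFrame:
    """genes x perturbations log2FC matrix over genes that are DEGs in at
    least ``min_perturbations`` perturbations (non-significant log2FCs for
    those genes are kept)."""
    if not de_results:
        raise ValueError("no DE results supplied")
    deg_counts: pd.Series | None = None
    for res in de_results.values():
        flags = res.table["is_deg"].astype(int)
        deg_counts = flags if deg_counts is None else deg_counts.add(flags,
                                                                     fill_value=0)
    genes = deg_counts.index[deg_counts >= min_perturbations]
    if len(genes) == 0:
        warnings.warn(f"no gene is a DEG in >= {min_perturbations} "
                      "perturbations; empty matrix")
    mat = pd.DataFrame({name: res.table["log2fc"].reindex(genes)
                        for name, res in de_results.items()})
    mat.index.name = "gene"
    return mat


def correlate_perturbations(matrix: pd.DataFrame, linkage: str = "average"
                            ) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise Pearson correlation of perturbation log2FC profiles and a
    hierarchical-clustering leaf order on distance 1 - r.

    Zero-variance profiles yield NaN correlations and are reported but
    placed last in the leaf order.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 perturbations to correlate")
    corr = matrix.corr(method="pearson")  # pairwise-complete, NaN if degenerate
    ok = matrix.std(ddof=0) > 0
    usable = corr.loc[ok, ok]
    if len(usable) >= 2:
        dist = 1.0 - usable.to_numpy()
        np.fill_diagonal(dist, 0.0)
        dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
        Z = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
        order = [usable.columns[i] for i in hierarchy.leaves_list(Z)]
    else:
        order = list(usable.columns)
    order += [c for c in corr.columns if c not in order]
    return corr, order


def exon_vs_ko(exon_de: DEResult, ko_de: DEResult,
               exon_vs_ko_de: DEResult | None = None,
               threshold: float = CONCORDANCE_R) -> DivergenceResult:
    """Concordance of an exon deletion with its gene's knockout.

    r = Pearson correlation of the two log2FC vectors over the union of
    their DEG sets; concordant iff r > ``threshold`` (strict: r equal to
    the threshold is not concordant). The divergent-gene set is the DEGs of
    the direct exon-vs-knockout comparison when supplied.
    """
    union = exon_de.degs.union(ko_de.degs)
    direct_degs = (exon_vs_ko_de.degs if exon_vs_ko_de is not None
                   else pd.Index([]))
    if len(union) < 3:
        return DivergenceResult(float("nan"), len(union), len(direct_degs),
                                False, direct_degs)
    a = exon_de.table["log2fc"].reindex(union)
    b = ko_de.table["log2fc"].reindex(union)
    ok = a.notna() & b.notna()
    if ok.sum() < 3 or a[ok].std() == 0 or b[ok].std() == 0:
        return DivergenceResult(float("nan"), len(union), len(direct_degs),
                                False, direct_degs)
    r = float(stats.pearsonr(a[ok], b[ok])[0])
    return DivergenceResult(r, int(len(union)), int(len(direct_degs)),
                            bool(r > threshold), direct_degs)


def phase_conditioned_de(expr: ad.AnnData, assignment: CellAssignment,
                         library: GuideLibrary, phases: pd.Series,
                         phase: str, target_groups: list[str],
                         control_groups: list[str], level: str = "guide",
                         min_cells: int = 10,
                         perturbed: pd.Series | None = None,
                         **de_kw) -> DEResult:
    """Pseudobulk DE recomputed using only cells of one cell-cycle phase.

    Groups that lose all cells in that phase are dropped (reported via the
    aggregation warning); an error is raised if no target or no control
    group survives.
    """
    if phase not in set(phases.unique()) | {"G1", "S", "G2M"}:
        raise ValueError(f"unknown phase {phase!r}")
    mask = phases == phase
    if mask.sum() == 0:
        raise ValueError(f"no cells in phase {phase}")
    pb = aggregate(expr, assignment, library, level=level, min_cells=min_cells,
                   perturbed=perturbed, cell_mask=mask)
    tg = [g for g in target_groups if g in pb.counts.index]
    cg = [g for g in control_groups if g in pb.counts.index]
    if not tg:
        raise ValueError(f"no target group has >= {min_cells} {phase} cells")
    return de_test(pb, tg, cg, **de_kw)
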