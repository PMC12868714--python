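"""Cell-cycle phase scoring, assignment and per-target enrichment testing.

Each cell gets S and G2/M program scores (mean marker expression minus the
mean of an expression-matched control gene set); a cell with both scores
non-positive is G1, otherwise the larger score wins. Per-target phase
redistribution relative to intergenic controls is tested with a dual gate
for exon targets — a one-sided Fisher's exact test on pooled cell counts
(BH-adjusted p < 0.01) AND a one-sided Mann-Whitney test on per-guide vs
per-control-group phase fractions (normal approximation, tie-corrected, no
continuity correction; BH-adjusted p < 0.05) — and a Fisher-only gate for
gene knockouts. When two phases pass, the one with the lowest adjusted p is
called.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats
from statsmodels.stats.multitest import multipletests

from .assignment import CellAssignment
from .library import GuideLibrary
from .simulate import PHASES

FISHER_ALPHA = 0.01
MW_ALPHA = 0.05


def load_default_markers() -> tuple[list[str], list[str]]:
    """Canonical S and G2/M marker gene symbols (regev lab list) shipped
    with the package, for use on real human data."""
    def _read(name: str) -> list[str]:
        text = resources.files("hgscreen.data").joinpath(name).read_text()
        return [line.strip() for line in text.splitlines()
                if line.strip() and not line.startswith("#")]
    return _read("s_genes.txt"), _read("g2m_genes.txt")


def score_gene_set(adata: ad.AnnData, gene_set: list[str], n_bins: int = 25,
                   ctrl_size: int = 50, seed: int = 0,
                   layer: str = "normalized") -> pd.Series:
    """Program score per cell: mean expression of ``gene_set`` minus the mean
    of a matched control set.

    All genes are cut into ``n_bins`` equal-frequency bins by average
    expression; for each bin containing a marker gene, up to ``ctrl_size``
    non-marker genes are sampled from it without replacement (seeded). The
    score is the marker mean minus the control mean, per cell.
    """
    genes = pd.Index(gene_set)
    present = genes.intersection(adata.var_names)
    missing = genes.difference(adata.var_names)
    if len(present) == 0:
        raise ValueError(f"no gene_set genes in the matrix; missing: "
                         f"{sorted(missing)[:10]}")
    X = adata.layers[layer] if layer in adata.layers else adata.X
    X = X.toarray() if sparse.issparse(X) else np.asarray(X)
    df = pd.DataFrame(X, index=adata.obs_names, columns=adata.var_names)

    avg = df.mean(axis=0)
    bins = pd.qcut(avg.rank(method="first"), min(n_bins, len(avg)), labels=False)
    rng = np.random.default_rng(seed)
    marker_bins = sorted(bins[present].unique())
    ctrl_genes: list[str] = []
    for b in marker_bins:
        pool = bins.index[(bins == b) & ~bins.index.isin(present)]
        k = min(ctrl_size, len(pool))
        if k:
            ctrl_genes.extend(rng.choice(pool.to_numpy(), size=k, replace=False))
    if not ctrl_genes:
        # control pool empty (e.g. gene_set == universe): score vs marker mean
        ctrl_mean = df[present].mean(axis=1)
    else:
        ctrl_mean = df[sorted(set(ctrl_genes))].mean(axis=1)
    return df[present].mean(axis=1) - ctrl_mean


def assign_phase(s_score: pd.Series, g2m_score: pd.Series) -> pd.Series:
    """G1 iff both scores <= 0; otherwise the phase of the larger score
    (ties at equal positive scores go to S by argmax order)."""
    s = s_score.to_numpy(dtype=float)
    g = g2m_score.reindex(s_score.index).to_numpy(dtype=float)
    if not (np.isfinite(s).all() and np.isfinite(g).all()):
        raise ValueError("phase scores must be finite")
    phase = np.where((s <= 0) & (g <= 0), "G1", np.where(s >= g, "S", "G2M"))
    return pd.Series(phase, index=s_score.index, name="phase")


def score_phases(adata: ad.AnnData, s_genes: list[str], g2m_genes: list[str],
                 n_bins: int = 25, ctrl_size: int = 50, seed: int = 0,
                 layer: str = "normalized") -> pd.DataFrame:
    """Convenience: S and G2/M scores plus the phase call, per cell."""
    s = score_gene_set(adata, s_genes, n_bins, ctrl_size, seed, layer)
    g = score_gene_set(adata, g2m_genes, n_bins, ctrl_size, seed + 1, layer)
    return pd.DataFrame({"s_score": s, "g2m_score": g,
                         "phase": assign_phase(s, g)})


def phase_fractions(phases: pd.Series, assignment: CellAssignment,
                    library: GuideLibrary, level: str = "guide",
                    perturbed: pd.Series | None = None) -> pd.DataFrame:
    """Per-group counts and fractions of G1/S/G2M cells.

    ``perturbed`` restricts non-control groups to perturbed-flagged cells
    (control cells are kept unconditionally). Empty groups are dropped with
    a warning. Fractions sum to 1 per group.
    """
    from .library import CONTROL_CLASSES
    tab = assignment.table
    cells = phases.index.intersection(tab.index[tab["status"] == "assigned"])
    tab = tab.loc[cells]
    cls = {r.hgrna_id: r.target_class for r in library.records}
    if perturbed is not None:
        is_ctrl = tab["assigned_hgrna"].map(cls).isin(CONTROL_CLASSES)
        keep = is_ctrl | perturbed.reindex(cells).fillna(False)
        cells = cells[keep.to_numpy()]
        tab = tab.loc[cells]
    target_of = {r.hgrna_id: r.target_id for r in library.records}
    group = (tab["assigned_hgrna"] if level == "guide"
             else tab["assigned_hgrna"].map(target_of))
    ph = phases.loc[cells]
    counts = (pd.crosstab(group.to_numpy(), ph.to_numpy())
              .reindex(columns=list(PHASES), fill_value=0))
    empty = counts.sum(axis=1) == 0
    if empty.any():
        warnings.warn(f"dropping {int(empty.sum())} empty phase groups")
        counts = counts[~empty]
    frac = counts.div(counts.sum(axis=1), axis=0)
    out = counts.add_prefix("n_").join(frac.add_prefix("frac_"))
    out.index.name = "group"
    meta_cls = {g: (cls[g] if level == "guide" else library.class_of_target(g))
                for g in out.index}
    out["class"] = pd.Series(meta_cls)
    if level == "guide":
        out["target_id"] = [target_of[g] for g in out.index]
    else:
        out["target_id"] = out.index
    return out


def mannwhitney_p(x: np.ndarray, y: np.ndarray) -> float:
    """One-sided Mann-Whitney p (x stochastically greater), normal
    approximation with tie correction, no continuity correction."""
    res = stats.mannwhitneyu(x, y, alternative="greater", method="asymptotic",
                             use_continuity=False)
    return float(res.pvalue)


@dataclass
class PhaseEnrichmentResult:
    table: pd.DataFrame            # (target, phase) rows with tests + flags
    calls: pd.Series               # per target: called phase or NaN
    params: dict = field(default_factory=dict)


def _enrichment(guide_fracs: pd.DataFrame, control_class: str, mode: str,
                fisher_alpha: float, mw_alpha: float) -> PhaseEnrichmentResult:
    ctrl = guide_fracs[guide_fracs["class"] == control_class]
    if len(ctrl) == 0:
        raise ValueError(f"no {control_class} control groups")
    ctrl_counts = {p: int(ctrl[f"n_{p}"].sum()) for p in PHASES}
    ctrl_total = sum(ctrl_counts.values())

    rows = []
    targets = [t for t in guide_fracs["target_id"].unique()
               if guide_fracs.loc[guide_fracs["target_id"] == t, "class"].iloc[0]
               not in ("intergenic", "non_targeting")]
    for t in targets:
        sub = guide_fracs[guide_fracs["target_id"] == t]
        t_counts = {p: int(sub[f"n_{p}"].sum()) for p in PHASES}
        t_total = sum(t_counts.values())
        n_guides = len(sub)
        for p in PHASES:
            table = np.array([
                [t_counts[p], t_total - t_counts[p]],
                [ctrl_counts[p], ctrl_total - ctrl_counts[p]]])
            fisher_p = stats.fisher_exact(table, alternative="greater")[1]
            if mode == "exon":
                if n_guides >= 2:
                    mw = mannwhitney_p(sub[f"frac_{p}"].to_numpy(),
                                       ctrl[f"frac_{p}"].to_numpy())
                else:
                    mw = np.nan
            else:
                mw = np.nan
            rows.append((t, p, t_counts[p], t_total - t_counts[p],
                         ctrl_counts[p], ctrl_total - ctrl_counts[p],
                         n_guides, fisher_p, mw))
    tab = pd.DataFrame(rows, columns=[
        "target_id", "phase", "target_in", "target_out", "control_in",
        "control_out", "n_guides", "fisher_p", "mw_p"])
    tab["fisher_padj"] = multipletests(tab["fisher_p"], method="fdr_bh")[1]
    tab["mw_padj"] = np.nan
    mw_ok = tab["mw_p"].notna()
    if mw_ok.any():
        tab.loc[mw_ok, "mw_padj"] = multipletests(
            tab.loc[mw_ok, "mw_p"], method="fdr_bh")[1]
    if mode == "exon":
        tab["significant"] = ((tab["fisher_padj"] < fisher_alpha)
                              & (tab["mw_padj"] < mw_alpha))
        tab["assessable"] = mw_ok
    else:
        tab["significant"] = tab["fisher_padj"] < fisher_alpha
        tab["assessable"] = True

    calls = {}
    for t, sub in tab.groupby("target_id"):
        sig = sub[sub["significant"]]
        if len(sig):
            best = sig.sort_values(["fisher_padj", "mw_padj"],
                                   na_position="last").iloc[0]
            calls[t] = best["phase"]
        else:
            calls[t] = np.nan
    return PhaseEnrichmentResult(
        tab, pd.Series(calls, name="called_phase"),
        params={"mode": mode, "fisher_alpha": fisher_alpha,
                "mw_alpha": mw_alpha, "control_class": control_class,
                "n_control_groups": int(len(ctrl))})


def exon_phase_enrichment(guide_fracs: pd.DataFrame,
                          control_class: str = "intergenic",
                          fisher_alpha: float = FISHER_ALPHA,
                          mw_alpha: float = MW_ALPHA) -> PhaseEnrichmentResult:
    """Dual-gate enrichment for exon targets.

    Per target and phase: (i) one-sided Fisher's exact test on the 2x2
    in-phase/out-of-phase x target/pooled-control cell counts; (ii)
    one-sided Mann-Whitney on per-guide target fractions vs per-group
    control fractions. BH within each test family across all (target,
    phase) pairs. Significant iff Fisher BH < ``fisher_alpha`` AND MW BH <
    ``mw_alpha``; targets with < 2 guides are unassessable by the MW gate.
    """
    exon = guide_fracs[guide_fracs["class"].isin(
        ["exon_deletion", control_class])]
    return _enrichment(exon, control_class, "exon", fisher_alpha, mw_alpha)


def knockout_phase_enrichment(guide_fracs: pd.DataFrame,
                              control_class: str = "intergenic",
                              fisher_alpha: float = FISHER_ALPHA
                              ) -> PhaseEnrichmentResult:
    """Fisher-only gate (BH < ``fisher_alpha``) for gene-knockout targets;
    same lowest-adjusted-p tie-break for the called phase."""
    ko = guide_fracs[guide_fracs["class"].isin(
        ["gene_knockout", control_class])]
    return _enrichment(ko, control_class, "knockout", fisher_alpha, np.nan)
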