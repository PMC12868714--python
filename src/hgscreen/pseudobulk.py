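"""Pseudobulk aggregation and negative-binomial differential expression.

Single-cell counts are summed within perturbation groups (per guide or per
target), turning guides into biological replicates. Testing follows the
count-based DE canon: median-of-ratios size factors, per-gene
method-of-moments dispersions shrunk toward a lowess mean-dispersion trend,
and a per-gene NB log-linear model with a Wald test on the condition
coefficient. A DEG is a gene with BH-adjusted p < 0.05 and |log2FC| > 0.5.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .assignment import CellAssignment
from .library import CONTROL_CLASSES, GuideLibrary

DEG_PADJ = 0.05
DEG_ABS_LFC = 0.5
LN2 = np.log(2.0)


@dataclass
class PseudobulkTable:
    counts: pd.DataFrame     # groups x genes, summed raw counts
    meta: pd.DataFrame       # index group; target_id, guide_index, class, n_cells

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.meta.index):
            raise ValueError("counts and meta must share the group index")


@dataclass
class DEResult:
    table: pd.DataFrame      # per gene: log2fc, se, wald_stat, p, padj, is_deg
    params: dict = field(default_factory=dict)

    @property
    def degs(self) -> pd.Index:
        return self.table.index[self.table["is_deg"].fillna(False)]


def aggregate(expr: ad.AnnData, assignment: CellAssignment,
              library: GuideLibrary, level: str = "guide",
              min_cells: int = 10, perturbed: pd.Series | None = None,
              layer: str | None = "counts",
              cell_mask: pd.Series | None = None) -> PseudobulkTable:
    """Sum raw counts of assigned cells within guide- or target-level groups.

    ``perturbed`` (optional per-cell flags) restricts non-control groups to
    perturbed cells; control-class cells are retained unconditionally since
    the classifier never labels them perturbed. ``cell_mask`` applies a
    further arbitrary restriction (e.g. one cell-cycle phase). Groups with
    fewer than ``min_cells`` member cells are dropped with a warning.
    """
    if level not in ("guide", "target"):
        raise ValueError("level must be 'guide' or 'target'")
    tab = assignment.table
    cells = expr.obs_names.intersection(tab.index[tab["status"] == "assigned"])
    tab = tab.loc[cells]
    cls = {r.hgrna_id: r.target_class for r in library.records}
    target_of = {r.hgrna_id: r.target_id for r in library.records}
    keep = pd.Series(True, index=cells)
    if perturbed is not None:
        is_ctrl = tab["assigned_hgrna"].map(cls).isin(CONTROL_CLASSES)
        keep &= is_ctrl | perturbed.reindex(cells).fillna(False)
    if cell_mask is not None:
        keep &= cell_mask.reindex(cells).fillna(False)
    cells = cells[keep.to_numpy()]
    tab = tab.loc[cells]

    group = (tab["assigned_hgrna"] if level == "guide"
             else tab["assigned_hgrna"].map(target_of))
    X = expr[cells].layers[layer] if layer else expr[cells].X
    X = X.toarray() if sparse.issparse(X) else np.asarray(X)
    df = pd.DataFrame(X, index=cells, columns=expr.var_names)
    summed = df.groupby(group.to_numpy()).sum()
    sizes = group.value_counts()

    rows, meta_rows = [], []
    for g in summed.index:
        n = int(sizes[g])
        if n < min_cells:
            warnings.warn(f"pseudobulk group {g}: {n} cells < {min_cells}, dropped")
            continue
        rows.append(g)
        if level == "guide":
            rec = library.record(g)
            meta_rows.append((rec.target_id, rec.guide_index, rec.target_class, n))
        else:
            meta_rows.append((g, 0, library.class_of_target(g), n))
    if not rows:
        raise ValueError("no pseudobulk groups survive the min_cells filter")
    counts = summed.loc[rows]
    meta = pd.DataFrame(meta_rows, index=pd.Index(rows, name="group"),
                        columns=["target_id", "guide_index", "class", "n_cells"])
    return PseudobulkTable(counts, meta)


def size_factors(pb: PseudobulkTable | pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors per group.

    Reference = per-gene geometric mean across groups over genes positive in
    every group; each group's factor is the median ratio to the reference.
    Falls back (with a warning) to genes positive in that group when no gene
    is positive everywhere.
    """
    counts = pb.counts if isinstance(pb, PseudobulkTable) else pb
    if len(counts) < 2:
        raise ValueError("size factors need >= 2 groups")
    M = counts.to_numpy(dtype=float)
    all_pos = (M > 0).all(axis=0)
    if all_pos.any():
        logg = np.log(M[:, all_pos])
        ref = logg.mean(axis=0)
        sf = np.exp(np.median(logg - ref, axis=1))
    else:
        warnings.warn("no gene positive in all groups; using per-group "
                      "positive genes for size factors")
        with np.errstate(divide="ignore"):
            logM = np.where(M > 0, np.log(M), np.nan)
        ref = np.nanmean(logM, axis=0)
        sf = np.exp(np.nanmedian(logM - ref, axis=1))
    return pd.Series(sf, index=counts.index, name="size_factor")


def estimate_dispersions(pb: PseudobulkTable | pd.DataFrame,
                         sf: pd.Series | None = None,
                         trend_weight: float = 0.7,
                         floor: float = 1e-8) -> pd.Series:
    """Per-gene NB dispersion: method-of-moments on normalized counts,
    shrunk in log space toward a lowess mean-dispersion trend.

    All-zero genes get NaN (excluded from testing downstream).
    """
    counts = pb.counts if isinstance(pb, PseudobulkTable) else pb
    if len(counts) < 3:
        raise ValueError("dispersion estimation needs >= 3 groups")
    if sf is None:
        sf = size_factors(counts)
    norm = counts.to_numpy(dtype=float) / sf.to_numpy()[:, None]
    mean = norm.mean(axis=0)
    var = norm.var(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = (var - mean) / mean ** 2
    raw = np.where(mean > 0, np.maximum(raw, floor), np.nan)

    ok = np.isfinite(raw)
    disp = np.full(len(mean), np.nan)
    if ok.sum() >= 10:
        fitted = lowess(np.log(raw[ok]), np.log(mean[ok]), frac=0.5,
                        return_sorted=False)
        shrunk = np.exp((1 - trend_weight) * np.log(raw[ok])
                        + trend_weight * fitted)
        disp[ok] = np.maximum(shrunk, floor)
    else:
        disp[ok] = np.maximum(raw[ok], floor)
    return pd.Series(disp, index=counts.columns, name="dispersion")


def _nb_irls(y: np.ndarray, x: np.ndarray, offset: np.ndarray,
             alpha: np.ndarray, n_iter: int = 50, tol: float = 1e-8
             ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized IRLS for per-gene NB GLM with design [1, x] and log link.

    ``y``: groups x genes; ``x``: condition indicator per group; ``offset``:
    log size factors; ``alpha``: per-gene dispersion. Returns (beta, se) for
    the condition coefficient with beta = [b0, b1] stacked as (2, genes).
    """
    n, g = y.shape
    X = np.column_stack([np.ones(n), x])
    # init from group means of normalized counts
    ynorm = y / np.exp(offset)[:, None]
    m0 = ynorm[x == 0].mean(axis=0)
    m1 = ynorm[x == 1].mean(axis=0) if (x == 1).any() else m0
    eps = 1e-8
    b0 = np.log(np.maximum(m0, eps))
    b1 = np.log(np.maximum(m1, eps)) - b0
    beta = np.vstack([b0, b1])

    for _ in range(n_iter):
        eta = X @ beta + offset[:, None]
        eta = np.clip(eta, -30, 30)
        mu = np.exp(eta)
        W = mu / (1.0 + alpha[None, :] * mu)
        z = (X @ beta) + (y - mu) / mu
        # weighted 2x2 normal equations per gene
        s00 = W.sum(axis=0)
        s01 = (W * x[:, None]).sum(axis=0)
        s11 = (W * (x ** 2)[:, None]).sum(axis=0)
        t0 = (W * z).sum(axis=0)
        t1 = (W * z * x[:, None]).sum(axis=0)
        det = s00 * s11 - s01 ** 2
        det = np.where(np.abs(det) < 1e-12, np.nan, det)
        new0 = (s11 * t0 - s01 * t1) / det
        new1 = (s00 * t1 - s01 * t0) / det
        new = np.vstack([np.nan_to_num(new0, nan=0.0),
                         np.nan_to_num(new1, nan=0.0)])
        new = np.clip(new, -30, 30)
        if np.nanmax(np.abs(new - beta)) < tol:
            beta = new
            break
        beta = new

    eta = np.clip(X @ beta + offset[:, None], -30, 30)
    mu = np.exp(eta)
    W = mu / (1.0 + alpha[None, :] * mu)
    s00 = W.sum(axis=0)
    s01 = (W * x[:, None]).sum(axis=0)
    s11 = (W * (x ** 2)[:, None]).sum(axis=0)
    det = s00 * s11 - s01 ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        var_b1 = np.where(det > 1e-12, s00 / det, np.inf)
    return beta, np.sqrt(var_b1)


def de_test(pb: PseudobulkTable, target_groups: list[str],
            control_groups: list[str], dispersions: pd.Series | None = None,
            sf: pd.Series | None = None, min_mean_norm: float = 1.0,
            deg_padj: float = DEG_PADJ, deg_abs_lfc: float = DEG_ABS_LFC
            ) -> DEResult:
    """Wald test of target vs control pseudobulk groups per gene.

    NB log-linear model with a condition indicator; log2FC reported on the
    base-2 scale; BH adjustment over tested genes. Genes with mean
    normalized count below ``min_mean_norm`` (independent filtering) or
    undefined dispersion get NaN p/padj and are never DEGs. Degenerate fits
    (zero variance / infinite SE) get p = 1.
    """
    groups = list(target_groups) + list(control_groups)
    missing = set(groups) - set(pb.counts.index)
    if missing:
        raise ValueError(f"groups not in pseudobulk table: {sorted(missing)}")
    if len(control_groups) < 2:
        raise ValueError("need >= 2 control groups")
    counts = pb.counts.loc[groups]
    if sf is None:
        sf = size_factors(pb)
    sf = sf.loc[groups]
    if dispersions is None:
        dispersions = estimate_dispersions(pb, sf=size_factors(pb))
    x = np.array([1.0] * len(target_groups) + [0.0] * len(control_groups))

    y = counts.to_numpy(dtype=float)
    offset = np.log(sf.to_numpy())
    norm_mean = (y / sf.to_numpy()[:, None]).mean(axis=0)
    alpha = dispersions.reindex(counts.columns).to_numpy()
    testable = np.isfinite(alpha) & (norm_mean >= min_mean_norm)

    lfc = np.full(counts.shape[1], np.nan)
    se = np.full(counts.shape[1], np.nan)
    wald = np.full(counts.shape[1], np.nan)
    p = np.full(counts.shape[1], np.nan)
    if testable.any():
        beta, se_b1 = _nb_irls(y[:, testable], x, offset, alpha[testable])
        b1 = beta[1]
        lfc[testable] = b1 / LN2
        se[testable] = se_b1 / LN2
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(np.isfinite(se_b1) & (se_b1 > 0), b1 / se_b1, 0.0)
        wald[testable] = z
        pv = 2.0 * stats.norm.sf(np.abs(z))
        pv = np.where(np.isfinite(se_b1) & (se_b1 > 0), pv, 1.0)
        p[testable] = pv

    padj = np.full(counts.shape[1], np.nan)
    tested = np.isfinite(p)
    if tested.any():
        padj[tested] = multipletests(p[tested], method="fdr_bh")[1]
    is_deg = (padj < deg_padj) & (np.abs(lfc) > deg_abs_lfc)
    table = pd.DataFrame(
        {"log2fc": lfc, "se": se, "wald_stat": wald, "p": p, "padj": padj,
         "is_deg": np.where(np.isfinite(padj), is_deg, False),
         "mean_norm": norm_mean},
        index=counts.columns.copy())
    table["is_deg"] = table["is_deg"].astype(bool)
    return DEResult(table, params={
        "target_groups": list(target_groups),
        "control_groups": list(control_groups),
        "min_mean_norm": min_mean_norm,
        "deg_padj": deg_padj, "deg_abs_lfc": deg_abs_lfc})


def de_per_target(pb: PseudobulkTable, library: GuideLibrary,
                  control_class: str = "intergenic",
                  dispersions: pd.Series | None = None,
                  sf: pd.Series | None = None,
                  targets: list[str] | None = None,
                  **kw) -> dict[str, DEResult]:
    """Run ``de_test`` for every non-control target against the control
    groups, sharing size factors and dispersions across tests."""
    meta = pb.meta
    control_groups = list(meta.index[meta["class"] == control_class])
    if sf is None:
        sf = size_factors(pb)
    if dispersions is None:
        dispersions = estimate_dispersions(pb, sf=sf)
    if targets is None:
        targets = [t for t in meta["target_id"].unique()
                   if library.class_of_target(t) not in CONTROL_CLASSES]
    out = {}
    for t in targets:
        tg = list(meta.index[meta["target_id"] == t])
        if not tg:
            continue
        out[t] = de_test(pb, tg, control_groups, dispersions=dispersions,
                         sf=sf, **kw)
    return out


def guide_concordance(per_guide: dict[str, DEResult],
                      hvg: pd.Index | list[str]) -> float:
    """Mean pairwise Pearson r of per-guide log2FCs over the HVG set.

    Returns NaN when fewer than two guides have results.
    """
    if len(per_guide) < 2:
        return float("nan")
    hvg = pd.Index(hvg)
    vecs = {}
    for g, res in per_guide.items():
        v = res.table["log2fc"].reindex(hvg)
        vecs[g] = v.to_numpy()
    rs = []
    for a, b in itertools.combinations(sorted(vecs), 2):
        va, vb = vecs[a], vecs[b]
        ok = np.isfinite(va) & np.isfinite(vb)
        if ok.sum() >= 3:
            rs.append(stats.pearsonr(va[ok], vb[ok])[0])
    return float(np.mean(rs)) if rs else float("nan")
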