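"""Cell/gene QC and the normalization -> log -> HVG -> regression -> scaling
transform chain.

The chain mirrors standard droplet scRNA-seq preprocessing: drop cells
expressing fewer than 200 genes and genes seen in fewer than three cells,
scale every cell to 10,000 counts and log1p, flag highly variable genes by
bin-normalized dispersion, regress library size and mitochondrial fraction
out of each gene, and z-scale with the upper tail clipped at 10.
"""

from __future__ import annotations

import warnings

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
from scipy import sparse


class EmptyMatrixWarning(UserWarning):
    """Raised (as a warning) when a filter empties the matrix."""


def compute_qc_metrics(adata: ad.AnnData, mito_prefix: str = "MT-") -> None:
    """Attach total_umi, n_genes_expressed and pct_mito to ``adata.obs``."""
    X = adata.X
    if sparse.issparse(X):
        total = np.asarray(X.sum(axis=1)).ravel()
        n_expr = np.asarray((X > 0).sum(axis=1)).ravel()
        mito_mask = adata.var_names.str.startswith(mito_prefix)
        mito = np.asarray(X[:, mito_mask].sum(axis=1)).ravel()
    else:
        total = X.sum(axis=1)
        n_expr = (X > 0).sum(axis=1)
        mito_mask = adata.var_names.str.startswith(mito_prefix)
        mito = X[:, mito_mask].sum(axis=1)
    adata.obs["total_umi"] = total
    adata.obs["n_genes_expressed"] = n_expr
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(total > 0, 100.0 * mito / total, 0.0)
    adata.obs["pct_mito"] = pct


def filter_cells_genes(adata: ad.AnnData, min_genes: int = 200,
                       min_cells: int = 3, iterate: bool = False) -> ad.AnnData:
    """Remove cells expressing < ``min_genes`` genes, then genes expressed in
    < ``min_cells`` cells (single pass by default; ``iterate`` repeats to a
    fixed point). An empty result is returned with a warning, not an error.
    """
    out = adata.copy()
    while True:
        n_before = out.shape
        if out.n_obs:
            sc.pp.filter_cells(out, min_genes=min_genes)
        if out.n_vars and out.n_obs:
            sc.pp.filter_genes(out, min_cells=min_cells)
        if 0 in out.shape:
            warnings.warn(
                f"QC filtering left an empty matrix (shape {out.shape})",
                EmptyMatrixWarning)
            return out
        if not iterate or out.shape == n_before:
            return out


def normalize_log(adata: ad.AnnData, target_sum: float = 10_000.0) -> None:
    """Scale each cell to ``target_sum`` counts and log1p; stores the raw
    counts in ``layers['counts']`` and the result in ``layers['normalized']``
    (and ``X``)."""
    X = adata.X
    totals = np.asarray(X.sum(axis=1)).ravel()
    if np.any(totals == 0):
        raise ValueError("zero-count cell encountered; run QC filtering first")
    adata.layers["counts"] = X.copy()
    adata.X = adata.X.astype(np.float64)   # keep row sums exact at 1e4 scale
    sc.pp.normalize_total(adata, target_sum=target_sum)
    sc.pp.log1p(adata)
    adata.layers["normalized"] = adata.X.copy()
    adata.uns["target_sum"] = target_sum


def select_hvg(adata: ad.AnnData, min_mean: float = 0.0125, max_mean: float = 3.0,
               min_disp: float = 0.5, n_bins: int = 20) -> None:
    """Flag highly variable genes by bin-normalized dispersion.

    Works on ``layers['normalized']``: per gene, mean and dispersion
    (variance/mean) of ``expm1`` of the log-normalized values; genes are cut
    into ``n_bins`` equal-frequency mean bins and dispersions z-scored within
    each bin. Flagged iff mean in (min_mean, max_mean) and normalized
    dispersion > ``min_disp``. Results land in ``var['highly_variable']``,
    ``var['hvg_mean']`` and ``var['hvg_dispersion_norm']``.
    """
    X = adata.layers["normalized"]
    X = X.toarray() if sparse.issparse(X) else np.asarray(X)
    vals = np.expm1(X)
    mean = vals.mean(axis=0)
    var = vals.var(axis=0, ddof=1) if vals.shape[0] > 1 else np.zeros(vals.shape[1])
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)

    n_genes = len(mean)
    if n_genes < n_bins:
        warnings.warn(
            f"only {n_genes} genes; reducing HVG bins from {n_bins}")
        n_bins = max(1, n_genes)
    bins = pd.qcut(pd.Series(mean).rank(method="first"), n_bins, labels=False)
    disp_s = pd.Series(disp)
    grp = disp_s.groupby(bins)
    mu_b = grp.transform("mean")
    sd_b = grp.transform("std")
    # degenerate bins (single gene or zero spread): fall back to raw offset
    sd_b = sd_b.replace(0.0, np.nan)
    disp_norm = ((disp_s - mu_b) / sd_b).fillna(0.0).to_numpy()

    flagged = (mean > min_mean) & (mean < max_mean) & (disp_norm > min_disp)
    flagged &= var > 0
    adata.var["hvg_mean"] = mean
    adata.var["hvg_dispersion"] = disp
    adata.var["hvg_dispersion_norm"] = disp_norm
    adata.var["highly_variable"] = flagged


def regress_and_scale(adata: ad.AnnData,
                      covariates: tuple[str, ...] = ("total_umi", "pct_mito"),
                      max_value: float = 10.0) -> None:
    """Replace each gene by OLS residuals on the covariates (+ intercept),
    then center, scale to unit variance, and clip the upper tail at
    ``max_value``. Zero-variance genes scale to 0. Result in
    ``layers['scaled']`` (and ``X``)."""
    for c in covariates:
        if c not in adata.obs.columns:
            raise ValueError(f"covariate {c} missing from obs; run QC metrics")
    Y = adata.layers["normalized"]
    Y = Y.toarray() if sparse.issparse(Y) else np.asarray(Y, dtype=float)
    X = np.column_stack([np.ones(adata.n_obs)]
                        + [adata.obs[c].to_numpy(dtype=float) for c in covariates])
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    mu = resid.mean(axis=0)
    sd = resid.std(axis=0, ddof=0)
    # residuals that are zero up to lstsq round-off count as zero-variance
    tol = 1e-10 * max(float(np.abs(Y).max()), 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(sd > tol, (resid - mu) / sd, 0.0)
    np.minimum(scaled, max_value, out=scaled)
    adata.layers["scaled"] = scaled
    adata.X = scaled.copy()
    adata.uns["scale_max_value"] = max_value
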