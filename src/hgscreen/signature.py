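"""Local perturbation signatures and perturbed-vs-escaping classification.

A cell's signature is its (scaled) expression minus the mean of its nearest
control cells, found in PCA space — removing shared technical/state
variation so that only the perturbation-induced shift remains. Per target,
cells are then classified perturbed vs escaping with a two-component
univariate Gaussian mixture on signature scores projected onto the
target-vs-control difference axis, with the control-like component anchored
on the control cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .assignment import CellAssignment
from .library import GuideLibrary


@dataclass
class SignatureResult:
    signature: pd.DataFrame            # cells x HVG
    perturbed: pd.Series               # bool per cell
    escape_rate: pd.Series             # per target
    params: dict = field(default_factory=dict)


def _control_mask(assignment: CellAssignment, library: GuideLibrary,
                  control_class: str, cells: pd.Index) -> np.ndarray:
    tab = assignment.table.loc[cells]
    cls = {r.hgrna_id: r.target_class for r in library.records}
    return (tab["assigned_hgrna"].map(cls) == control_class).to_numpy()


def compute_signature(adata: ad.AnnData, assignment: CellAssignment,
                      library: GuideLibrary, control_class: str = "intergenic",
                      n_neighbors: int = 20, n_pcs: int = 40,
                      layer: str = "scaled") -> pd.DataFrame:
    """Signature = scaled expression minus the mean of the ``n_neighbors``
    nearest control cells, neighbours found in a ``n_pcs``-component PCA of
    the HVG-scaled layer. Uses only cells present in both the matrix and the
    assignment table; returns a cells x HVG DataFrame."""
    hvg = adata.var["highly_variable"].to_numpy()
    if hvg.sum() == 0:
        raise ValueError("no highly variable genes flagged")
    X = adata.layers[layer]
    X = X.toarray() if hasattr(X, "toarray") else np.asarray(X)
    X = X[:, hvg]
    cells = adata.obs_names
    ctrl = _control_mask(assignment, library, control_class, cells)
    n_ctrl = int(ctrl.sum())
    if n_ctrl < n_neighbors:
        raise ValueError(
            f"need >= {n_neighbors} {control_class} control cells, "
            f"found {n_ctrl}")

    n_pcs = min(n_pcs, min(X.shape) - 1)
    pcs = PCA(n_components=n_pcs, random_state=0).fit_transform(X)
    # query one extra neighbour and drop self-matches, so control cells do
    # not subtract themselves (which would deflate their signature variance
    # relative to target cells)
    k = min(n_neighbors + 1, n_ctrl)
    nn = NearestNeighbors(n_neighbors=k).fit(pcs[ctrl])
    _, idx = nn.kneighbors(pcs)
    ctrl_pos = np.flatnonzero(ctrl)
    own = np.full(X.shape[0], -1)
    own[ctrl_pos] = np.arange(n_ctrl)
    keep = np.empty((X.shape[0], min(n_neighbors, k - 1) if n_ctrl > n_neighbors
                     else k), dtype=int)
    n_keep = keep.shape[1]
    for i in range(X.shape[0]):
        row = idx[i]
        row = row[row != own[i]]
        keep[i] = row[:n_keep]
    ctrl_X = X[ctrl]
    sig = X - ctrl_X[keep].mean(axis=1)
    return pd.DataFrame(sig, index=cells.copy(),
                        columns=adata.var_names[hvg].copy())


def classify_perturbed(signature: pd.DataFrame, assignment: CellAssignment,
                       library: GuideLibrary, control_class: str = "intergenic",
                       max_iter: int = 100, tol: float = 1e-4,
                       min_cells: int = 10, min_separation: float = 0.5,
                       n_boot: int = 200, boot_quantile: float = 0.99,
                       seed: int = 0) -> SignatureResult:
    """Label each target cell perturbed or escaping.

    Per target: project target and control signatures onto the difference
    axis (mean target signature - mean control signature); the control
    component's Gaussian parameters are estimated from control cells and
    held fixed, the perturbed component is re-estimated from the currently
    perturbed-labelled target cells, and cells are reassigned by posterior
    until labels stabilise. Ties break toward escaping. A perturbation is
    declared undetectable — all its cells escape — unless (i) its mean
    signature shift exceeds the ``boot_quantile`` of a control-cell
    bootstrap null of the same group size (``n_boot`` draws, seeded), and
    (ii) the components' standardized mean separation, corrected for the
    sampling bias of the empirical mean-difference norm, stays at or above
    ``min_separation``.
    Control cells are never labelled perturbed. Targets with fewer than
    ``min_cells`` cells are left unclassified (retained, flagged perturbed)
    with a warning.
    """
    cells = signature.index
    tab = assignment.table.loc[cells]
    cls = {r.hgrna_id: r.target_class for r in library.records}
    target_of = {r.hgrna_id: r.target_id for r in library.records}
    ctrl = (tab["assigned_hgrna"].map(cls) == control_class).to_numpy()
    sig = signature.to_numpy()
    ctrl_sig = sig[ctrl]
    ctrl_mean = ctrl_sig.mean(axis=0)
    rng = np.random.default_rng(seed)
    boot_cache: dict[int, float] = {}

    def _boot_threshold(n_t: int) -> float:
        """boot_quantile of ||group mean - control mean||^2 for a random
        control subgroup of size n_t."""
        if n_t not in boot_cache:
            n_c = len(ctrl_sig)
            draws = np.empty(n_boot)
            for b in range(n_boot):
                idx = rng.choice(n_c, size=min(n_t, n_c), replace=False)
                draws[b] = ((ctrl_sig[idx].mean(axis=0) - ctrl_mean) ** 2).sum()
            boot_cache[n_t] = float(np.quantile(draws, boot_quantile))
        return boot_cache[n_t]

    perturbed = pd.Series(False, index=cells)
    rates: dict[str, float] = {}
    targets = tab["assigned_hgrna"].map(target_of)
    for target in sorted(t for t in targets.dropna().unique()
                         if library.class_of_target(t) != control_class
                         and library.class_of_target(t) != "non_targeting"):
        mask = (targets == target).to_numpy()
        n_t = int(mask.sum())
        if n_t < min_cells:
            warnings.warn(f"target {target}: only {n_t} cells, unclassifiable; "
                          "all retained")
            perturbed[mask] = True
            rates[target] = 0.0
            continue
        t_sig = sig[mask]
        delta = t_sig.mean(axis=0) - ctrl_mean
        nrm = np.linalg.norm(delta)
        if nrm == 0:
            perturbed[mask] = False
            rates[target] = 1.0
            continue
        axis = delta / nrm
        x_t = t_sig @ axis
        x_c = ctrl_sig @ axis
        mu0, sd0 = x_c.mean(), max(x_c.std(ddof=0), 1e-8)

        # The empirical mean-difference norm is biased upward under the
        # null (it sums sampling noise over every HVG dimension); subtract
        # its no-effect expectation before testing separation.
        n_c = len(ctrl_sig)
        null_sq = (1.0 / n_t + 1.0 / n_c) * ctrl_sig.var(axis=0, ddof=1).sum()
        eff = np.sqrt(max(nrm ** 2 - null_sq, 0.0))
        sd_t = max(x_t.std(ddof=0), 1e-8)
        pooled0 = np.sqrt(0.5 * (sd0 ** 2 + sd_t ** 2))
        if eff / pooled0 < min_separation or nrm ** 2 <= _boot_threshold(n_t):
            perturbed[mask] = False
            rates[target] = 1.0
            continue

        # EM on the projected scores: control component anchored at
        # (mu0, sd0); perturbed component and mixing weight re-estimated
        # from soft responsibilities until they stabilise.
        w1 = 0.5
        upper = x_t >= np.median(x_t)
        mu1 = x_t[upper].mean()
        sd1 = max(x_t[upper].std(ddof=0), 1e-8)
        resp = np.full(n_t, 0.5)
        separated = True
        for _ in range(max_iter):
            like0 = (1.0 - w1) * norm.pdf(x_t, mu0, sd0)
            like1 = w1 * norm.pdf(x_t, mu1, sd1)
            total = like0 + like1
            total[total == 0] = 1e-300
            new_resp = like1 / total
            w1 = float(np.clip(new_resp.mean(), 0.01, 0.99))
            wsum = new_resp.sum()
            if wsum < 1e-8:
                separated = False
                break
            mu1 = float((new_resp * x_t).sum() / wsum)
            sd1 = float(np.sqrt((new_resp * (x_t - mu1) ** 2).sum() / wsum))
            sd1 = max(sd1, 1e-8)
            pooled = np.sqrt(0.5 * (sd0 ** 2 + sd1 ** 2))
            separated = abs(mu1 - mu0) / pooled >= min_separation
            if not separated:
                break
            if np.abs(new_resp - resp).max() < tol:
                resp = new_resp
                break
            resp = new_resp
        labels = resp > 0.5                         # ties -> escaping
        if not separated:
            labels = np.zeros(n_t, dtype=bool)
        perturbed[mask] = labels
        rates[target] = float(1.0 - labels.mean())

    perturbed[ctrl] = False
    return SignatureResult(
        signature=signature,
        perturbed=perturbed,
        escape_rate=pd.Series(rates, name="escape_rate"),
        params={"max_iter": max_iter, "tol": tol, "min_cells": min_cells,
                "min_separation": min_separation,
                "control_class": control_class})
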