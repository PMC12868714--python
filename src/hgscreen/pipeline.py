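"""End-to-end orchestration: one config, one seed, one run manifest.

Stages run in a fixed order (simulate? -> assign -> qc -> signature -> de ->
cellcycle -> compare); each stage derives its own child seed from the global
seed and the stage name, so toggling one stage never shifts another stage's
random stream. Every parameter is echoed verbatim into the run manifest
along with SHA-256 hashes of all written outputs; unknown config keys are
rejected before anything runs.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from . import io as hio
from .assignment import assign_perturbations, assignment_summary, detect_guides
from .cellcycle import (exon_phase_enrichment, knockout_phase_enrichment,
                        phase_fractions, score_phases)
from .compare import correlate_perturbations, exon_vs_ko, shared_deg_matrix
from .library import GuideLibrary, simulate_guide_library
from .pseudobulk import (aggregate, de_per_target, estimate_dispersions,
                         size_factors)
from .qc import (compute_qc_metrics, filter_cells_genes, normalize_log,
                 regress_and_scale, select_hvg)
from .signature import classify_perturbed, compute_signature
from .simulate import default_marker_sets, simulate_cells, simulate_truth


class SimulateParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_exon_targets: int = 8
    guides_per_exon: int = 3
    n_gene_targets: int = 4
    guides_per_gene: int = 2
    n_intergenic: int = 40
    n_nontargeting: int = 8
    n_genes: int = 1000
    n_cells_per_guide: int = 50
    mean_affected_per_target: int = 20
    lfc_scale: float = 1.0
    escape_fraction: float = 0.0
    p_detect_cas9: float = 0.95
    p_detect_cas12a: float = 0.9
    doublet_rate: float = 0.05
    decoupling_rate: float = 0.02
    phase_proportions: tuple[float, float, float] = (0.18, 0.52, 0.30)
    phase_effect_lfc: float = 1.0
    ambient_rate: float = 0.1


class AssignParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    min_umi: int = 5
    dominance_ratio: float = 3.0
    exclude_nontargeting: bool = True
    require_dual: bool = False


class QCParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    min_genes: int = 200
    min_cells: int = 3
    target_sum: float = 10_000.0
    hvg_min_mean: float = 0.0125
    hvg_max_mean: float = 3.0
    hvg_min_disp: float = 0.5
    scale_max_value: float = 10.0


class SignatureParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    control_class: str = "intergenic"
    n_neighbors: int = 20
    n_pcs: int = 40
    min_separation: float = 0.5


class DEParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    level: str = "target"
    min_cells: int = 10
    perturbed_only: bool = True
    min_mean_norm: float = 1.0


class CellCycleParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_bins: int = 25
    ctrl_size: int = 50


class CompareParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    min_perturbations: int = 30
    concordance_r: float = 0.4


class RunConfig(BaseModel):
    """Full pipeline configuration; unknown keys are rejected."""
    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    outdir: str = "hgscreen_run"
    run_signature: bool = True
    run_de: bool = True
    run_cellcycle: bool = True
    run_compare: bool = True
    simulate: SimulateParams = SimulateParams()
    assign: AssignParams = AssignParams()
    qc: QCParams = QCParams()
    signature: SignatureParams = SignatureParams()
    de: DEParams = DEParams()
    cellcycle: CellCycleParams = CellCycleParams()
    compare: CompareParams = CompareParams()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)


def stage_seed(seed: int, stage: str) -> int:
    """Child seed for a stage: stable hash of (seed, stage name), < 2^31."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def run_pipeline(config: RunConfig) -> dict:
    """Run the synthetic end-to-end pipeline; returns the run manifest."""
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": json.loads(config.model_dump_json()),
                      "stages": {}, "outputs": {}}

    def _done(stage: str, started: float) -> None:
        manifest["stages"][stage] = {"seconds": round(time.time() - started, 3)}

    def _write_tsv(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t")
        manifest["outputs"][name] = hio.file_sha256(path)

    # --- simulate ---------------------------------------------------------
    ts = time.time()
    sp = config.simulate
    library = simulate_guide_library(
        sp.n_exon_targets, sp.guides_per_exon, sp.n_gene_targets,
        sp.guides_per_gene, sp.n_intergenic, sp.n_nontargeting,
        seed=stage_seed(config.seed, "library"))
    truth = simulate_truth(
        library, sp.n_genes, sp.mean_affected_per_target, sp.lfc_scale,
        sp.escape_fraction, seed=stage_seed(config.seed, "truth"))
    s_markers, g2m_markers = default_marker_sets(truth)
    guide_adata, expr, cell_truth = simulate_cells(
        library, truth, sp.n_cells_per_guide, sp.p_detect_cas9,
        sp.p_detect_cas12a, sp.doublet_rate, sp.decoupling_rate,
        sp.phase_proportions, s_markers, g2m_markers, sp.phase_effect_lfc,
        seed=stage_seed(config.seed, "cells"), ambient_rate=sp.ambient_rate)
    library.write_tsv(outdir / "library.tsv")
    manifest["outputs"]["library.tsv"] = hio.file_sha256(outdir / "library.tsv")
    _write_tsv(cell_truth, "cell_truth.tsv")
    _done("simulate", ts)

    # --- assign -----------------------------------------------------------
    ts = time.time()
    ap = config.assign
    detected = detect_guides(guide_adata, ap.min_umi, ap.dominance_ratio)
    assignment = assign_perturbations(detected, library,
                                      ap.exclude_nontargeting, ap.require_dual)
    out_tab = assignment.table[["capture_category", "assigned_hgrna",
                                "status"]].copy()
    _write_tsv(out_tab, "assignments.tsv")
    hio.write_json(assignment_summary(assignment), outdir / "assignment_summary.json")
    manifest["outputs"]["assignment_summary.json"] = hio.file_sha256(
        outdir / "assignment_summary.json")
    _done("assign", ts)

    # --- qc ---------------------------------------------------------------
    ts = time.time()
    qp = config.qc
    assigned_cells = assignment.table.index[
        assignment.table["status"] == "assigned"]
    adata = expr[expr.obs_names.isin(assigned_cells)].copy()
    adata = filter_cells_genes(adata, qp.min_genes, qp.min_cells)
    compute_qc_metrics(adata)
    normalize_log(adata, qp.target_sum)
    select_hvg(adata, qp.hvg_min_mean, qp.hvg_max_mean, qp.hvg_min_disp)
    regress_and_scale(adata, max_value=qp.scale_max_value)
    _write_tsv(adata.obs[["total_umi", "n_genes_expressed", "pct_mito"]],
               "qc_metrics.tsv")
    _done("qc", ts)

    # --- signature --------------------------------------------------------
    perturbed = None
    if config.run_signature:
        ts = time.time()
        gp = config.signature
        sig = compute_signature(adata, assignment, library, gp.control_class,
                                gp.n_neighbors, gp.n_pcs)
        sig_res = classify_perturbed(sig, assignment, library,
                                     gp.control_class,
                                     min_separation=gp.min_separation)
        perturbed = sig_res.perturbed
        _write_tsv(perturbed.to_frame("perturbed"), "perturbed_cells.tsv")
        _write_tsv(sig_res.escape_rate.to_frame(), "escape_rates.tsv")
        _done("signature", ts)

    # --- de ---------------------------------------------------------------
    de_results = {}
    if config.run_de:
        ts = time.time()
        dp = config.de
        pb = aggregate(adata, assignment, library, level=dp.level,
                       min_cells=dp.min_cells,
                       perturbed=perturbed if dp.perturbed_only else None)
        sf = size_factors(pb)
        disp = estimate_dispersions(pb, sf=sf)
        de_results = de_per_target(pb, library, config.signature.control_class,
                                   dispersions=disp, sf=sf,
                                   min_mean_norm=dp.min_mean_norm)
        de_tab = pd.concat(
            {t: r.table for t, r in de_results.items()}, names=["target", "gene"])
        _write_tsv(de_tab, "de_results.tsv")
        _done("de", ts)

    # --- cellcycle --------------------------------------------------------
    if config.run_cellcycle:
        ts = time.time()
        cp = config.cellcycle
        phases = score_phases(adata, s_markers, g2m_markers, cp.n_bins,
                              cp.ctrl_size,
                              seed=stage_seed(config.seed, "cellcycle"))
        _write_tsv(phases, "phase_calls.tsv")
        fracs = phase_fractions(phases["phase"], assignment, library,
                                level="guide", perturbed=perturbed)
        _write_tsv(fracs, "phase_fractions.tsv")
        if (fracs["class"] == "exon_deletion").any():
            exon_res = exon_phase_enrichment(fracs)
            _write_tsv(exon_res.table, "exon_phase_enrichment.tsv")
        if (fracs["class"] == "gene_knockout").any():
            ko_res = knockout_phase_enrichment(fracs)
            _write_tsv(ko_res.table, "ko_phase_enrichment.tsv")
        _done("cellcycle", ts)

    # --- compare ----------------------------------------------------------
    if config.run_compare and de_results:
        ts = time.time()
        mp = config.compare
        mat = shared_deg_matrix(de_results,
                                min_perturbations=min(mp.min_perturbations,
                                                      max(1, len(de_results))))
        if mat.shape[0] >= 1 and mat.shape[1] >= 2:
            corr, order = correlate_perturbations(mat)
            _write_tsv(corr, "perturbation_correlation.tsv")
            hio.write_json({"leaf_order": order}, outdir / "dendrogram_order.json")
            manifest["outputs"]["dendrogram_order.json"] = hio.file_sha256(
                outdir / "dendrogram_order.json")
        rows = []
        for exon_t in library.targets("exon_deletion"):
            for ko_t in library.targets("gene_knockout"):
                if exon_t in de_results and ko_t in de_results:
                    div = exon_vs_ko(de_results[exon_t], de_results[ko_t],
                                     threshold=mp.concordance_r)
                    rows.append((exon_t, ko_t, div.r_exon_vs_ko,
                                 div.n_union_degs, div.concordant))
                    break
        if rows:
            _write_tsv(pd.DataFrame(
                rows, columns=["exon", "ko", "r", "n_union_degs",
                               "concordant"]).set_index("exon"),
                "divergence.tsv")
        _done("compare", ts)

    manifest["total_seconds"] = round(time.time() - t0, 3)
    hio.write_json(manifest, outdir / "run_manifest.json")
    return manifest
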