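"""Shared fixtures: synthetic screens at various noise settings and a toy
GTF builder. Everything is generated programmatically and seeded."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from hgscreen.assignment import assign_perturbations, detect_guides
from hgscreen.library import simulate_guide_library
from hgscreen.qc import (compute_qc_metrics, filter_cells_genes,
                         normalize_log, regress_and_scale, select_hvg)
from hgscreen.simulate import (default_marker_sets, simulate_cells,
                               simulate_truth)


def build_screen(n_exon=4, n_gene=0, n_intergenic=40, n_ntc=0,
                 n_genes=1000, cells_per_guide=60, lfc_scale=0.0,
                 escape_fraction=0.0, mean_affected=20, seed=100,
                 p9=1.0, p12=1.0, doublet_rate=0.0, decoupling_rate=0.0,
                 ambient_rate=0.0, phase_effect_lfc=1.0,
                 phase_proportions=(0.18, 0.52, 0.30),
                 phase_by_target=None, planted=None):
    """One synthetic screen: (library, truth, guide_adata, expr, cell_truth,
    markers). ``planted`` optionally maps target -> {gene_idx: lfc} applied
    on top of the drawn truth."""
    lib = simulate_guide_library(n_exon, 3, n_gene, 2, n_intergenic, n_ntc,
                                 seed=seed)
    truth = simulate_truth(lib, n_genes, mean_affected, lfc_scale,
                           escape_fraction, seed=seed + 1)
    if planted:
        for t, prog in planted.items():
            truth.log2fc[t] = {truth.genes[i]: float(l)
                               for i, l in prog.items()}
    s_m, g_m = default_marker_sets(truth)
    ga, expr, ct = simulate_cells(
        lib, truth, cells_per_guide, p9, p12, doublet_rate, decoupling_rate,
        phase_proportions, s_m, g_m, phase_effect_lfc, seed=seed + 2,
        ambient_rate=ambient_rate, phase_proportions_by_target=phase_by_target)
    return lib, truth, ga, expr, ct, (s_m, g_m)


def preprocess(expr, min_genes=200, min_cells=3):
    """QC chain on a copy of the expression matrix."""
    ad2 = expr.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ad2 = filter_cells_genes(ad2, min_genes, min_cells)
        compute_qc_metrics(ad2)
        normalize_log(ad2)
        select_hvg(ad2)
        regress_and_scale(ad2)
    return ad2


def mid_expression_program(truth, rng, n_genes=20, lfc=2.0):
    """A strong planted program on genes inside the HVG mean window."""
    order = np.argsort(truth.baseline_mean)
    mid = order[int(0.35 * len(order)):int(0.70 * len(order))]
    idx = rng.choice(mid, n_genes, replace=False)
    return {int(i): float(rng.choice([-lfc, lfc])) for i in idx}


@pytest.fixture(scope="session")
def clean_screen():
    """Noise-free screen with strong mid-expression programs: 4 exon
    targets x 3 guides, 40 intergenic controls, 60 cells per guide."""
    rng = np.random.default_rng(7)
    lib = simulate_guide_library(4, 3, 0, 2, 40, 0, seed=100)
    truth = simulate_truth(lib, 1000, 20, 0.0, 0.0, seed=101)
    planted = {t: mid_expression_program(truth, rng)
               for t in lib.targets("exon_deletion")}
    for t, prog in planted.items():
        truth.log2fc[t] = {truth.genes[i]: l for i, l in prog.items()}
    s_m, g_m = default_marker_sets(truth)
    ga, expr, ct = simulate_cells(lib, truth, 60, 1.0, 1.0, 0.0, 0.0,
                                  (0.18, 0.52, 0.30), s_m, g_m, 1.0,
                                  seed=102, ambient_rate=0.0)
    return dict(library=lib, truth=truth, guides=ga, expr=expr,
                cell_truth=ct, markers=(s_m, g_m))


@pytest.fixture(scope="session")
def clean_assignment(clean_screen):
    det = detect_guides(clean_screen["guides"])
    return assign_perturbations(det, clean_screen["library"])


@pytest.fixture(scope="session")
def clean_processed(clean_screen):
    return preprocess(clean_screen["expr"])


def toy_gtf(tmp_path, name="toy.gtf", strand="+", mxe=False):
    """Small single-gene GTF with inclusion / strict-skipping / long-skipping
    isoforms; with ``mxe`` a mutually-exclusive-exon pair is added."""
    def line(feat, s, e, tx=None, gene="GENE1"):
        attrs = f'gene_id "{gene}";'
        if tx:
            attrs += f' transcript_id "{tx}";'
        return f"chr1\ttoy\t{feat}\t{s}\t{e}\t.\t{strand}\t.\t{attrs}"

    rows = [line("gene", 101, 800)]
    txs = {
        "TX_INC": ([(101, 200), (301, 498), (601, 700)],
                   [(151, 200), (301, 498), (601, 650)]),
        "TX_SKIP": ([(101, 200), (601, 700)], [(151, 200), (601, 650)]),
        "TX_LONG": ([(101, 200), (601, 790)], [(151, 200), (601, 655)]),
    }
    if mxe:
        # partner exon of the same length in the downstream intron
        txs["TX_MXE"] = ([(101, 200), (501, 698), (701, 800)],
                         [(151, 200), (501, 698), (701, 750)])
        txs["TX_INC"] = ([(101, 200), (301, 498), (701, 800)],
                         [(151, 200), (301, 498), (701, 750)])
        del txs["TX_SKIP"], txs["TX_LONG"]
    for tx, (exons, cds) in txs.items():
        rows.append(line("transcript", exons[0][0], exons[-1][1], tx))
        rows.extend(line("exon", s, e, tx) for s, e in exons)
        rows.extend(line("CDS", s, e, tx) for s, e in cds)
    path = tmp_path / name
    path.write_text("\n".join(rows) + "\n")
    return path
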