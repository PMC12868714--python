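"""Ground-truthed synthetic screen generator.

Emulates the statistical structure a dual-nuclease guide-capture screen
hands to the downstream pipeline: per-modality guide detection, ambient
guide background, cell doublets, Cas9/Cas12a guide decoupling, negative
binomial expression with per-target log2 fold-change programs, a fraction
of escaping (unperturbed) cells, cell-cycle-phase-structured marker
expression, and log-normal library-size variation.

Every stage is deterministic in its seed, and the returned
:class:`CellTruth` table carries the hidden labels (true hgRNA(s), doublet /
decoupled / escaping flags, true phase) so recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

from .library import CONTROL_CLASSES, GuideLibrary

PHASES = ("G1", "S", "G2M")


def make_gene_names(n_genes: int, n_mito: int = 5) -> list[str]:
    """Synthetic gene universe; the first ``n_mito`` genes carry the
    mitochondrial name prefix so percent-mito QC is exercisable."""
    if n_mito > n_genes:
        raise ValueError("n_mito cannot exceed n_genes")
    mito = [f"MT-G{i + 1:03d}" for i in range(n_mito)]
    rest = [f"G{i + 1:05d}" for i in range(n_genes - n_mito)]
    return mito + rest


def default_marker_sets(truth: "PerturbationTruth", n_s: int = 20,
                        n_g2m: int = 20) -> tuple[list[str], list[str]]:
    """Disjoint S and G2/M marker sets for a synthetic truth object.

    Real cycling markers sit at moderate expression in their off phase and
    are induced a few-fold when active, so markers are taken from the
    middle of the baseline-expression distribution (55th-80th percentile,
    interleaved between the two sets) rather than the heavy lognormal tail.
    """
    n = len(truth.genes)
    if n < 4 * (n_s + n_g2m):
        raise ValueError("gene universe too small for requested marker sets")
    order = np.argsort(truth.baseline_mean)
    lo, hi = int(0.55 * n), int(0.80 * n)
    band = order[lo:hi]
    picks = band[: 2 * (n_s + n_g2m):2]
    s_idx, g2m_idx = picks[:n_s], picks[n_s:n_s + n_g2m]
    return ([truth.genes[i] for i in s_idx], [truth.genes[i] for i in g2m_idx])


@dataclass
class PerturbationTruth:
    """Hidden effect model behind a synthetic screen.

    ``log2fc``: per target id, a mapping gene -> planted log2 fold-change
    (controls map to an empty dict). ``escape_fraction``: per target,
    the probability a cell carrying it shows no expression shift.
    """

    genes: list[str]
    baseline_mean: np.ndarray          # per gene, > 0
    nb_dispersion: np.ndarray          # per gene, > 0
    log2fc: dict[str, dict[str, float]] = field(default_factory=dict)
    escape_fraction: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.baseline_mean <= 0) or np.any(self.nb_dispersion <= 0):
            raise ValueError("baseline means and dispersions must be positive")
        for t, f in self.escape_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"escape_fraction for {t} outside [0, 1]")

    def lfc_vector(self, target_id: str) -> np.ndarray:
        """Planted log2FC over the full gene universe (zeros elsewhere)."""
        v = np.zeros(len(self.genes))
        prog = self.log2fc.get(target_id, {})
        if prog:
            idx = {g: i for i, g in enumerate(self.genes)}
            for g, l in prog.items():
                v[idx[g]] = l
        return v


def simulate_truth(
    library: GuideLibrary,
    n_genes: int,
    mean_affected_per_target: int = 20,
    lfc_scale: float = 1.0,
    escape_fraction: float = 0.0,
    seed: int = 0,
    n_mito: int = 5,
) -> PerturbationTruth:
    """Draw the hidden effect model for a library.

    Each non-control target receives a Poisson(``mean_affected_per_target``)-
    sized affected gene set with log2 fold-changes symmetric about zero at
    scale ``lfc_scale`` (magnitudes uniform in [0.5, 1.5] x scale). Baseline
    means are log-normal with a heavy tail (log-sd 2, median 1 UMI/cell), so
    per-gene relative abundances span orders of magnitude as in droplet
    scRNA-seq; dispersions are log-normal around 0.15.
    """
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    if not 0.0 <= escape_fraction <= 1.0:
        raise ValueError("escape_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = make_gene_names(n_genes, n_mito=min(n_mito, n_genes))
    baseline = np.exp(rng.normal(0.0, 2.0, size=n_genes))
    disp = np.exp(rng.normal(np.log(0.15), 0.3, size=n_genes))

    log2fc: dict[str, dict[str, float]] = {}
    escape: dict[str, float] = {}
    for target in library.targets():
        cls = library.class_of_target(target)
        if cls in CONTROL_CLASSES:
            log2fc[target] = {}
            escape[target] = 0.0
            continue
        k = min(int(rng.poisson(mean_affected_per_target)), n_genes)
        idx = rng.choice(n_genes, size=k, replace=False)
        signs = rng.choice([-1.0, 1.0], size=k)
        mags = lfc_scale * rng.uniform(0.5, 1.5, size=k)
        log2fc[target] = {genes[i]: float(s * m)
                         for i, s, m in zip(idx, signs, mags)}
        escape[target] = escape_fraction
    return PerturbationTruth(genes, baseline, disp, log2fc, escape)


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, disp: np.ndarray
               ) -> np.ndarray:
    """Gamma-Poisson draw: NB with mean mu and Var = mu + disp * mu^2."""
    shape = 1.0 / disp
    lam = rng.gamma(shape, mu * disp)
    return rng.poisson(lam)


def simulate_cells(
    library: GuideLibrary,
    truth: PerturbationTruth,
    n_cells_per_guide: int,
    p_detect_cas9: float = 0.95,
    p_detect_cas12a: float = 0.9,
    doublet_rate: float = 0.0,
    decoupling_rate: float = 0.0,
    phase_proportions: tuple[float, float, float] = (0.18, 0.52, 0.30),
    s_markers: list[str] | None = None,
    g2m_markers: list[str] | None = None,
    phase_effect_lfc: float = 1.0,
    seed: int = 0,
    ambient_rate: float = 0.1,
    guide_umi_mean: float = 20.0,
    libsize_sigma: float = 0.3,
    phase_proportions_by_target: dict[str, tuple[float, float, float]] | None = None,
) -> tuple[ad.AnnData, ad.AnnData, pd.DataFrame]:
    """Simulate the guide-capture and expression matrices for a library.

    Each cell carries one true hgRNA (doublets carry two; expression vectors
    of both constituents are summed and both hgRNAs emitted). A carried
    hgRNA's Cas9 and Cas12a guide features are detected independently with
    the stated probabilities; detected guides receive ``1 + Poisson(lambda)``
    UMIs, and up to two random guide features per cell receive ambient
    ``Poisson(ambient_rate)`` background. Decoupled cells emit the Cas12a
    guide of a random other hgRNA. Expression counts are negative binomial
    with mean ``baseline * 2^planted_lfc * 2^phase_effect (own-phase markers
    only) * lognormal library-size factor``; escaping cells use baseline
    means. ``phase_proportions_by_target`` overrides the global phase mix
    for cells of the named targets, letting phase-redistribution phenotypes
    be planted.

    Returns ``(guide_adata, expr_adata, cell_truth)``.
    """
    if len(library) == 0:
        raise ValueError("library is empty")
    for name, p in (("p_detect_cas9", p_detect_cas9),
                    ("p_detect_cas12a", p_detect_cas12a),
                    ("doublet_rate", doublet_rate),
                    ("decoupling_rate", decoupling_rate)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    props = np.asarray(phase_proportions, dtype=float)
    if props.shape != (3,) or not np.isclose(props.sum(), 1.0):
        raise ValueError("phase_proportions must be a 3-simplex")
    genes = truth.genes
    gene_index = {g: i for i, g in enumerate(genes)}
    s_markers = [] if s_markers is None else list(s_markers)
    g2m_markers = [] if g2m_markers is None else list(g2m_markers)
    for m in s_markers + g2m_markers:
        if m not in gene_index:
            raise ValueError(f"marker gene {m} not in gene universe")

    rng = np.random.default_rng(seed)
    n_guides = len(library)
    n_cells = n_guides * n_cells_per_guide
    n_genes = len(genes)

    hgrna_ids = library.hgrna_ids
    primary = np.repeat(np.arange(n_guides), n_cells_per_guide)
    is_doublet = rng.random(n_cells) < doublet_rate
    partner = np.full(n_cells, -1)
    for i in np.flatnonzero(is_doublet):
        choices = np.delete(np.arange(n_guides), primary[i])
        partner[i] = rng.choice(choices) if len(choices) else primary[i]
    can_decouple = ~is_doublet
    is_decoupled = can_decouple & (rng.random(n_cells) < decoupling_rate)
    swapped = np.full(n_cells, -1)
    for i in np.flatnonzero(is_decoupled):
        choices = np.delete(np.arange(n_guides), primary[i])
        if len(choices) == 0:
            is_decoupled[i] = False
            continue
        swapped[i] = rng.choice(choices)

    target_of = np.array([library.records[g].target_id for g in range(n_guides)])
    esc_p = np.array([truth.escape_fraction.get(t, 0.0) for t in target_of])

    # per-target phase mixes
    def _phase_draw(guide_idx: np.ndarray) -> np.ndarray:
        out = np.empty(len(guide_idx), dtype="<U3")
        for j, g in enumerate(guide_idx):
            p = props
            if phase_proportions_by_target:
                ov = phase_proportions_by_target.get(target_of[g])
                if ov is not None:
                    p = np.asarray(ov, dtype=float)
            out[j] = PHASES[rng.choice(3, p=p / p.sum())]
        return out

    phase = _phase_draw(primary)
    is_escaping = rng.random(n_cells) < esc_p[primary]
    is_escaping[is_doublet] = False

    # planted-effect multiplier per target (log2 scale), cached
    lfc_cache: dict[str, np.ndarray] = {}

    def _mult(target: str) -> np.ndarray:
        if target not in lfc_cache:
            lfc_cache[target] = np.exp2(truth.lfc_vector(target))
        return lfc_cache[target]

    s_idx = np.array([gene_index[m] for m in s_markers], dtype=int)
    g2m_idx = np.array([gene_index[m] for m in g2m_markers], dtype=int)
    phase_mult = np.exp2(phase_effect_lfc)

    def _draw_constituent(guide_idx: np.ndarray, cell_phase: np.ndarray,
                          escaping: np.ndarray) -> np.ndarray:
        mu = np.tile(truth.baseline_mean, (len(guide_idx), 1))
        for t in np.unique(target_of[guide_idx]):
            rows = np.flatnonzero((target_of[guide_idx] == t) & ~escaping)
            if len(rows):
                mu[rows] *= _mult(t)[None, :]
        if len(s_idx):
            mu[np.ix_(cell_phase == "S", s_idx)] *= phase_mult
        if len(g2m_idx):
            mu[np.ix_(cell_phase == "G2M", g2m_idx)] *= phase_mult
        mu *= np.exp(rng.normal(0.0, libsize_sigma, size=len(guide_idx)))[:, None]
        return _nb_counts(rng, mu, truth.nb_dispersion[None, :])

    counts = _draw_constituent(primary, phase, is_escaping)
    dbl = np.flatnonzero(is_doublet)
    if len(dbl):
        partner_phase = _phase_draw(partner[dbl])
        counts[dbl] += _draw_constituent(
            partner[dbl], partner_phase, np.zeros(len(dbl), dtype=bool))

    # --- guide capture -----------------------------------------------------
    n_feat = 2 * n_guides           # cas9 features then cas12a features
    guide_counts = np.zeros((n_cells, n_feat), dtype=np.int64)

    def _emit(rows: np.ndarray, feat: np.ndarray, p: float) -> None:
        det = rows[rng.random(len(rows)) < p]
        guide_counts[det, feat[np.isin(rows, det)]] += (
            1 + rng.poisson(guide_umi_mean, size=len(det)))

    all_rows = np.arange(n_cells)
    cas9_feat = primary.copy()
    cas12a_feat = n_guides + np.where(is_decoupled, swapped, primary)
    _emit(all_rows, cas9_feat, p_detect_cas9)
    _emit(all_rows, cas12a_feat, p_detect_cas12a)
    if len(dbl):
        _emit(dbl, partner[dbl], p_detect_cas9)
        _emit(dbl, n_guides + partner[dbl], p_detect_cas12a)
    if ambient_rate > 0:
        amb_feat = rng.integers(0, n_feat, size=(n_cells, 2))
        amb_counts = rng.poisson(ambient_rate, size=(n_cells, 2))
        for j in range(2):
            np.add.at(guide_counts, (all_rows, amb_feat[:, j]), amb_counts[:, j])

    barcodes = [f"CELL{i + 1:06d}" for i in range(n_cells)]
    feat_ids = ([f"{h}|cas9" for h in hgrna_ids]
                + [f"{h}|cas12a" for h in hgrna_ids])
    guide_var = pd.DataFrame(
        {"hgrna_id": hgrna_ids * 2,
         "modality": ["cas9"] * n_guides + ["cas12a"] * n_guides},
        index=pd.Index(feat_ids, name="feature_id"))
    guide_adata = ad.AnnData(
        X=sparse.csr_matrix(guide_counts),
        obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
        var=guide_var)
    expr_adata = ad.AnnData(
        X=sparse.csr_matrix(counts),
        obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")))

    true_ids = []
    for i in range(n_cells):
        ids = [hgrna_ids[primary[i]]]
        if is_doublet[i]:
            ids.append(hgrna_ids[partner[i]])
        true_ids.append(",".join(ids))
    cell_truth = pd.DataFrame(
        {"true_hgrna_ids": true_ids,
         "is_doublet": is_doublet,
         "is_decoupled": is_decoupled,
         "is_escaping": is_escaping,
         "true_phase": phase},
        index=pd.Index(barcodes, name="barcode"))
    return guide_adata, expr_adata, cell_truth
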