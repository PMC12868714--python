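import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import build_screen
from hgscreen.assignment import assign_perturbations, detect_guides
from hgscreen.pseudobulk import (DEResult, PseudobulkTable, aggregate,
                                 de_test, estimate_dispersions,
                                 guide_concordance, size_factors)


def nb_pseudobulk(rng, n_target, n_ctrl, n_genes, disp, base_log_mean=4.5,
                  lfc=None, sf_sigma=0.2):
    """Directly simulated pseudobulk NB table with known effects."""
    base = np.exp(rng.normal(base_log_mean, 1.0, n_genes))
    lfc = np.zeros(n_genes) if lfc is None else lfc
    sf_true = np.exp(rng.normal(0, sf_sigma, n_target + n_ctrl))
    cond = (np.arange(n_target + n_ctrl) < n_target).astype(float)
    mu = np.outer(sf_true, base) * np.exp2(np.outer(cond, lfc))
    counts = rng.poisson(rng.gamma(1.0 / disp, mu * disp)) if disp > 0 \
        else rng.poisson(mu)
    idx = [f"T{i}" for i in range(n_target)] + [f"C{i}" for i in range(n_ctrl)]
    meta = pd.DataFrame(
        {"target_id": ["T"] * n_target + idx[n_target:],
         "guide_index": 1,
         "class": ["exon_deletion"] * n_target + ["intergenic"] * n_ctrl,
         "n_cells": 100}, index=pd.Index(idx, name="group"))
    pb = PseudobulkTable(
        pd.DataFrame(counts, index=meta.index,
                     columns=[f"g{j}" for j in range(n_genes)]), meta)
    return pb, sf_true


class TestAggregate:
    @pytest.fixture(scope="class")
    def screen(self):
        lib, truth, ga, expr, ct, markers = build_screen(
            n_exon=2, n_gene=1, n_intergenic=6, cells_per_guide=20, seed=400)
        asn = assign_perturbations(detect_guides(ga), lib)
        expr.layers["counts"] = expr.X.copy()
        return lib, expr, asn

    def test_group_rows_are_member_sums(self, screen):
        lib, expr, asn = screen
        pb = aggregate(expr, asn, lib, level="guide", min_cells=1)
        g = pb.counts.index[0]
        cells = asn.table.index[(asn.table["assigned_hgrna"] == g)
                                & (asn.table["status"] == "assigned")]
        expected = np.asarray(
            expr[expr.obs_names.isin(cells)].layers["counts"].sum(axis=0)
        ).ravel()
        assert np.array_equal(pb.counts.loc[g].to_numpy(), expected)

    def test_total_umis_conserved(self, screen):
        lib, expr, asn = screen
        pb = aggregate(expr, asn, lib, level="guide", min_cells=1)
        cells = asn.table.index[asn.table["status"] == "assigned"]
        total = expr[expr.obs_names.isin(cells)].layers["counts"].sum()
        assert pb.counts.to_numpy().sum() == total

    def test_target_level_merges_guides(self, screen):
        lib, expr, asn = screen
        by_guide = aggregate(expr, asn, lib, level="guide", min_cells=1)
        by_target = aggregate(expr, asn, lib, level="target", min_cells=1)
        t = lib.targets("exon_deletion")[0]
        guides = [g for g in by_guide.counts.index
                  if by_guide.meta.loc[g, "target_id"] == t]
        assert np.array_equal(by_target.counts.loc[t].to_numpy(),
                              by_guide.counts.loc[guides].sum().to_numpy())

    def test_min_cells_drops_underpopulated_group_with_warning(self, screen):
        lib, expr, asn = screen
        g = lib.hgrna_ids[0]
        cells_of_g = asn.table.index[asn.table["assigned_hgrna"] == g]
        mask = pd.Series(True, index=asn.table.index)
        mask[cells_of_g[10:]] = False          # leave g with 10 cells
        with pytest.warns(UserWarning, match="dropped"):
            pb = aggregate(expr, asn, lib, level="guide", min_cells=15,
                           cell_mask=mask)
        assert g not in pb.counts.index
        assert len(pb.counts) > 0

    def test_nothing_survives_is_an_error(self, screen):
        lib, expr, asn = screen
        with pytest.raises(ValueError, match="no pseudobulk groups"), \
                pytest.warns(UserWarning):
            aggregate(expr, asn, lib, level="guide", min_cells=10 ** 6)


class TestSizeFactors:
    def test_identical_groups_get_unit_factors(self):
        counts = pd.DataFrame([[10, 20, 30]] * 4,
                              index=list("abcd"), columns=list("xyz"))
        assert np.allclose(size_factors(counts), 1.0)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(1)
        row = rng.poisson(50, 100)
        counts = pd.DataFrame([row, 2 * row], index=["a", "b"])
        sf = size_factors(counts)
        assert np.isclose(sf["b"] / sf["a"], 2.0)

    def test_matches_direct_median_of_ratios(self):
        rng = np.random.default_rng(2)
        M = rng.negative_binomial(5, 0.1, size=(8, 120)).astype(float)
        counts = pd.DataFrame(M)
        sf = size_factors(counts)
        pos = (M > 0).all(axis=0)
        logg = np.log(M[:, pos])
        expected = np.exp(np.median(logg - logg.mean(axis=0), axis=1))
        assert np.allclose(sf.to_numpy(), expected)

    def test_no_common_positive_gene_falls_back(self):
        counts = pd.DataFrame([[5, 0], [0, 5]], columns=["x", "y"])
        with pytest.warns(UserWarning, match="positive"):
            sf = size_factors(counts)
        assert np.isfinite(sf).all()


class TestEstimateDispersions:
    def test_poisson_data_gives_near_zero_dispersion(self):
        rng = np.random.default_rng(3)
        pb, _ = nb_pseudobulk(rng, 0, 40, 300, disp=0.0)
        d = estimate_dispersions(pb)
        assert np.nanmedian(d) <= 0.05

    def test_nb_dispersion_recovered(self):
        rng = np.random.default_rng(4)
        pb, _ = nb_pseudobulk(rng, 0, 50, 400, disp=0.2)
        d = estimate_dispersions(pb)
        assert abs(np.nanmedian(d) - 0.2) <= 0.05

    def test_all_zero_gene_excluded(self):
        rng = np.random.default_rng(5)
        pb, _ = nb_pseudobulk(rng, 0, 10, 50, disp=0.1)
        pb.counts.iloc[:, 0] = 0
        d = estimate_dispersions(pb)
        assert np.isnan(d.iloc[0])


class TestDETest:
    def test_planted_lfc_recovered_and_flagged(self):
        rng = np.random.default_rng(6)
        n_genes = 600
        lfc = np.zeros(n_genes)
        planted = rng.choice(n_genes, 60, replace=False)
        lfc[planted] = 1.0
        pb, _ = nb_pseudobulk(rng, 3, 40, n_genes, disp=0.005, lfc=lfc)
        res = de_test(pb, [f"T{i}" for i in range(3)],
                      [f"C{i}" for i in range(40)])
        est = res.table["log2fc"].to_numpy()[planted]
        assert abs(np.nanmedian(est) - 1.0) <= 0.25
        hi = res.table["mean_norm"].to_numpy()[planted] >= 50
        assert res.table["is_deg"].to_numpy()[planted][hi].mean() >= 0.8

    def test_null_genes_controlled(self):
        rng = np.random.default_rng(7)
        pb, _ = nb_pseudobulk(rng, 3, 40, 500, disp=0.01)
        res = de_test(pb, [f"T{i}" for i in range(3)],
                      [f"C{i}" for i in range(40)])
        padj = res.table["padj"].dropna()
        assert (padj < 0.05).mean() <= 0.1
        assert not res.table["is_deg"].any() or \
            res.table["is_deg"].mean() < 0.02

    def test_identical_conditions_give_null_result(self):
        rng = np.random.default_rng(8)
        base = rng.poisson(200, 50)
        counts = pd.DataFrame([base] * 6,
                              index=[f"T{i}" for i in range(3)]
                              + [f"C{i}" for i in range(3)])
        meta = pd.DataFrame({"target_id": "x", "guide_index": 1,
                             "class": "exon_deletion", "n_cells": 10},
                            index=counts.index)
        pb = PseudobulkTable(counts, meta)
        res = de_test(pb, ["T0", "T1", "T2"], ["C0", "C1", "C2"])
        tested = res.table.dropna(subset=["p"])
        assert np.allclose(tested["log2fc"], 0.0, atol=1e-6)
        assert (tested["p"] > 0.999).all()

    def test_padj_never_below_p(self):
        rng = np.random.default_rng(9)
        pb, _ = nb_pseudobulk(rng, 3, 10, 200, disp=0.05)
        res = de_test(pb, [f"T{i}" for i in range(3)],
                      [f"C{i}" for i in range(10)])
        t = res.table.dropna(subset=["p"])
        assert (t["padj"] >= t["p"] - 1e-12).all()

    def test_single_target_group_still_runs(self):
        rng = np.random.default_rng(10)
        pb, _ = nb_pseudobulk(rng, 1, 10, 100, disp=0.05)
        res = de_test(pb, ["T0"], [f"C{i}" for i in range(10)])
        assert res.table["p"].notna().any()

    def test_fewer_than_two_controls_rejected(self):
        rng = np.random.default_rng(11)
        pb, _ = nb_pseudobulk(rng, 3, 2, 50, disp=0.05)
        with pytest.raises(ValueError, match="control"):
            de_test(pb, ["T0"], ["C0"])


def bh_oracle(p):
    """Independent BH step-up."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestBenjaminiHochberg:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=60))
    def test_statsmodels_bh_matches_step_up_oracle(self, pvals):
        from statsmodels.stats.multitest import multipletests
        adj = multipletests(pvals, method="fdr_bh")[1]
        assert np.allclose(adj, bh_oracle(pvals), atol=1e-12)

    def test_sorted_padj_monotone(self):
        rng = np.random.default_rng(12)
        p = rng.uniform(size=100)
        adj = bh_oracle(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestGuideConcordance:
    def _mk(self, lfc, genes):
        tab = pd.DataFrame({"log2fc": lfc, "se": 0.1, "wald_stat": 0.0,
                            "p": 1.0, "padj": 1.0, "is_deg": False},
                           index=genes)
        return DEResult(tab)

    def test_identical_results_give_r_one(self):
        genes = [f"g{i}" for i in range(30)]
        lfc = np.random.default_rng(13).normal(size=30)
        res = {"a": self._mk(lfc, genes), "b": self._mk(lfc, genes)}
        assert guide_concordance(res, genes) == pytest.approx(1.0)

    def test_sign_flip_gives_minus_one(self):
        genes = [f"g{i}" for i in range(30)]
        lfc = np.random.default_rng(14).normal(size=30)
        res = {"a": self._mk(lfc, genes), "b": self._mk(-lfc, genes)}
        assert guide_concordance(res, genes) == pytest.approx(-1.0)

    def test_three_guides_mean_of_pairwise(self):
        rng = np.random.default_rng(15)
        genes = [f"g{i}" for i in range(40)]
        vecs = {k: rng.normal(size=40) for k in "abc"}
        res = {k: self._mk(v, genes) for k, v in vecs.items()}
        expected = np.mean([np.corrcoef(vecs[a], vecs[b])[0, 1]
                            for a, b in itertools.combinations("abc", 2)])
        assert guide_concordance(res, genes) == pytest.approx(expected)

    def test_single_guide_undefined(self):
        genes = ["g0", "g1", "g2"]
        res = {"a": self._mk([1.0, 2.0, 3.0], genes)}
        assert np.isnan(guide_concordance(res, genes))


class TestAgainstPyDESeq2:
    def test_log2fc_agrees_with_reference_implementation(self):
        """Cross-check the NB Wald engine against an independent DE
        framework on one small table."""
        import anndata as ad
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        rng = np.random.default_rng(16)
        n_genes = 150
        lfc = np.zeros(n_genes)
        lfc[:15] = rng.choice([-1.5, 1.5], 15)
        pb, _ = nb_pseudobulk(rng, 3, 12, n_genes, disp=0.02, lfc=lfc)
        ours = de_test(pb, [f"T{i}" for i in range(3)],
                       [f"C{i}" for i in range(12)], min_mean_norm=0.0)

        counts = pb.counts.astype(int)
        meta = pd.DataFrame(
            {"condition": ["T"] * 3 + ["C"] * 12}, index=counts.index)
        dds = DeseqDataSet(adata=ad.AnnData(X=counts.values, obs=meta,
                                            var=pd.DataFrame(
                                                index=counts.columns)),
                           design="~condition", quiet=True)
        dds.deseq2()
        stats = DeseqStats(dds, contrast=["condition", "T", "C"], quiet=True)
        stats.summary()
        ref = stats.results_df["log2FoldChange"]

        both = ours.table["log2fc"].notna() & ref.notna()
        r = np.corrcoef(ours.table["log2fc"][both], ref[both])[0, 1]
        assert r > 0.98
        planted = np.abs(lfc) > 0
        assert np.allclose(ours.table["log2fc"][planted], ref[planted],
                           atol=0.3)
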