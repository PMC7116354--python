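import numpy as np
import pytest

import gwasprio as gp
from gwasprio import mapping, simulate
from gwasprio.io import GeneSetCollection


def small_scenario(**kw):
    kw.setdefault("causal_specs", gp.example_causal_loci(5))
    kw.setdefault("n_null_snps", 2000)
    kw.setdefault("snps_per_region", 10)
    kw.setdefault("n_replicates", 1)
    return gp.SimScenario(**kw)


class TestCausalZ:
    def test_null_odds_ratio_gives_standard_normal_z(self):
        spec = gp.CausalSpec("1", 100, 0.3, 1.0, "G")
        rng = np.random.default_rng(11)
        zs = np.array([gp.simulate_causal_z(spec, 1500, 1500, rng)
                       for _ in range(2000)])
        assert abs(zs.mean()) < 0.07
        assert 0.9 < zs.var() < 1.1

    def test_mean_z_matches_analytic_noncentrality(self):
        spec = gp.CausalSpec("1", 100, 0.3, 1.5, "G")
        rng = np.random.default_rng(12)
        zs = np.array([gp.simulate_causal_z(spec, 1500, 1500, rng)
                       for _ in range(2000)])
        want = simulate.analytic_mean_z(spec, 1500, 1500)
        assert abs(zs.mean() - want) < 3 * zs.std(ddof=1) / np.sqrt(len(zs))

    def test_case_frequency_follows_odds_ratio(self):
        spec = gp.CausalSpec("1", 100, 0.2, 1.4, "G")
        p0, r = 0.2, 1.4
        assert spec.case_maf == pytest.approx(r * p0 / (1 - p0 + r * p0))

    def test_tiny_counts_warn(self):
        spec = gp.CausalSpec("1", 100, 0.01, 1.2, "G")
        with pytest.warns(UserWarning, match="allele count"):
            gp.simulate_causal_z(spec, 100, 100, np.random.default_rng(0))


class TestSnpLayout:
    def test_gene_intervals_are_disjoint_and_cover_their_snps(self):
        snp_map = gp.build_snp_map(small_scenario())
        t = snp_map.table
        by_chrom = {}
        for gene, chrom, s, e in snp_map.coords.table.itertuples(index=False):
            by_chrom.setdefault(chrom, []).append((s, e, gene))
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            for (s1, e1, _), (s2, e2, _) in zip(ivs, ivs[1:]):
                assert e1 <= s2  # disjoint
        # positional mapping at flank 0 recovers exactly the host gene
        gs = GeneSetCollection([(g, frozenset({g}))
                                for g in snp_map.causal_genes + snp_map.null_genes])
        annot = mapping.map_snps_to_pathways(snp_map.base_stats(),
                                             snp_map.coords, gs, 0)
        dense = annot.V.toarray()
        col = {n: j for j, n in enumerate(annot.annotation_names)}
        assert np.all(dense.sum(axis=1) == 1)
        for j, gene in enumerate(t["gene"]):
            assert dense[j, col[gene]] == 1

    def test_null_snps_outside_causal_windows(self):
        scen = small_scenario()
        snp_map = gp.build_snp_map(scen)
        t = snp_map.table
        for spec in scen.causal_specs:
            same = t["chrom"] == spec.chrom
            d = np.abs(t["pos"][same] - spec.pos)
            near = d <= scen.region_halfwidth_bp
            assert np.all(t["in_region"][same][near])


class TestReplicate:
    def test_null_only_scenario_gives_uniform_p(self):
        scen = gp.SimScenario(causal_specs=[], n_null_snps=20_000)
        stats, truth = gp.simulate_replicate(scen, np.random.default_rng(3))
        assert truth.is_null.all()
        for t in (0.5, 0.1, 0.01):
            frac = (stats.p <= t).mean()
            se = np.sqrt(t * (1 - t) / stats.n_snps)
            assert abs(frac - t) < 4 * se

    def test_causal_snp_z_equals_locus_z_and_ld_decays(self):
        scen = small_scenario(ld_decay_bp=50_000)
        snp_map = gp.build_snp_map(scen)
        reps = [gp.simulate_replicate(scen, np.random.default_rng(s), snp_map)[0]
                for s in range(200)]
        Z = np.array([r.z for r in reps])
        t = snp_map.table
        li = t["locus"].to_numpy()
        causal = t["is_causal"].to_numpy()
        zc = Z[:, (li == 0) & causal].ravel()
        region0 = np.flatnonzero((li == 0) & ~causal)
        pos = t["pos"].to_numpy()
        cpos = pos[(li == 0) & causal][0]
        # empirical correlation with the causal Z matches exp(-d/decay)
        for j in (region0[len(region0) // 2], region0[0]):
            want = np.exp(-abs(pos[j] - cpos) / scen.ld_decay_bp)
            got = np.corrcoef(zc, Z[:, j])[0, 1]
            assert got == pytest.approx(want, abs=0.25)

    def test_p_is_one_sided_tail_of_z(self):
        from scipy.stats import norm
        scen = small_scenario()
        stats, _ = gp.simulate_replicate(scen, np.random.default_rng(5))
        assert np.allclose(stats.p, np.clip(norm.sf(stats.z), 1e-300, 1 - 1e-16))


class TestSyntheticPathways:
    def _genes(self):
        return [f"C{i}" for i in range(25)], [f"N{i}" for i in range(500)]

    def test_true_pathways_hold_exactly_tg_causal_genes(self):
        causal, null = self._genes()
        cfg = gp.SyntheticPathwayConfig(30, 10, 100, 20)
        gs = gp.make_synthetic_pathways(cfg, causal, null,
                                        np.random.default_rng(0))
        causal_set = set(causal)
        counts = [len(g & causal_set) for _, g in gs]
        assert counts[:30] == [10] * 30
        assert all(c == 0 for c in counts[30:])
        assert all(len(g) == 20 for _, g in gs)

    def test_tp_zero_means_no_causal_gene_anywhere(self):
        causal, null = self._genes()
        cfg = gp.SyntheticPathwayConfig(0, 0, 40, 15)
        gs = gp.make_synthetic_pathways(cfg, causal, null,
                                        np.random.default_rng(1))
        assert all(not (g & set(causal)) for _, g in gs)

    @pytest.mark.parametrize("tp,tg", [(40, 5), (35, 8), (30, 10)])
    def test_connectivity_configs_feasible_with_25_causal_genes(self, tp, tg):
        causal, null = self._genes()
        cfg = gp.SyntheticPathwayConfig(tp, tg, max(tp, 50), 20)
        gs = gp.make_synthetic_pathways(cfg, causal, null,
                                        np.random.default_rng(2))
        assert len(gs) == max(tp, 50)

    def test_infeasible_configs_rejected(self):
        causal, null = self._genes()
        with pytest.raises(ValueError):
            gp.make_synthetic_pathways(gp.SyntheticPathwayConfig(5, 30, 10, 40),
                                       causal, null, np.random.default_rng(0))
        with pytest.raises(ValueError):
            gp.SyntheticPathwayConfig(50, 5, 10, 20)


class TestEvaluate:
    def _truth(self, n_null=100, n_causal=4):
        delta = np.r_[np.ones(n_causal, bool), np.zeros(n_null, bool)]
        return simulate.TruthLabels(delta, delta.copy(), np.array(
            [f"g{i}" for i in range(n_null + n_causal)], object))

    def test_no_rejections_means_zero_type1(self):
        truth = self._truth()
        rep = gp.evaluate(np.ones((3, 104)), truth)
        assert np.all(rep.type1 == 0)

    def test_uniform_null_calibration(self):
        rng = np.random.default_rng(8)
        truth = simulate.TruthLabels(np.zeros(20_000, bool),
                                     np.zeros(20_000, bool),
                                     np.array(["g"] * 20_000, object))
        P = rng.random((50, 20_000))
        rep = gp.evaluate(P, truth, levels=(0.01,))
        assert 0.008 <= rep.type1[0] <= 0.012

    def test_certain_hits_give_full_power(self):
        truth = self._truth()
        P = np.ones((2, 104))
        P[:, :4] = 1e-12
        rep = gp.evaluate(P, truth, levels=(1e-7,))
        assert rep.power[0] == 1.0
        assert np.all(rep.per_snp_power == 1.0)

    def test_no_null_snps_is_an_error(self):
        truth = simulate.TruthLabels(np.ones(5, bool), np.ones(5, bool),
                                     np.array(["g"] * 5, object))
        with pytest.raises(ValueError):
            gp.evaluate(np.ones((1, 5)), truth)
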