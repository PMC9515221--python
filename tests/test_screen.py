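import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tribescreen import screen
from tribescreen.errors import ContrastError, DesignError, NormalizationError
from tribescreen.simulate import ScreenSimConfig, simulate_screen

# edgeR::calcNormFactors(method="TMM") reference factors for the crafted
# composition-bias instance below (guides 0-3 inflated 6x in S_2, two zero
# guides in S_3) — the independent oracle for the doubly-trimmed,
# precision-weighted TMM formula.
TMM_INSTANCE = pd.DataFrame(
    {
        "S_1": [224, 1559, 1326, 905, 894, 1724, 217, 1409, 442, 233,
                1076, 1952, 1484, 1534, 1449, 1582, 1050, 299, 1687, 928],
        "S_2": [2280, 15900, 13524, 9228, 1519, 2930, 368, 2395, 751, 396,
                1829, 3318, 2522, 2607, 2463, 2689, 1785, 508, 2867, 1577],
        "S_3": [201, 1403, 1193, 814, 804, 1551, 195, 1268, 397, 209,
                0, 0, 1335, 1380, 1304, 1423, 945, 269, 1518, 835],
    },
    index=[f"g{i:02d}" for i in range(20)],
)
TMM_EXPECTED = np.array([1.181568280976, 0.617575205426, 1.370412541903])


class TestTMM:
    def test_identical_samples_get_unit_factors(self):
        counts = pd.DataFrame({"A_1": [10, 200, 3000], "A_2": [10, 200, 3000]})
        assert np.allclose(screen.tmm_factors(counts), 1.0)

    def test_library_size_scaling_absorbs_global_doubling(self):
        a = np.array([10, 200, 3000, 50])
        counts = pd.DataFrame({"A_1": a, "A_2": 2 * a})
        assert np.allclose(screen.tmm_factors(counts), 1.0)

    def test_matches_edger_reference_on_composition_bias_instance(self):
        factors = screen.tmm_factors(TMM_INSTANCE)
        assert np.max(np.abs(factors.to_numpy() - TMM_EXPECTED)) < 1e-6

    def test_factors_have_geometric_mean_one(self):
        factors = screen.tmm_factors(TMM_INSTANCE)
        assert np.exp(np.mean(np.log(factors))) == pytest.approx(1.0, abs=1e-12)

    def test_no_shared_nonzero_guides_raises(self):
        counts = pd.DataFrame({"A_1": [5, 0, 7, 0], "A_2": [0, 3, 0, 2],
                               "A_3": [5, 0, 6, 0]})
        with pytest.raises(NormalizationError):
            screen.tmm_factors(counts)


class TestGuideLog2FC:
    def _counts(self, a, b):
        return pd.DataFrame({"DMSO_1": a, "DRUG_1": b})

    def test_equal_abundance_gives_zero(self):
        counts = self._counts([100, 900], [100, 900])
        factors = screen.tmm_factors(counts)
        res = screen.guide_log2fc(counts, factors, ("DRUG", "DMSO"))
        assert np.allclose(res["log2fc"], 0.0)

    def test_doubled_numerator_composition(self):
        # guide 0 doubles under drug while the large filler guide pins the
        # library scale; in the CPM >> pseudocount regime lfc ~ 1
        counts = pd.DataFrame({"DMSO_1": [1000, 1_000_000], "DRUG_1": [2000, 1_000_000]})
        factors = pd.Series([1.0, 1.0], index=counts.columns)
        res = screen.guide_log2fc(counts, factors, ("DRUG", "DMSO"))
        assert res["log2fc"].iloc[0] == pytest.approx(1.0, abs=0.01)

    def test_zero_denominator_uses_pseudocount(self):
        # 100 CPM in the numerator, zero in the denominator, pseudocount 0.5
        lfc = np.log2((100 + 0.5) / (0 + 0.5))
        assert lfc == pytest.approx(7.651, abs=1e-3)
        counts = pd.DataFrame({"DMSO_1": [0, 999_900], "DRUG_1": [100, 999_900]})
        factors = pd.Series([1.0, 1.0], index=counts.columns)
        res = screen.guide_log2fc(counts, factors, ("DRUG", "DMSO"))
        assert res["log2fc"].iloc[0] == pytest.approx(lfc, abs=0.01)

    def test_unknown_condition_raises(self):
        counts = self._counts([10], [10])
        factors = screen.tmm_factors(counts)
        with pytest.raises(ContrastError):
            screen.guide_log2fc(counts, factors, ("NOPE", "DMSO"))


def _guide_stats(lfcs):
    return pd.DataFrame({"guide_id": [f"g{i}" for i in range(len(lfcs))],
                         "log2fc": lfcs})


class TestCameraRankTest:
    def test_vif_formula(self):
        # m=4 guides, rho=0.01 -> variance inflation 1.03: z shrinks by sqrt(1.03)
        lfcs = list(np.linspace(-1, 1, 40))
        stats = _guide_stats(lfcs)
        grouping = {"G": ["g36", "g37", "g38", "g39"]}
        z0 = screen.camera_rank_test(stats, grouping, inter_guide_corr=0.0)["z"].iloc[0]
        z1 = screen.camera_rank_test(stats, grouping, inter_guide_corr=0.01)["z"].iloc[0]
        assert z0 / z1 == pytest.approx(np.sqrt(1.03), rel=1e-12)

    def test_matches_wilcoxon_normal_approximation(self):
        # spec'd instance: 10 guides, one gene's 3 guides at the top ranks
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(6, 13))
            m = int(rng.integers(1, n - 1))
            lfcs = rng.normal(size=n)  # continuous -> no ties
            stats = _guide_stats(lfcs)
            guides = [f"g{i}" for i in range(m)]
            res = screen.camera_rank_test(stats, {"G": guides}, inter_guide_corr=0.0)
            ref = sps.ranksums(lfcs[:m], lfcs[m:])
            assert res["z"].iloc[0] == pytest.approx(ref.statistic, abs=1e-10)
            assert res["p"].iloc[0] == pytest.approx(ref.pvalue, abs=1e-10)

    def test_top_ranks_instance(self):
        lfcs = np.arange(10, dtype=float)
        stats = _guide_stats(lfcs)
        res = screen.camera_rank_test(stats, {"G": ["g7", "g8", "g9"]}, inter_guide_corr=0.0)
        ref = sps.ranksums(lfcs[7:], lfcs[:7])
        assert res["p"].iloc[0] == pytest.approx(ref.pvalue, abs=1e-10)

    def test_symmetric_gene_is_null(self):
        lfcs = list(np.linspace(-1, 1, 21))
        stats = _guide_stats(lfcs)
        res = screen.camera_rank_test(stats, {"G": ["g0", "g10", "g20"]})
        assert abs(res["z"].iloc[0]) < 1e-12
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_tied_values_use_midranks(self):
        lfcs = [0.0, 0.0, 0.0, 1.0, 1.0, 2.0]
        stats = _guide_stats(lfcs)
        res = screen.camera_rank_test(stats, {"G": ["g3", "g4"]}, inter_guide_corr=0.0)
        # midranks: ties at 0 -> 2, ties at 1 -> 4.5; T = 9
        n, m = 6, 2
        tie_term = (3**3 - 3) + (2**3 - 2)
        var = m * (n - m) / 12 * ((n + 1) - tie_term / (n * (n - 1)))
        z = (9 - m * (n + 1) / 2) / np.sqrt(var)
        assert res["z"].iloc[0] == pytest.approx(z, rel=1e-12)

    def test_degenerate_grouping_raises(self):
        stats = _guide_stats([1.0, 2.0])
        with pytest.raises(ValueError):
            screen.camera_rank_test(stats, {"G": ["g0", "g1"]})


class TestBHAdjust:
    def test_step_up_rule(self):
        assert np.allclose(screen.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_boundaries(self):
        assert np.allclose(screen.bh_adjust([1.0, 1.0]), 1.0)
        assert screen.bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            screen.bh_adjust([0.5, 1.5])


class TestHitCalling:
    def _results(self, rows):
        df = pd.DataFrame(rows, columns=["gene", "lfc", "padj", "n_concordant"])
        df["n_guides"] = 4
        df["z"] = 0.0
        df["p"] = df["padj"]
        df["class"] = "none"
        return df

    def test_essential_rule(self):
        res = self._results([("A", -3.0, 0.01, 4), ("B", -1.5, 0.01, 4)])
        assert screen.call_essential(res) == {"A"}

    def test_resistance_needs_three_concordant(self):
        # (+3,+3,+3,+0.5) -> 3 concordant -> resistance; (+3,+3,-1,-1) -> none
        res = self._results([("A", 3.0, 0.01, 3), ("B", 1.0, 0.01, 2)])
        called = screen.call_hits(res, essential=set())
        assert called.set_index("gene")["class"].to_dict() == {"A": "resistance", "B": "none"}

    def test_essential_gene_excluded_from_hits(self):
        res = self._results([("A", -4.0, 0.001, 4)])
        called = screen.call_hits(res, essential={"A"})
        assert called["class"].iloc[0] == "essential"

    def test_invariant_to_guide_and_sample_order(self, small_screen):
        _cfg, manifest, counts, _truth = small_screen
        rng = np.random.default_rng(3)

        def run(man, cnt):
            factors = screen.tmm_factors(cnt)
            stats = screen.guide_log2fc(cnt, factors, ("DRUG", "DMSO"))
            res = screen.gene_results(stats, man)
            return screen.call_hits(res, set()).sort_values("gene").reset_index(drop=True)

        base = run(manifest, counts)
        perm = run(manifest.sample(frac=1, random_state=7),
                   counts.iloc[rng.permutation(len(counts))][list(reversed(counts.columns))])
        pd.testing.assert_frame_equal(base, perm)


class TestValidationLibrary:
    def test_published_design_arithmetic(self):
        """316 + 89 hit genes x 4 guides + 200 + 200 controls = 2020 over 405 genes."""
        cfg = ScreenSimConfig(n_genes=405, n_nontargeting=200, n_safe_harbor=200, seed=0,
                              frac_essential=0, frac_sensitizer=0, frac_resistance=0)
        manifest, _counts, _truth = simulate_screen(cfg)
        genes = manifest.loc[manifest["class"] == "targeting", "gene"].unique()
        hits = list(genes[:316]) + list(genes[316:405])
        lib = screen.design_validation_library(hits, manifest, seed=1)
        assert len(lib) == 2020
        assert lib.loc[lib["class"] == "targeting", "gene"].nunique() == 405
        assert (lib["class"] == "non-targeting").sum() == 200
        assert (lib["class"] == "safe-harbor").sum() == 200

    def test_empty_hit_list_gives_controls_only(self, small_screen):
        _cfg, manifest, _counts, _truth = small_screen
        lib = screen.design_validation_library([], manifest, n_nontargeting=50,
                                               n_safe_harbor=50, seed=2)
        assert len(lib) == 100
        assert set(lib["class"]) == {"non-targeting", "safe-harbor"}

    def test_missing_hit_gene_raises(self, small_screen):
        _cfg, manifest, _counts, _truth = small_screen
        with pytest.raises(DesignError, match="NOT_A_GENE"):
            screen.design_validation_library(["NOT_A_GENE"], manifest)

    def test_deterministic_under_seed(self, small_screen):
        _cfg, manifest, _counts, _truth = small_screen
        a = screen.design_validation_library([], manifest, 50, 50, seed=9)
        b = screen.design_validation_library([], manifest, 50, 50, seed=9)
        pd.testing.assert_frame_equal(a, b)


def screen_gene_table(manifest, counts, contrast):
    factors = screen.tmm_factors(counts)
    stats = screen.guide_log2fc(counts, factors, contrast)
    return screen.gene_results(stats, manifest)


def test_planted_classes_recovered(small_screen):
    """The full caller recovers planted essential/sensitizer/resistance genes."""
    _cfg, manifest, counts, truth = small_screen
    res_t0 = screen_gene_table(manifest, counts, ("DMSO+DRUG", "T0"))
    essential = screen.call_essential(res_t0)
    res = screen_gene_table(manifest, counts, ("DRUG", "DMSO"))
    called = screen.call_hits(res, essential)
    for cls in ("sensitizer", "resistance"):
        planted = truth.genes_of(cls)
        found = set(called.loc[called["class"] == cls, "gene"])
        assert len(found & planted) / len(planted) >= 0.8
        assert len(found - planted) <= 0.1 * max(len(found), 1)
    planted_ess = truth.genes_of("essential")
    assert len(essential & planted_ess) / len(planted_ess) >= 0.8
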