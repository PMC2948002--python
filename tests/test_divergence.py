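from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecocline import divergence as dv
from ecocline import morphometrics as mm
from ecocline import synthetic_data as sd

from conftest import make_sites, make_two_region_dataset


def enumerate_ranksum_p(x, y):
    """Oracle: exact two-sided p by enumerating all rank assignments."""
    pooled = np.concatenate([x, y])
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    nx = len(x)
    w_obs = ranks[:nx].sum()
    mu = nx * (len(pooled) + 1) / 2
    ws = [sum(c) for c in combinations(ranks, nx)]
    extreme = sum(abs(w - mu) >= abs(w_obs - mu) - 1e-12 for w in ws)
    return extreme / len(ws)


class TestWilcoxonRankSum:
    def test_exact_small_example(self):
        # [DERIVED] all C(6,3)=20 assignments -> two-sided p = 2/20 = 0.1
        x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        assert enumerate_ranksum_p(x, y) == pytest.approx(0.1)
        res = dv.wilcoxon_rank_sum(x, y)
        assert res.method == "exact"
        assert res.p_two_sided == pytest.approx(0.1)
        assert res.W == 6.0

    def test_identical_multisets(self):
        x = [3.0, 1.0, 2.0]
        res = dv.wilcoxon_rank_sum(x, x)
        assert res.p_two_sided == pytest.approx(1.0)

    def test_exact_matches_enumeration_random(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = rng.normal(size=4)
            y = rng.normal(size=5)
            res = dv.wilcoxon_rank_sum(x, y, method="exact")
            assert res.p_two_sided == pytest.approx(enumerate_ranksum_p(x, y), abs=1e-12)

    def test_exact_vs_approx_agreement(self):
        # [DERIVED] untied n=8 vs 8: typical agreement within 0.01 (the
        # continuity-corrected normal can deviate by up to ~0.011 mid-range)
        rng = np.random.default_rng(1)
        diffs = []
        for _ in range(50):
            a = rng.normal(size=8)
            b = rng.normal(0.5, 1.0, size=8)
            diffs.append(
                abs(
                    dv.wilcoxon_rank_sum(a, b, method="exact").p_two_sided
                    - dv.wilcoxon_rank_sum(a, b, method="approx").p_two_sided
                )
            )
        assert max(diffs) < 0.012
        assert np.mean(np.asarray(diffs) <= 0.01) > 0.7

    def test_ties_use_approx(self):
        res = dv.wilcoxon_rank_sum([1.0, 2.0, 2.0], [2.0, 3.0, 4.0])
        assert res.method == "approx"

    def test_empty_group(self):
        with pytest.raises(ValueError, match="nonempty"):
            dv.wilcoxon_rank_sum([], [1.0])

    @given(
        st.lists(st.floats(-100, 100), min_size=2, max_size=12),
        st.lists(st.floats(-100, 100), min_size=2, max_size=12),
    )
    @settings(max_examples=60, deadline=None)
    def test_symmetry_property(self, x, y):
        a = dv.wilcoxon_rank_sum(x, y)
        b = dv.wilcoxon_rank_sum(y, x)
        assert a.p_two_sided == pytest.approx(b.p_two_sided, abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=9), rng.normal(size=7)
        p0 = dv.wilcoxon_rank_sum(x, y).p_two_sided
        p1 = dv.wilcoxon_rank_sum(np.exp(x), np.exp(y)).p_two_sided
        assert p0 == pytest.approx(p1, abs=1e-12)


class TestDunnSidak:
    def test_paper_constant(self):
        # [PAPER] alpha' = 1 - (1 - 0.05)^(1/6) = 0.0085 (4 dp)
        assert round(dv.dunn_sidak(0.05, 6), 4) == 0.0085

    def test_identity_at_m1(self):
        assert dv.dunn_sidak(0.37, 1) == pytest.approx(0.37)

    def test_m2_value(self):
        # [DERIVED] direct formula evaluation
        assert dv.dunn_sidak(0.05, 2) == pytest.approx(1 - (1 - 0.05) ** 0.5, abs=1e-12)
        assert round(dv.dunn_sidak(0.05, 2), 5) == 0.02532

    @given(st.floats(0.001, 0.5), st.integers(1, 50))
    @settings(max_examples=100, deadline=None)
    def test_decreasing_in_m_and_bounded(self, alpha, m):
        a_m = dv.dunn_sidak(alpha, m)
        assert a_m <= alpha + 1e-15
        if m > 1:
            assert a_m < dv.dunn_sidak(alpha, m - 1)

    def test_validation(self):
        with pytest.raises(ValueError):
            dv.dunn_sidak(0.05, 0)
        with pytest.raises(ValueError):
            dv.dunn_sidak(1.5, 3)


def prepared_dataset(model, seed, **kw):
    table = make_two_region_dataset(model, seed, **kw)
    pca, _ = mm.pooled_pca(table, list(model.traits), gate="skip")
    return mm.add_derived_traits(table, pca)


TESTED_TRAITS = ["PC1", "log_tarsus", "log_wing", "log_tail", "wing_sc", "tail_sc"]


class TestHabitatDivergence:
    def test_divergent_region_detected(self, trait_model):
        aug = prepared_dataset(trait_model, seed=0)
        results = dv.habitat_divergence(aug, "Central", TESTED_TRAITS)
        frame = dv.results_frame(results)
        assert len(frame) == 6
        assert frame["alpha_corrected"].iloc[0] == pytest.approx(
            dv.dunn_sidak(0.05, 6)
        )
        assert frame.loc[frame["trait"] == "PC1", "significant"].item()

    def test_homogeneous_region_fwer(self, flat_model):
        # [DERIVED] identical habitat distributions: family-wise error <= alpha
        n_seeds, families_hit = 300, 0
        for seed in range(n_seeds):
            table = make_two_region_dataset(
                flat_model, seed=seed, west_covers=(50.0, 50.0), n_west=15
            )
            pca, _ = mm.pooled_pca(table, list(flat_model.traits), gate="skip")
            aug = mm.add_derived_traits(table, pca)
            res = dv.habitat_divergence(aug, "West", TESTED_TRAITS)
            families_hit += any(r.significant for r in res)
        rate = families_hit / n_seeds
        assert rate <= 0.05 + 1.96 * np.sqrt(0.05 * 0.95 / n_seeds)

    def test_montane_rows_rejected(self, trait_model):
        aug = prepared_dataset(trait_model, seed=1)
        aug.loc[aug.index[:3], "habitat"] = "montane"
        with pytest.raises(ValueError, match="montane"):
            dv.habitat_divergence(aug, "Central", ["PC1"])

    def test_missing_habitat_errors(self, trait_model):
        aug = prepared_dataset(trait_model, seed=2)
        only_forest = aug[aug["habitat"] == "forest"]
        with pytest.raises(ValueError, match="both habitats"):
            dv.habitat_divergence(only_forest, "Central", ["PC1"])


class TestEraDivergence:
    def build(self, model, seed, era_shift=0.0, west_shift_contemp=0.0):
        sites_c = make_sites("Central", 80.0, 30.0)
        sites_w = make_sites("West", 80.0, 30.0)
        shifted = sd.TraitGenModel(
            traits=model.traits,
            log_intercepts=tuple(
                np.asarray(model.log_intercepts) + west_shift_contemp
            ),
            cover_slopes=model.cover_slopes,
            covariance=model.covariance.copy(),
        )
        contemp = pd.concat(
            [
                sd.generate_individuals(sites_c, model, 15, seed=seed),
                sd.generate_individuals(sites_w, shifted, 15, seed=seed + 1),
            ],
            ignore_index=True,
        )
        hist = pd.concat(
            [
                sd.generate_historical_cohort(
                    model, era_shift, 1, seed=seed + 2,
                    sites=sites_c[sites_c.habitat == "forest"], n_per_site=8,
                ),
                sd.generate_historical_cohort(
                    model, era_shift, 1, seed=seed + 3,
                    sites=sites_w[sites_w.habitat == "forest"], n_per_site=8,
                ),
            ],
            ignore_index=True,
        )
        pca_c, _ = mm.pooled_pca(contemp, list(model.traits), gate="skip")
        pca_h, _ = mm.pooled_pca(hist, list(model.traits), gate="skip", scope="historical")
        return mm.add_derived_traits(contemp, pca_c), mm.add_derived_traits(hist, pca_h)

    def test_null_rate_nominal(self, flat_model):
        # [DERIVED] no regional shift: within-era tests fire at ~alpha
        hits = total = 0
        for seed in range(0, 300, 4):
            contemp, hist = self.build(flat_model, seed)
            res = dv.era_divergence(contemp, hist, ["log_wing"], sc_gate=False)
            hits += sum(r.significant for r in res)
            total += len(res)
        rate = hits / total
        assert rate <= 0.05 + 1.96 * np.sqrt(0.05 * 0.95 / total)

    def test_contemporary_only_shift_recovered(self, flat_model):
        # [DERIVED] West shifted only in the contemporary era: contemporary
        # divergence exceeds historical divergence in nearly all seeds
        wins = 0
        n_seeds = 30
        for seed in range(n_seeds):
            contemp, hist = self.build(
                flat_model, seed * 10, west_shift_contemp=0.08
            )
            res = dv.era_divergence(contemp, hist, ["log_wing"], sc_gate=False)
            by_era = {r.scope: abs(r.means[0] - r.means[1]) for r in res}
            wins += by_era["contemporary"] > by_era["historical"]
        assert wins >= 0.95 * n_seeds

    def test_single_region_era_errors(self, trait_model):
        contemp, hist = self.build(trait_model, 0)
        with pytest.raises(ValueError, match="single region"):
            dv.era_divergence(contemp, hist[hist["region"] == "Central"], ["log_wing"])

    def test_historical_sc_gate_omits_nonsignificant(self, flat_model):
        # decorrelate wing from tarsus in the historical sample -> _sc omitted
        contemp, hist = self.build(flat_model, 3)
        rng = np.random.default_rng(0)
        hist = hist.copy()
        hist["wing"] = np.exp(rng.normal(4.1, 0.04, len(hist)))
        hist["wing_sc"] = np.log(hist["wing"])  # placeholder column
        res = dv.era_divergence(contemp, hist, ["log_wing", "wing_sc"])
        eras = {(r.scope, r.trait) for r in res}
        assert ("contemporary", "wing_sc") in eras
        assert ("historical", "wing_sc") not in eras


class TestFstSummary:
    def test_paper_two_values(self):
        # [PAPER] West Africa: mean 0.058 +/- 0.005 SE, range 0.053-0.063
        mat = pd.DataFrame(
            [[0.0, 0.053, 0.063], [0.053, 0.0, 0.01], [0.063, 0.01, 0.0]],
            index=["f1", "f2", "e1"], columns=["f1", "f2", "e1"],
        )
        # f1-f2 is within-habitat; f1-e1 and f2-e1 are between
        mat.loc["f1", "f2"] = mat.loc["f2", "f1"] = 0.02
        mat.loc["f1", "e1"] = mat.loc["e1", "f1"] = 0.053
        mat.loc["f2", "e1"] = mat.loc["e1", "f2"] = 0.063
        habitat = {"f1": "forest", "f2": "forest", "e1": "ecotone"}
        s = dv.fst_between_habitat_summary(mat, habitat, region="West")
        assert round(s.mean_fst, 3) == 0.058
        assert round(s.se_fst, 3) == 0.005
        assert s.fst_range == (0.053, 0.063)
        assert s.n_pairs == 2

    def test_single_pair_se_undefined(self):
        mat = pd.DataFrame(
            [[0.0, 0.1], [0.1, 0.0]], index=["a", "b"], columns=["a", "b"]
        )
        s = dv.fst_between_habitat_summary(mat, {"a": "forest", "b": "ecotone"})
        assert s.mean_fst == pytest.approx(0.1)
        assert not s.se_defined and np.isnan(s.se_fst)

    def test_pair_enumeration_counts(self):
        # [DERIVED] 3 forest + 2 ecotone populations -> 6 between-habitat pairs
        pops = ["f1", "f2", "f3", "e1", "e2"]
        rng = np.random.default_rng(0)
        vals = rng.uniform(0.01, 0.2, size=(5, 5))
        mat = (vals + vals.T) / 2
        np.fill_diagonal(mat, 0.0)
        habitat = {p: ("forest" if p.startswith("f") else "ecotone") for p in pops}
        s = dv.fst_between_habitat_summary(mat, habitat, populations=pops)
        assert s.n_pairs == 6

    def test_no_between_pair_errors(self):
        mat = np.array([[0.0, 0.1], [0.1, 0.0]])
        with pytest.raises(ValueError, match="no between-habitat"):
            dv.fst_between_habitat_summary(
                mat, {"a": "forest", "b": "forest"}, populations=["a", "b"]
            )

    def test_asymmetric_matrix_rejected(self):
        mat = np.array([[0.0, 0.1], [0.3, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            dv.fst_between_habitat_summary(
                mat, {"a": "forest", "b": "ecotone"}, populations=["a", "b"]
            )
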