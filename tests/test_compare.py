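import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu

from cellorg import compare


class TestMatchShapes:
    def test_identical_query_distance_zero(self):
        rng = np.random.default_rng(0)
        B = rng.standard_normal((10, 8))
        match = compare.match_shapes(B, B[3:4],
                                     baseline_ids=[f"b{i}" for i in range(10)],
                                     query_ids=["q"])
        assert match.nearest_by_query["q"] == "b3"

    def test_brute_force_oracle_50x20(self):
        rng = np.random.default_rng(1)
        B = rng.standard_normal((50, 8))
        Q = rng.standard_normal((20, 8))
        bids = [f"b{i:02d}" for i in range(50)]
        qids = [f"q{i:02d}" for i in range(20)]
        match = compare.match_shapes(B, Q, baseline_ids=bids, query_ids=qids)
        for qi, qid in enumerate(qids):
            d = np.linalg.norm(B - Q[qi], axis=1)  # exhaustive search
            expect = bids[int(np.argmin(d))]
            assert match.nearest_by_query[qid] == expect

    def test_duplicate_flags_collapse(self):
        B = np.zeros((3, 8))
        B[1] += 10.0
        B[2] += 20.0
        Q = np.zeros((2, 8)) + 0.1  # both nearest to baseline 0
        match = compare.match_shapes(B, Q, baseline_ids=["b0", "b1", "b2"],
                                     query_ids=["q0", "q1"])
        assert match.matched_baseline_ids == ["b0"]
        assert match.duplicate_flag_count == 1

    def test_tie_break_lowest_baseline_id(self):
        B = np.vstack([np.ones(8), np.ones(8)])  # exact tie
        match = compare.match_shapes(B, np.ones((1, 8)),
                                     baseline_ids=["z9", "a1"], query_ids=["q"])
        assert match.nearest_by_query["q"] == "a1"

    def test_empty_baseline_error(self):
        with pytest.raises(ValueError, match="empty"):
            compare.match_shapes(np.zeros((0, 8)), np.zeros((1, 8)))

    def test_combined_dataset_composition(self):
        rng = np.random.default_rng(2)
        B, Q = rng.standard_normal((6, 8)), rng.standard_normal((3, 8))
        match = compare.match_shapes(B, Q)
        assert len(match.matched_baseline_ids) == len(set(match.matched_baseline_ids))
        assert match.combined_mean_coords.shape == (8,)


class TestFitLdaAxis:
    def test_reduced_dim_rule(self):
        rng = np.random.default_rng(3)
        X = list(rng.standard_normal((40, 100)))
        labels = ["a"] * 20 + ["b"] * 20
        assert compare.fit_lda_axis(X, labels).reduced_dim == 32
        X10 = list(rng.standard_normal((10, 100)))
        assert compare.fit_lda_axis(X10, ["a"] * 5 + ["b"] * 5).reduced_dim == 10

    def test_two_populations_required(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError, match="two populations"):
            compare.fit_lda_axis(list(rng.standard_normal((6, 10))), ["a"] * 6)

    def test_minimum_population_size(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError, match="fewer than 3"):
            compare.fit_lda_axis(list(rng.standard_normal((5, 10))),
                                 ["a", "a", "a", "b", "b"])

    def test_planted_polarization_auc(self, polarization_populations):
        pilrs, labels = polarization_populations
        model = compare.fit_lda_axis(pilrs, labels)
        pos = compare.project_cells(model, pilrs)
        labels = np.array(labels)
        a, b = pos[labels == "uniform"], pos[labels == "polarized"]
        u = mannwhitneyu(b, a).statistic / (len(a) * len(b))
        assert max(u, 1.0 - u) >= 0.9

    def test_null_split_small_separation(self):
        # identical populations, random label split; large n keeps the
        # overfitting of the discriminant small
        rng = np.random.default_rng(6)
        X = list(rng.standard_normal((600, 400)))
        labels = list(rng.permutation(["a"] * 300 + ["b"] * 300))
        model = compare.fit_lda_axis(X, labels)
        assert abs(model.group_means["b"] - model.group_means["a"]) <= 0.5

    def test_label_swap_negates_positions(self, polarization_populations):
        pilrs, labels = polarization_populations
        m1 = compare.fit_lda_axis(pilrs[:20] + pilrs[-20:],
                                  labels[:20] + labels[-20:])
        # sign convention: second sorted label has positive mean
        assert m1.group_means[m1.labels[1]] > 0
        assert m1.group_means[m1.labels[0]] < 0

    def test_unit_norm_direction(self, polarization_populations):
        pilrs, labels = polarization_populations
        model = compare.fit_lda_axis(pilrs[:30] + pilrs[-30:],
                                     labels[:30] + labels[-30:])
        assert np.linalg.norm(model.direction) == pytest.approx(1.0)


class TestProjectReconstruct:
    @pytest.fixture(scope="class")
    def model_and_data(self, polarization_populations):
        pilrs, labels = polarization_populations
        return compare.fit_lda_axis(pilrs, labels), pilrs, np.array(labels)

    def test_mean_pilr_projects_to_mean_position(self, model_and_data):
        model, pilrs, labels = model_and_data
        sel = labels == "polarized"
        mean_pilr = np.mean([p.values for p, s in zip(pilrs, sel) if s], axis=0)
        pos = compare.project_cells(model, [mean_pilr])[0]
        expected = np.mean(compare.project_cells(
            model, [p for p, s in zip(pilrs, sel) if s]))
        assert pos == pytest.approx(expected, abs=1e-6)

    def test_project_reconstruct_identity(self, model_and_data):
        model, _, _ = model_and_data
        for p in (-2.0, -0.5, 0.0, 1.5):
            rec = compare.reconstruct_along_axis(model, p)
            assert compare.project_cells(model, [rec[0]])[0] == pytest.approx(p, abs=1e-6)

    def test_reconstruction_x_centroid_monotone(self, model_and_data, noisy_cell_coeffs):
        from cellorg import pilr as pilr_mod
        model, pilrs, _ = model_and_data
        shape = pilrs[0].values.shape
        fam = pilr_mod.build_shell_family(*noisy_cell_coeffs,
                                          n_nuclear_shells=8, n_cyto_shells=16,
                                          grid=(12, 24))
        x = fam.mesh_points()[..., 2].ravel()
        # orient positions from the uniform side towards the polarized side
        sgn = np.sign(model.group_means["polarized"])
        centroids = []
        for p in np.array([-2, -1, 0, 1, 2]) * sgn:
            w = np.clip(compare.reconstruct_along_axis(model, p)[0], 0, None)
            centroids.append((w * x).sum() / w.sum())
        assert np.all(np.diff(centroids) > 0)

    def test_nonfinite_position_error(self, model_and_data):
        model, _, _ = model_and_data
        with pytest.raises(ValueError, match="finite"):
            compare.reconstruct_along_axis(model, np.nan)


def F(vals, labels=("s1", "s2")):
    return pd.DataFrame(np.asarray(vals, dtype=float), index=list(labels),
                        columns=list(labels))


class TestFlagDifferences:
    def test_clear_change_flagged(self):
        flags, meas = compare.flag_differences(F([[0.5, 0.5], [0.5, 0.5]]),
                                               F([[0.4, 0.4], [0.4, 0.4]]))
        assert flags.loc["s1", "s1"] and meas.loc["s1", "s1"]

    def test_below_measurable_cutoff(self):
        flags, meas = compare.flag_differences(F([[0.02, 0.5], [0.5, 0.5]]),
                                               F([[0.5, 0.5], [0.5, 0.5]]))
        assert not meas.loc["s1", "s1"]
        assert not flags.loc["s1", "s1"]

    def test_small_difference_not_flagged(self):
        flags, meas = compare.flag_differences(F([[0.50, 0.5], [0.5, 0.5]]),
                                               F([[0.49, 0.5], [0.5, 0.5]]))
        assert meas.loc["s1", "s1"] and not flags.loc["s1", "s1"]

    def test_label_mismatch_error(self):
        with pytest.raises(ValueError, match="labels"):
            compare.flag_differences(F(np.eye(2)), F(np.eye(2), labels=("a", "b")))

    def test_relative_override_suppresses(self):
        # very high baseline, tiny relative change
        flags, _ = compare.flag_differences(F([[0.99, 0.5], [0.5, 0.5]]),
                                            F([[0.96, 0.5], [0.5, 0.5]]),
                                            relative_override=0.05)
        assert not flags.loc["s1", "s1"]
        flags_default, _ = compare.flag_differences(F([[0.99, 0.5], [0.5, 0.5]]),
                                                    F([[0.96, 0.5], [0.5, 0.5]]))
        assert flags_default.loc["s1", "s1"]

    @settings(max_examples=40, deadline=None)
    @given(st.floats(0.04, 0.9), st.floats(0.0, 0.5), st.floats(0.0, 0.3))
    def test_monotonicity_property(self, a, d1, extra):
        # increasing |A - B| never un-flags
        b_near, b_far = a - d1, a - d1 - extra
        f1, _ = compare.flag_differences(F([[a, a], [a, a]]),
                                         F([[b_near] * 2, [b_near] * 2]))
        f2, _ = compare.flag_differences(F([[a, a], [a, a]]),
                                         F([[b_far] * 2, [b_far] * 2]))
        if f1.loc["s1", "s1"]:
            assert f2.loc["s1", "s1"]


def toc_oracle(f1, f2, f3):
    """Independent enumeration of the category definitions.

    f1 = change interphase->m1; f2 = change i2->m2; f3 = change m1->m2.
    """
    if f1 and not f3:
        return "m1_only"
    if f1 and f3:
        return "stepwise"
    if not f1 and (f3 or f2):
        return "m2_change"
    return "no_change"


class TestTocCategories:
    def test_spec_examples(self):
        t = compare.toc_categories(F([[1, 0], [0, 0]]), F([[0, 0], [0, 0]]),
                                   F([[0, 0], [0, 0]]))
        assert t.categories.loc["s1", "s1"] == "m1_only"
        t = compare.toc_categories(F([[1, 0], [0, 0]]), F([[0, 0], [0, 0]]),
                                   F([[1, 0], [0, 0]]))
        assert t.categories.loc["s1", "s1"] == "stepwise"
        t = compare.toc_categories(F(np.zeros((2, 2))), F(np.zeros((2, 2))),
                                   F(np.zeros((2, 2))))
        assert t.categories.loc["s1", "s1"] == "no_change"

    def test_exhaustive_truth_table(self):
        for f1, f2, f3 in itertools.product([0, 1], repeat=3):
            t = compare.toc_categories(F([[f1, 0], [0, 0]]), F([[f2, 0], [0, 0]]),
                                       F([[f3, 0], [0, 0]]))
            assert t.categories.loc["s1", "s1"] == toc_oracle(f1, f2, f3), (f1, f2, f3)

    def test_unmeasurable_annotated(self):
        meas = F([[0, 1], [1, 1]])
        t = compare.toc_categories(F([[1, 0], [0, 0]]), F(np.zeros((2, 2))),
                                   F(np.zeros((2, 2))),
                                   measurable_i1m1=meas, measurable_i2m2=F(np.ones((2, 2))),
                                   measurable_m1m2=F(np.ones((2, 2))))
        assert t.categories.loc["s1", "s1"] == "no_change"
        assert t.annotations[("s1", "s1")] == "undetermined"


def relationship_oracle(sa, sb, cc):
    """Independent oracle over explicit change time points."""
    times = {"no_change": set(), "m1_only": {"m1"}, "m2_change": {"m2"},
             "stepwise": {"m1", "m2"}}
    S = times[sa] | times[sb]
    C = times[cc]
    if not S and not C:
        return "no_changes"
    if C and C.issubset(S):
        return "co_timed"
    return "independent"


class TestRelationship:
    @staticmethod
    def build(sa, sb, cc):
        cats = pd.DataFrame("no_change", index=["a", "b"], columns=["a", "b"],
                            dtype=object)
        cats.loc["a", "a"] = sa
        cats.loc["b", "b"] = sb
        stereo = compare.TOCTable(["a", "b"], cats.copy(),
                                  pd.DataFrame(True, index=["a", "b"], columns=["a", "b"]))
        ccats = cats.copy()
        ccats.loc["a", "b"] = ccats.loc["b", "a"] = cc
        conc = compare.TOCTable(["a", "b"], ccats,
                                pd.DataFrame(True, index=["a", "b"], columns=["a", "b"]))
        return stereo, conc

    def test_all_no_change(self):
        df = compare.stereotypy_concordance_relationship(
            *self.build("no_change", "no_change", "no_change"))
        assert df.iloc[0]["category"] == "no_changes"

    def test_co_timed_at_first_change(self):
        df = compare.stereotypy_concordance_relationship(
            *self.build("m1_only", "no_change", "m1_only"))
        row = df.iloc[0]
        assert row["category"] == "co_timed" and row["at_first_change"]

    def test_independent_histone_microtubule_pattern(self):
        # stereotypy changed at m1, concordance only at m2
        df = compare.stereotypy_concordance_relationship(
            *self.build("m1_only", "m1_only", "m2_change"))
        assert df.iloc[0]["category"] == "independent"

    def test_exhaustive_4x4x4_enumeration(self):
        cats = ("no_change", "m1_only", "m2_change", "stepwise")
        for sa, sb, cc in itertools.product(cats, repeat=3):
            df = compare.stereotypy_concordance_relationship(*self.build(sa, sb, cc))
            assert df.iloc[0]["category"] == relationship_oracle(sa, sb, cc), (sa, sb, cc)


class TestPlantedPhenotypeRanking:
    @staticmethod
    def lean_pilr(bias, seed):
        from cellorg import fixtures as fx
        from cellorg import pilr, shparam
        spec = fx.SyntheticCellSpec(cell_base_radius=8, shape_noise_amplitude=0.04,
                                    seed=seed)
        cell, nuc = fx.generate_cell_shape(spec)
        struct = fx.generate_structure(
            fx.StructurePattern(kind="polarized_punctate", density=30,
                                polarization_bias=bias, seed=seed + 1), cell, nuc)
        cc, nc = shparam.parameterize_cell(cell, nuc, lmax=6)
        return pilr.sample_pilr(struct.astype(np.uint8), cc, nc,
                                n_nuclear_shells=6, n_cyto_shells=12, grid=(8, 16))

    def test_polarized_structures_rank_top(self):
        # 2 of 5 structures polarized in population B (downscaled from 10);
        # n = 64 per group keeps the discriminant away from the saturated
        # small-sample regime so separations rank the planted structures
        seps = {}
        for k in range(5):
            bias = 1.0 if k < 2 else 0.0
            pilrs, labels = [], []
            for i in range(64):
                pilrs.append(self.lean_pilr(0.0, 9000 + 31 * (k * 64 + i)))
                labels.append("popA")
            for i in range(64):
                pilrs.append(self.lean_pilr(bias, 700000 + 31 * (k * 64 + i)))
                labels.append("popB")
            model = compare.fit_lda_axis(pilrs, labels)
            seps[k] = abs(model.group_means["popB"] - model.group_means["popA"])
        ranking = sorted(seps, key=seps.get, reverse=True)
        assert set(ranking[:2]) == {0, 1}
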