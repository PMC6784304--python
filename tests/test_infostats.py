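import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.stats import f_oneway, kstest

from handoverid.errors import RankDeficiencyError
from handoverid.infostats import (
    Descriptor,
    choose_descriptor,
    entropy,
    manova,
    mi_matrix,
    model_reduction,
    mutual_information,
)


class TestDescriptor:
    def test_binary_labels_get_two_cells(self):
        x = np.array([0, 1] * 50)
        assert choose_descriptor(x).n_cells == 2

    def test_constant_sample_gets_one_cell(self):
        assert choose_descriptor(np.full(40, 3.7)).n_cells == 1
        assert entropy(np.full(40, 3.7)) == 0.0

    def test_sturges_rule_for_continuous_inputs(self):
        rng = np.random.default_rng(0)
        assert choose_descriptor(rng.normal(size=128)).n_cells == 8

    def test_categorical_strings_one_cell_per_category(self):
        x = np.array(["a", "b", "c"] * 10)
        assert choose_descriptor(x).n_cells == 3


class TestMutualInformation:
    def test_self_information_of_fair_binary_is_one_bit(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 2, 10_000)
        assert mutual_information(x, x) == pytest.approx(1.0, abs=0.05)

    def test_independent_binaries_have_near_zero_information(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 2, 10_000)
        y = rng.integers(0, 2, 10_000)
        assert abs(mutual_information(x, y)) < 0.02

    def test_plugin_estimate_matches_hand_evaluation_on_printed_table(self):
        # joint counts [[30, 10], [10, 50]]: plug-in MI by direct formula
        x = np.repeat([0, 0, 1, 1], [30, 10, 10, 50])
        y = np.repeat([0, 1, 0, 1], [30, 10, 10, 50])
        p = np.array([[0.3, 0.1], [0.1, 0.5]])
        px, py = p.sum(1), p.sum(0)
        expected = sum(
            p[i, j] * np.log2(p[i, j] / (px[i] * py[j]))
            for i in range(2) for j in range(2)
        )
        assert mutual_information(x, y, corrected=False) == pytest.approx(
            expected, abs=1e-12
        )

    def test_bias_correction_subtracts_miller_madow_term(self):
        x = np.array([0, 1, 0, 1, 1, 0, 0, 1, 1, 0])
        y = np.array([0, 0, 1, 1, 0, 1, 0, 1, 0, 1])
        raw = mutual_information(x, y, corrected=False)
        corr = mutual_information(x, y, corrected=True)
        assert raw - corr == pytest.approx(1 / (20 * np.log(2)), abs=1e-12)

    def test_uncorrected_agrees_with_independent_implementation(self):
        sklearn = pytest.importorskip("sklearn")
        from sklearn.metrics import mutual_info_score

        rng = np.random.default_rng(3)
        x = rng.integers(0, 4, 500)
        y = (x + rng.integers(0, 2, 500)) % 4
        theirs = mutual_info_score(x, y) / np.log(2)  # nats -> bits
        assert mutual_information(x, y, corrected=False) == pytest.approx(
            theirs, abs=1e-10
        )

    @given(st.integers(0, 5_000))
    def test_symmetry_and_selfinformation_identity(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 3, 200)
        y = rng.integers(0, 3, 200)
        assert mutual_information(x, y) == pytest.approx(mutual_information(y, x))
        assert mutual_information(x, x, corrected=False) == pytest.approx(
            entropy(x), abs=1e-12
        )
        assert mutual_information(x, y, corrected=False) >= -1e-12


class TestMIMatrix:
    def test_randomized_condition_factors_are_mutually_uninformative(self, tiny_frame):
        from handoverid.datagen import FACTOR_NAMES

        M = mi_matrix(tiny_frame[list(FACTOR_NAMES)])
        off = M.to_numpy()[~np.eye(5, dtype=bool)]
        assert np.all(np.abs(off) < 0.08)

    def test_diagonal_dominates_each_row_for_uncorrected_estimate(self, tiny_frame):
        cols = ["participant", "gender", "age", "platform", "giver_side"]
        M = mi_matrix(tiny_frame[cols], corrected=False)
        v = M.to_numpy()
        for i in range(len(cols)):
            assert v[i, i] >= v[i].max() - 1e-12

    def test_functional_dependence_reaches_the_entropy_ceiling(self, tiny_frame):
        frame = pd.DataFrame({
            "identity": tiny_frame["participant"],
            "copied": tiny_frame["participant"].map(lambda s: s + "!"),
        })
        M = mi_matrix(frame, corrected=False)
        h = entropy(frame["identity"].to_numpy())
        assert M.loc["identity", "copied"] == pytest.approx(h, abs=1e-12)
        assert M.loc["identity", "identity"] == pytest.approx(h, abs=1e-12)


def _anova_oracle(y, groups):
    """Closed-form one-way ANOVA F and p via scipy.stats.f_oneway."""
    samples = [y[groups == g] for g in sorted(set(groups))]
    return f_oneway(*samples)


class TestManova:
    def test_univariate_case_reduces_to_oneway_anova(self):
        rng = np.random.default_rng(4)
        groups = np.repeat(list("abcd"), 15)
        y = rng.normal(size=60) + np.repeat([0, 0.5, 1.0, 0.2], 15)
        res = manova(y[:, None], pd.DataFrame({"g": groups}), ["g"])
        F, p = _anova_oracle(y, groups)
        for stat in ("Pillai", "Wilks", "Hotelling", "Roy"):
            assert res.terms["g"][stat].F == pytest.approx(F, abs=1e-8)
            assert res.terms["g"][stat].p == pytest.approx(p, abs=1e-8)

    def test_agrees_with_statsmodels_on_multivariate_data(self):
        sm = pytest.importorskip("statsmodels.multivariate.manova")

        rng = np.random.default_rng(5)
        n = 80
        g = rng.choice(list("abc"), n)
        x = rng.normal(size=n)
        Y = rng.normal(size=(n, 4))
        Y[:, 0] += (g == "a") * 1.5
        Y[:, 2] += 0.8 * x
        data = pd.DataFrame({"g": g, "x": x})
        ours = manova(Y, data, ["g", "x"])

        frame = data.copy()
        for j in range(4):
            frame[f"y{j}"] = Y[:, j]
        theirs = sm.MANOVA.from_formula("y0 + y1 + y2 + y3 ~ g + x", data=frame)
        tbl = theirs.mv_test().results
        name_map = {
            "Pillai": "Pillai's trace", "Wilks": "Wilks' lambda",
            "Hotelling": "Hotelling-Lawley trace", "Roy": "Roy's greatest root",
        }
        for term in ("g", "x"):
            stat_df = tbl[term]["stat"]
            for ours_name, theirs_name in name_map.items():
                row = stat_df.loc[theirs_name]
                assert ours.terms[term][ours_name].value == pytest.approx(
                    float(row["Value"]), abs=1e-8
                )
                assert ours.terms[term][ours_name].p == pytest.approx(
                    float(row["Pr > F"]), abs=1e-8
                )

    def test_statistics_satisfy_single_eigenvalue_identities(self):
        # two groups (q = 1): a single nonzero eigenvalue lambda must satisfy
        # Pillai = l/(1+l), Wilks = 1/(1+l), Hotelling = l, Roy = l
        rng = np.random.default_rng(6)
        g = np.repeat(["a", "b"], 25)
        Y = rng.normal(size=(50, 3))
        Y[g == "b"] += [1.0, 0.5, 0.0]
        res = manova(Y, pd.DataFrame({"g": g}), ["g"])
        lam = res.terms["g"]["Hotelling"].value
        assert res.terms["g"]["Roy"].value == pytest.approx(lam, abs=1e-10)
        assert res.terms["g"]["Pillai"].value == pytest.approx(lam / (1 + lam), abs=1e-10)
        assert res.terms["g"]["Wilks"].value == pytest.approx(1 / (1 + lam), abs=1e-10)

    def test_null_p_values_are_uniform_over_seeds(self):
        ps = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            g = rng.permutation(np.repeat(["a", "b", "c"], 20))
            Y = rng.normal(size=(60, 2))
            ps.append(manova(Y, pd.DataFrame({"g": g}), ["g"]).p("g", "Wilks"))
        assert kstest(ps, "uniform").pvalue > 0.05

    def test_singular_error_matrix_names_offending_columns(self):
        rng = np.random.default_rng(7)
        g = np.repeat(["a", "b"], 10)
        Y = np.column_stack([rng.normal(size=20), np.full(20, 2.0)])
        with pytest.raises(RankDeficiencyError, match="1"):
            manova(Y, pd.DataFrame({"g": g}), ["g"])

    def test_redundant_term_gets_p_of_one(self):
        # a trait constant within participants adds nothing once participant
        # identity is in the model
        rng = np.random.default_rng(8)
        people = np.repeat([f"P{i}" for i in range(4)], 10)
        trait = pd.Series(people).map({"P0": 1.0, "P1": 3.0, "P2": 2.0, "P3": 5.0})
        Y = rng.normal(size=(40, 2))
        res = manova(Y, pd.DataFrame({"participant": people, "trait": trait}),
                     ["participant", "trait"])
        assert res.p("trait", "Wilks") == 1.0


class TestModelReduction:
    def test_noise_factor_is_eliminated_and_signal_retained(self):
        rng = np.random.default_rng(9)
        n = 90
        signal = rng.choice(["u", "v"], n)
        noise = rng.normal(size=n)
        Y = rng.normal(size=(n, 3))
        Y[:, 0] += (signal == "u") * 2.0
        data = pd.DataFrame({"signal": signal, "noise": noise})
        retained, results = model_reduction(Y, data, ["signal", "noise"], alpha=0.05)
        assert retained == ["signal"]
        assert results[0].p("signal", "Wilks") < 0.05

    def test_alpha_one_keeps_every_informative_candidate(self):
        rng = np.random.default_rng(10)
        n = 60
        data = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        Y = rng.normal(size=(n, 2))
        retained, _ = model_reduction(Y, data, ["a", "b"], alpha=1.0)
        assert retained == ["a", "b"]

    def test_pure_noise_candidates_empty_out(self):
        rng = np.random.default_rng(11)
        n = 80
        Ys = [rng.normal(size=(n, 2)) for _ in range(3)]
        data = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        retained, results = model_reduction(Ys, data, ["a", "b"], alpha=0.01)
        assert retained == []
        assert results == []

    def test_fixed_identity_term_absorbs_participant_constant_traits(self):
        rng = np.random.default_rng(12)
        people = np.repeat([f"P{i}" for i in range(6)], 8)
        trait = pd.Series(people).map(
            {f"P{i}": float(i % 3) for i in range(6)}
        )
        Y = rng.normal(size=(48, 2))
        # make identity genuinely informative
        Y[:, 0] += pd.Series(people).map(
            {f"P{i}": float(i) for i in range(6)}
        ).to_numpy()
        data = pd.DataFrame({"participant": people, "trait": trait})
        retained, _ = model_reduction(
            Y, data, ["trait"], alpha=0.05, fixed_terms=["participant"]
        )
        assert retained == []
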