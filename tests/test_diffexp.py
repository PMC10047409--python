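"""Normalization, exact NB test, calling, profiles, Venn and merging."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as ss

from cernapipe import diffexp, simdata
from cernapipe.diffexp import _quantile_adjust

from conftest import make_count_matrix
from oracles import brute_force_venn


def nb_matrix(rng, n_features, mean, dispersion, n_per_group=3):
    lam = rng.gamma(1.0 / dispersion, mean * dispersion, size=(n_features, 2 * n_per_group))
    counts = rng.poisson(lam)
    return make_count_matrix(
        {f"s{i}": counts[:, i] for i in range(2 * n_per_group)},
        stages=["A"] * n_per_group + ["B"] * n_per_group,
        features=[f"f{i}" for i in range(n_features)],
    )


class TestNormalize:
    def test_identical_columns_give_unit_factors(self):
        cm = make_count_matrix(
            {f"s{i}": [10, 50, 200, 5] for i in range(6)},
            stages=["A"] * 3 + ["B"] * 3,
        )
        f = diffexp.normalize(cm)
        assert all(abs(v - 1.0) < 1e-12 for v in f.factors.values())

    def test_pure_depth_difference_is_equalized_in_cpm(self):
        rng = np.random.default_rng(0)
        base = rng.integers(10, 500, size=200)
        cm = make_count_matrix(
            {"s0": base, "s1": base * 3, "s2": base, "s3": base * 3},
            stages=["A", "A", "B", "B"],
            features=[f"f{i}" for i in range(200)],
        )
        values = diffexp.cpm(cm, diffexp.normalize(cm))
        assert np.allclose(values["s0"], values["s1"], rtol=1e-9)

    def test_factors_have_unit_geometric_mean(self):
        rng = np.random.default_rng(3)
        for seed in range(3):
            cm = nb_matrix(np.random.default_rng(seed), 300, 100, 0.2)
            f = diffexp.normalize(cm)
            logs = np.log(list(f.factors.values()))
            assert abs(logs.mean()) < 1e-9

    def test_all_zero_sample_is_an_error(self):
        cm = make_count_matrix(
            {"s0": [1, 2], "s1": [0, 0], "s2": [3, 1], "s3": [1, 1]},
            stages=["A", "A", "B", "B"],
        )
        with pytest.raises(ValueError, match="s1"):
            diffexp.normalize(cm)


class TestExactNbTest:
    def test_identical_groups_give_p_one_and_zero_lfc(self):
        col = [10, 50, 200, 5]
        cm = make_count_matrix(
            {f"s{i}": col for i in range(6)}, stages=["A"] * 3 + ["B"] * 3
        )
        res = diffexp.exact_nb_test(cm, "A", "B", diffexp.normalize(cm))
        assert (res["pvalue"] == 1.0).all()
        assert (res["log2fc"] == 0.0).all()

    def test_group_swap_negates_lfc_and_keeps_p(self):
        cm = nb_matrix(np.random.default_rng(5), 100, 80, 0.1)
        f = diffexp.normalize(cm)
        ab = diffexp.exact_nb_test(cm, "A", "B", f)
        ba = diffexp.exact_nb_test(cm, "B", "A", f)
        assert np.allclose(ab["log2fc"], -ba["log2fc"], atol=1e-12)
        assert np.allclose(ab["pvalue"], ba["pvalue"], atol=1e-12)

    def test_poisson_limit_agrees_with_exact_binomial_split(self):
        cm = nb_matrix(np.random.default_rng(6), 300, 60, 1e-6)
        f = diffexp.normalize(cm)
        res = diffexp.exact_nb_test(cm, "A", "B", f, dispersion=1e-6)
        eff = f.effective_lib_sizes()
        ne = np.array([eff[s] for s in cm.counts.columns])
        ntilde = float(np.exp(np.log(ne).mean()))
        x = cm.counts.to_numpy(float)
        phat = x.sum(1) / ne.sum()
        y = _quantile_adjust(
            x, phat[:, None] * ne[None, :], phat[:, None] * np.full(6, ntilde)[None, :], 1e-6
        )
        sa = np.rint(y[:, :3].sum(1)).astype(int)
        sb = np.rint(y[:, 3:].sum(1)).astype(int)
        binom_p = np.array(
            [ss.binomtest(a, a + b, 0.5).pvalue if a + b else 1.0 for a, b in zip(sa, sb)]
        )
        assert np.abs(res["pvalue"].to_numpy() - binom_p).max() < 1e-3

    def test_power_is_monotone_in_effect_size(self):
        # 40 planted features among 400; power measured on the planted subset
        rng = np.random.default_rng(8)
        hits = []
        for lfc in (0.5, 1.0, 2.0):
            lam = np.full((400, 6), 100.0)
            lam[:40, 3:] *= 2**lfc
            counts = rng.poisson(rng.gamma(10.0, lam / 10.0))
            cm = make_count_matrix(
                {f"s{i}": counts[:, i] for i in range(6)},
                stages=["A"] * 3 + ["B"] * 3,
                features=[f"f{i}" for i in range(400)],
            )
            res = diffexp.exact_nb_test(cm, "A", "B", diffexp.normalize(cm))
            called = diffexp.call_de(res, keep_all=True)["significant"][:40]
            hits.append(float(called.mean()))
        assert hits[0] <= hits[1] <= hits[2]
        assert hits[0] < hits[2]

    def test_missing_stage_is_an_error(self):
        cm = nb_matrix(np.random.default_rng(1), 10, 50, 0.1)
        with pytest.raises(ValueError, match="stage"):
            diffexp.exact_nb_test(cm, "A", "Z", diffexp.normalize(cm))


class TestCallDe:
    def _frame(self, p, lfc):
        return pd.DataFrame(
            {"feature": ["x"], "comparison": ["A_vs_B"], "log2fc": [lfc], "pvalue": [p], "fdr": [p]}
        )

    @pytest.mark.parametrize(
        "p,lfc,expected_sig,expected_dir",
        [
            (0.04, 1.2, True, "up"),
            (0.04, 0.5, False, "none"),
            (0.05, 1.0, True, "up"),  # boundary values are inclusive
            (0.05, -1.0, True, "down"),
            (0.051, 1.5, False, "none"),
        ],
    )
    def test_threshold_semantics(self, p, lfc, expected_sig, expected_dir):
        out = diffexp.call_de(self._frame(p, lfc), keep_all=True)
        assert bool(out["significant"][0]) is expected_sig
        assert out["direction"][0] == expected_dir

    def test_returns_significant_subset_by_default(self):
        df = pd.concat([self._frame(0.01, 2.0), self._frame(0.5, 2.0)], ignore_index=True)
        out = diffexp.call_de(df)
        assert len(out) == 1 and out["direction"][0] == "up"


class TestClassifyProfiles:
    def _matrix(self, rows):
        # balanced column sums so normalization leaves stage means intact
        features = [f"f{i}" for i in range(len(rows))]
        cols = {}
        for j, stage in enumerate(("D85", "D105", "D135")):
            for r in range(3):
                cols[f"{stage}-{r + 1}"] = [row[j] for row in rows]
        cm = make_count_matrix(cols, stages=["D85"] * 3 + ["D105"] * 3 + ["D135"] * 3, features=features)
        return cm

    def test_textbook_patterns(self):
        rows = [
            (10, 20, 40),  # incremental
            (40, 20, 10),  # decreasing
            (40, 10, 40),  # high-low-high
            (10, 40, 10),  # low-high-low
            (10, 10, 10),  # irregular: both deltas below tau
        ]
        cm = self._matrix(rows)
        cats = diffexp.classify_profiles(cm, diffexp.normalize(cm))
        assert list(cats) == [
            "incremental",
            "decreasing",
            "high_low_high",
            "low_high_low",
            "irregular",
        ]

    def test_sub_tau_step_breaks_the_pattern(self):
        # column sums balanced so CPM preserves the planted means
        cm = self._matrix([(10, 12, 40), (40, 38, 10)])  # first steps < log2(1.5)
        cats = diffexp.classify_profiles(cm, diffexp.normalize(cm))
        assert list(cats) == ["irregular", "irregular"]

    def test_requires_three_stages(self):
        cm = make_count_matrix(
            {"a": [1], "b": [2], "c": [1], "d": [2]}, stages=["A", "A", "B", "B"]
        )
        with pytest.raises(ValueError, match="3 stages"):
            diffexp.classify_profiles(cm, diffexp.normalize(cm))

    def test_classifier_recovers_planted_shapes_on_noise_free_means(self):
        shapes = simdata.PROFILE_SHAPES[:4]
        rows, want = [], []
        for shape in shapes:
            offs = simdata.profile_offsets(shape, 2.0)
            rows.append(tuple(int(round(1000 * 2**o)) for o in offs))
            rows.append(tuple(int(round(1000 * 2**-o)) for o in offs))  # mirror keeps sums balanced
            want.append(shape)
            want.append(
                {
                    "incremental": "decreasing",
                    "decreasing": "incremental",
                    "high_low_high": "low_high_low",
                    "low_high_low": "high_low_high",
                }[shape]
            )
        cm = self._matrix(rows)
        cats = diffexp.classify_profiles(cm, diffexp.normalize(cm))
        assert list(cats) == want


class TestVennOverlap:
    def test_enumerable_example(self):
        part = diffexp.venn_overlap({"c1": {"a", "b", "c"}, "c2": {"b", "c", "d"}, "c3": {"c", "e"}})
        assert part.core == {"c"}
        assert part.regions[(True, False, False)] == {"a"}
        assert part.regions[(True, True, False)] == {"b"}
        assert part.regions[(False, True, False)] == {"d"}
        assert part.regions[(False, False, True)] == {"e"}
        assert part.regions[(True, False, True)] == frozenset()

    def test_disjoint_sets_have_empty_core(self):
        part = diffexp.venn_overlap({"x": {"a"}, "y": {"b"}, "z": {"c"}})
        assert part.core == frozenset()

    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(2)
        ids = [f"id{i}" for i in range(100)]
        sets = {
            name: set(rng.choice(ids, size=rng.integers(10, 60), replace=False))
            for name in ("A_vs_B", "B_vs_C", "A_vs_C")
        }
        part = diffexp.venn_overlap(sets)
        want = brute_force_venn(sets)
        for mask, members in part.regions.items():
            assert set(members) == want.get(mask, set())
        union = set().union(*sets.values())
        assert set().union(*part.regions.values()) == union
        assert len(part.core) <= min(len(s) for s in sets.values())


class TestMergeDuplicateMatures:
    def test_sixteen_ids_with_two_duplicate_pairs_give_fourteen(self):
        seqs = {f"m{i:02d}": f"SEQ{i}" for i in range(16)}
        seqs["m01"] = seqs["m00"] = "UGAGGUAGUAGGUUGUAUAGUU"
        seqs["m03"] = seqs["m02"] = "AGUGGUUUUACCCUAUGGUAG"
        kept, aliases = diffexp.merge_duplicate_matures(seqs.keys(), seqs)
        assert len(kept) == 14
        assert aliases == {"m00": ("m01",), "m02": ("m03",)}

    def test_distinct_sequences_pass_through(self):
        seqs = {"a": "AAAA", "b": "CCCC"}
        kept, aliases = diffexp.merge_duplicate_matures(seqs, seqs)
        assert kept == ["a", "b"] and aliases == {}

    def test_three_way_duplicates_collapse_transitively(self):
        seqs = {"z": "AAAA", "a": "AAAA", "m": "AAAA"}
        kept, aliases = diffexp.merge_duplicate_matures(seqs, seqs)
        assert kept == ["a"] and aliases == {"a": ("m", "z")}

    def test_missing_sequence_is_an_error(self):
        with pytest.raises(ValueError, match="nope"):
            diffexp.merge_duplicate_matures(["nope"], {})
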