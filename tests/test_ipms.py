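"""IP-MS scoring: SAINT aggregation, normalization, differential calls,
stability ratios, quadrant assignment, Venn partitioning."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hipnet.errors import BaitQuantError, EmptyInputError, InvalidThresholdError
from hipnet.ipms import (
    assign_specific_stable,
    differential_interactions,
    filter_quantified,
    normalize_to_bait,
    saint_specificity,
    select_replicates_min_cv,
    stability_ratio,
    venn_partition,
)


class TestSaint:
    def test_perfect_scores(self):
        assert saint_specificity([1.0, 1.0, 0.0]) == (1.0, True)

    def test_boundary_inclusive(self):
        avg, specific = saint_specificity([0.9, 0.7, 0.1])
        assert avg == pytest.approx(0.8) and specific

    def test_below_threshold(self):
        avg, specific = saint_specificity([0.7, 0.7, 0.7])
        assert not specific

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=8))
    @settings(max_examples=100, deadline=None)
    def test_matches_sort_and_mean_oracle(self, scores):
        avg, _ = saint_specificity(scores)
        expected = sum(sorted(scores)[-2:]) / 2
        assert avg == pytest.approx(expected)

    def test_too_few_scores(self):
        with pytest.raises(EmptyInputError):
            saint_specificity([0.9])


class TestBaitNormalization:
    def matrix(self, data, samples):
        return pd.DataFrame(data, index=list(data), columns=samples).T.T

    def test_constant_bait_is_identity(self):
        m = pd.DataFrame({"s1": [10.0, 2.0], "s2": [20.0, 2.0]},
                         index=["P", "HTT"])
        out = normalize_to_bait(m, "HTT")
        pd.testing.assert_frame_equal(out, m)

    def test_hand_computed_example(self):
        m = pd.DataFrame({"s1": [10.0, 2.0], "s2": [20.0, 4.0]},
                         index=["P", "HTT"])
        out = normalize_to_bait(m, "HTT")
        assert out.loc["P"].tolist() == pytest.approx([15.0, 15.0])

    def test_bait_row_constant_after_normalization(self):
        rng = np.random.default_rng(3)
        samples = [f"s{i}" for i in range(6)]
        m = pd.DataFrame(rng.uniform(1, 100, size=(10, 6)),
                         index=[f"P{i}" for i in range(9)] + ["HTT"],
                         columns=samples)
        out = normalize_to_bait(m, "HTT")
        bait = out.loc["HTT"].to_numpy()
        assert np.all(np.abs(bait - bait[0]) < 1e-9)

    def test_missing_bait_rejected(self):
        m = pd.DataFrame({"s1": [1.0, np.nan], "s2": [2.0, 3.0]},
                         index=["P", "HTT"])
        with pytest.raises(BaitQuantError) as exc:
            normalize_to_bait(m, "HTT")
        assert "s1" in str(exc.value)


class TestFilterQuantified:
    def test_full_group_kept(self):
        m = pd.DataFrame(
            [[1.0, 1, 1, np.nan, np.nan, np.nan]],
            index=["P"],
            columns=[f"{g}_r{r}" for g in ("Q20-2M", "Q140-2M")
                     for r in (1, 2, 3)],
        )
        out = filter_quantified(m, groups=("Q20-2M", "Q140-2M"))
        assert list(out.index) == ["P"]

    def test_scattered_singletons_dropped(self):
        m = pd.DataFrame(
            [[1.0, np.nan, np.nan, 2.0, np.nan, np.nan]],
            index=["P"],
            columns=[f"{g}_r{r}" for g in ("Q20-2M", "Q140-2M")
                     for r in (1, 2, 3)],
        )
        out = filter_quantified(m, groups=("Q20-2M", "Q140-2M"))
        assert out.empty

    def test_matches_comprehension_oracle(self):
        rng = np.random.default_rng(5)
        groups = ("Q20-2M", "Q140-2M", "Q20-10M", "Q140-10M")
        cols = [f"{g}_r{r}" for g in groups for r in (1, 2, 3)]
        vals = rng.uniform(1, 10, size=(40, 12))
        mask = rng.random(size=(40, 12)) < 0.45
        vals[mask] = np.nan
        m = pd.DataFrame(vals, index=[f"P{i}" for i in range(40)], columns=cols)
        out = filter_quantified(m, groups=groups, min_values=2)
        expected = {
            p for p in m.index
            if any(
                m.loc[p, [c for c in cols if c.startswith(g + "_")]]
                .notna().sum() >= 2
                for g in groups
            )
        }
        assert set(out.index) == expected


class TestMinCVSelection:
    def test_outlier_replicate_excluded(self):
        cols = ["G_r1", "G_r2", "G_r3"]
        m = pd.DataFrame(
            {"G_r1": [10.0, 20.0], "G_r2": [10.0, 20.0],
             "G_r3": [50.0, 90.0]},
            index=["P1", "P2"],
        )
        assert select_replicates_min_cv(m, "G") == ["G_r1", "G_r2"]

    def test_keep_equals_group_size_identity(self):
        m = pd.DataFrame({"G_r1": [1.0], "G_r2": [2.0], "G_r3": [3.0]},
                         index=["P"])
        assert select_replicates_min_cv(m, "G", keep=3) == \
            ["G_r1", "G_r2", "G_r3"]

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(7)
        cols = [f"G_r{i}" for i in range(1, 4)]
        m = pd.DataFrame(rng.uniform(5, 50, size=(20, 3)),
                         index=[f"P{i}" for i in range(20)], columns=cols)
        got = select_replicates_min_cv(m, "G", keep=2)
        best = None
        for subset in itertools.combinations(cols, 2):
            sub = m[list(subset)]
            cv = (sub.std(axis=1, ddof=1) / sub.mean(axis=1)).median()
            if best is None or (cv, subset) < best:
                best = (float(cv), subset)
        assert tuple(got) == best[1]


def ttest_oracle(a, b):
    """Classical equal-variance two-sample t, from the textbook formulas."""
    from scipy.stats import t as tdist

    na, nb = len(a), len(b)
    ma, mb = np.mean(a), np.mean(b)
    sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) \
        / (na + nb - 2)
    tstat = (mb - ma) / math.sqrt(sp2 * (1 / na + 1 / nb))
    return 2 * tdist.sf(abs(tstat), na + nb - 2)


class TestDifferential:
    def cols(self):
        return [f"{g}_r{r}" for g in ("Q20-2M", "Q140-2M") for r in (1, 2, 3)]

    def test_identical_groups_no_call(self):
        m = pd.DataFrame([[5.0, 6, 7, 5, 6, 7]], index=["P"],
                         columns=self.cols())
        res = differential_interactions(m, "Q20-2M", "Q140-2M")
        assert res.loc["P", "log2fc"] == pytest.approx(0.0)
        assert not res.loc["P", "call"]

    def test_exact_fourfold_ratio(self):
        m = pd.DataFrame([[100.0, 100, 100, 400, 400, 400]], index=["P"],
                         columns=self.cols())
        res = differential_interactions(m, "Q20-2M", "Q140-2M")
        assert res.loc["P", "log2fc"] == pytest.approx(2.0)
        assert res.loc["P", "call"]

    def test_degenerate_equal_constant_groups(self):
        m = pd.DataFrame([[5.0, 5, 5, 5, 5, 5]], index=["P"],
                         columns=self.cols())
        res = differential_interactions(m, "Q20-2M", "Q140-2M")
        assert res.loc["P", "p_value"] == pytest.approx(1.0)
        assert not res.loc["P", "call"]

    def test_untested_proteins_reported(self):
        m = pd.DataFrame([[5.0, np.nan, np.nan, 5, 6, 7]], index=["P"],
                         columns=self.cols())
        res = differential_interactions(m, "Q20-2M", "Q140-2M")
        assert not res.loc["P", "tested"] and not res.loc["P", "call"]

    def test_matches_textbook_oracle_on_spiked_matrix(self):
        rng = np.random.default_rng(21)
        n = 60
        spiked = set(range(10))
        rows = []
        for i in range(n):
            base = rng.uniform(18, 24)
            a = 2.0 ** (base + rng.normal(0, 0.2, size=3))
            shift = 2.0 if i in spiked else 0.0
            b = 2.0 ** (base + shift + rng.normal(0, 0.2, size=3))
            rows.append(np.concatenate([a, b]))
        m = pd.DataFrame(rows, index=[f"P{i}" for i in range(n)],
                         columns=self.cols())
        res = differential_interactions(m, "Q20-2M", "Q140-2M")
        for i in range(n):
            a = np.log2(m.iloc[i, :3].to_numpy())
            b = np.log2(m.iloc[i, 3:].to_numpy())
            p_expected = ttest_oracle(a, b)
            fc_expected = np.log2(m.iloc[i, 3:].mean() / m.iloc[i, :3].mean())
            row = res.iloc[i]
            assert row["p_value"] == pytest.approx(p_expected, rel=1e-9)
            assert row["log2fc"] == pytest.approx(fc_expected, rel=1e-9)
            expected_call = abs(fc_expected) >= 1.0 and p_expected < 0.05
            assert bool(row["call"]) == expected_call

    def test_antisymmetric(self):
        rng = np.random.default_rng(22)
        m = pd.DataFrame(rng.uniform(10, 1000, size=(15, 6)),
                         index=[f"P{i}" for i in range(15)],
                         columns=self.cols())
        fwd = differential_interactions(m, "Q20-2M", "Q140-2M")
        rev = differential_interactions(m, "Q140-2M", "Q20-2M")
        assert np.allclose(fwd["log2fc"], -rev["log2fc"])
        assert np.allclose(fwd["p_value"], rev["p_value"])


class TestStability:
    def test_anchors(self):
        assert stability_ratio(1000.0, 1000.0) == pytest.approx(0.5)
        assert stability_ratio(1000.0, 0.0) == pytest.approx(1.0)
        assert stability_ratio(1.0, 3.0) == pytest.approx(0.25)

    @given(
        st.floats(1e-6, 1e6), st.floats(0, 1e6), st.floats(1e-3, 1e3)
    )
    @settings(max_examples=200, deadline=None)
    def test_scale_invariance(self, light, heavy, c):
        assert stability_ratio(c * light, c * heavy) == pytest.approx(
            stability_ratio(light, heavy)
        )

    def test_invalid_inputs(self):
        with pytest.raises(EmptyInputError):
            stability_ratio(0.0, 0.0)
        with pytest.raises(InvalidThresholdError):
            stability_ratio(-1.0, 2.0)


class TestSpecStable:
    def test_corners(self):
        assert assign_specific_stable("G", "Q20-2M", 1.0, 1.0).classification \
            == "specific_stable"
        assert assign_specific_stable("G", "Q20-2M", 0.0, 0.51).classification \
            == "neither"

    def test_missing_stability_flagged(self):
        call = assign_specific_stable("G", "Q20-2M", 0.9, None)
        assert call.classification == "specific_only"
        assert call.stability_missing

    def test_grid_matches_two_threshold_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(200):
            saint = float(rng.uniform(0, 1))
            stab = float(rng.uniform(0, 1))
            call = assign_specific_stable("G", "g", saint, stab,
                                          saint_threshold=0.8,
                                          stability_threshold=0.75)
            spec = saint >= 0.8
            stable = stab >= 0.75
            expected = ("specific_stable" if spec and stable else
                        "specific_only" if spec else
                        "stable_only" if stable else "neither")
            assert call.classification == expected

    def test_threshold_range_enforced(self):
        with pytest.raises(InvalidThresholdError):
            assign_specific_stable("G", "g", 0.9, 0.9,
                                   stability_threshold=0.4)


class TestVenn:
    def test_disjoint(self):
        counts = venn_partition({"A": {1, 2}, "B": {3, 4, 5}})
        assert counts[frozenset({"A"})] == 2
        assert counts[frozenset({"B"})] == 3
        assert counts[frozenset({"A", "B"})] == 0

    def test_identical_sets(self):
        counts = venn_partition({"A": {1, 2}, "B": {1, 2}})
        assert counts[frozenset({"A", "B"})] == 2
        assert counts[frozenset({"A"})] == 0

    def test_counts_sum_to_union(self):
        rng = np.random.default_rng(31)
        sets = {
            lab: set(rng.choice(100, size=rng.integers(5, 40), replace=False))
            for lab in "ABCD"
        }
        counts = venn_partition(sets)
        assert sum(counts.values()) == len(set().union(*sets.values()))
        # every region equals brute-force membership enumeration
        for region, count in counts.items():
            expected = sum(
                1 for x in set().union(*sets.values())
                if all((x in sets[l]) == (l in region) for l in sets)
            )
            assert count == expected

    def test_too_many_sets(self):
        with pytest.raises(InvalidThresholdError):
            venn_partition({str(i): {i} for i in range(5)})
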