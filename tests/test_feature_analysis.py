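import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chromsig.data_model import ContactMatrix, PanelSample, SamplePanel
from chromsig.feature_analysis import (
    class_mean_maps,
    discretize_supervised,
    information_gain,
    rank_informative_contacts,
    scores_to_matrix,
    ttest_contacts,
)
from chromsig.synthetic import PlantedEffect, SimulationDesign, simulate_panel


def _panel(matrices, statuses):
    samples = [
        PanelSample(f"s{k}", m, st) for k, (m, st) in enumerate(zip(matrices, statuses))
    ]
    return SamplePanel(samples)


class TestClassMeanMaps:
    def test_identical_samples_mean_equals_sample(self):
        v = np.array([[np.nan, 3.0], [3.0, np.nan]])
        m = ContactMatrix.from_dense(v)
        panel = _panel([m, m.copy(), m.copy(), m.copy()], ["fusion"] * 2 + ["wt"] * 2)
        means, sems, diff = class_mean_maps(panel, "mll_status")
        assert means["fusion"].values[0, 1] == pytest.approx(3.0)
        assert diff.values[0, 1] == pytest.approx(0.0)

    def test_constant_difference_map(self):
        a = ContactMatrix.from_dense(np.full((3, 3), 4.0))
        b = ContactMatrix.from_dense(np.full((3, 3), 1.0))
        panel = _panel([a, a.copy(), b, b.copy()], ["fusion"] * 2 + ["wt"] * 2)
        _, _, diff = class_mean_maps(panel, "mll_status")
        assert np.allclose(diff.values, 3.0)

    def test_matches_brute_force_per_cell_average(self, rng):
        mats = [
            ContactMatrix.from_dense(
                0.5 * (a := rng.uniform(0, 9, (4, 4))) + 0.5 * a.T
            )
            for _ in range(6)
        ]
        statuses = ["fusion"] * 3 + ["wt"] * 3
        panel = _panel(mats, statuses)
        means, sems, diff = class_mean_maps(panel, "mll_status")
        for i in range(4):
            for j in range(4):
                manual = np.mean([m.values[i, j] for m in mats[:3]])
                assert means["fusion"].values[i, j] == pytest.approx(manual)
                manual_sem = np.std(
                    [m.values[i, j] for m in mats[:3]], ddof=1
                ) / math.sqrt(3)
                assert sems["fusion"].values[i, j] == pytest.approx(manual_sem)

    def test_cell_unmeasured_in_whole_class_is_unmeasured(self):
        v = np.full((3, 3), 2.0)
        holed = v.copy()
        holed[0, 2] = holed[2, 0] = np.nan
        panel = _panel(
            [ContactMatrix.from_dense(holed), ContactMatrix.from_dense(holed),
             ContactMatrix.from_dense(v), ContactMatrix.from_dense(v)],
            ["fusion", "fusion", "wt", "wt"],
        )
        means, _, diff = class_mean_maps(panel, "mll_status")
        assert not means["fusion"].mask[0, 2]
        assert not diff.mask[0, 2]


class TestDiscretization:
    def test_clean_split_yields_one_cut_between_groups(self):
        cuts = discretize_supervised([1, 1, 9, 9], ["A", "A", "B", "B"])
        assert len(cuts) == 1
        assert 1 < cuts[0] < 9

    def test_interleaved_labels_yield_no_cut(self):
        cuts = discretize_supervised([1, 2, 3, 4, 5, 6, 7, 8],
                                     ["A", "B", "A", "B", "A", "B", "A", "B"])
        assert cuts == []

    def test_constant_values_yield_no_cut(self):
        assert discretize_supervised([5, 5, 5, 5], ["A", "A", "B", "B"]) == []


def reference_information_gain(values, labels):
    """Independent re-derivation: plain-python recursive MDL discretization
    evaluating every boundary by direct entropy sums."""

    def H(labs):
        out = 0.0
        for c in set(labs):
            p = labs.count(c) / len(labs)
            out -= p * math.log2(p)
        return out

    def cuts_of(pairs):
        n = len(pairs)
        if n < 2 or H([l for _, l in pairs]) == 0:
            return []
        pairs = sorted(pairs, key=lambda t: t[0])
        vals = [v for v, _ in pairs]
        labs = [l for _, l in pairs]
        best = None
        for pos in range(1, n):
            if vals[pos] == vals[pos - 1]:
                continue
            e = (pos / n) * H(labs[:pos]) + ((n - pos) / n) * H(labs[pos:])
            if best is None or e < best[0] - 1e-12:
                best = (e, (vals[pos - 1] + vals[pos]) / 2, pos)
        if best is None:
            return []
        _, cut, pos = best
        left, right = pairs[:pos], pairs[pos:]
        ent, e1, e2 = H(labs), H(labs[:pos]), H(labs[pos:])
        gain = ent - (pos / n) * e1 - ((n - pos) / n) * e2
        k = len(set(labs))
        k1, k2 = len(set(labs[:pos])), len(set(labs[pos:]))
        delta = math.log2(3**k - 2) - (k * ent - k1 * e1 - k2 * e2)
        if gain <= (math.log2(n - 1) + delta) / n:
            return []
        return cuts_of(left) + [cut] + cuts_of(right)

    pairs = list(zip([float(v) for v in values], list(labels)))
    cuts = sorted(cuts_of(pairs))
    if not cuts:
        return 0.0
    labs = [l for _, l in pairs]
    n = len(pairs)
    h0 = H(labs)
    cond = 0.0
    edges = [-math.inf] + cuts + [math.inf]
    for lo, hi in zip(edges, edges[1:]):
        bucket = [l for v, l in pairs if lo < v <= hi]
        if bucket:
            cond += (len(bucket) / n) * H(bucket)
    return h0 - cond


class TestInformationGain:
    def test_perfect_balanced_split_is_one_bit(self):
        assert information_gain([1, 1, 9, 9], ["A", "A", "B", "B"]) == pytest.approx(1.0)

    def test_constant_feature_is_zero(self):
        assert information_gain([4, 4, 4, 4], ["A", "A", "B", "B"]) == 0.0

    def test_unbalanced_separating_feature(self):
        # H(2/5, 3/5) = 0.970951 bits, conditional entropy 0 after the cut
        expected = -(0.4 * math.log2(0.4) + 0.6 * math.log2(0.6))
        got = information_gain([1, 2, 8, 9, 10], ["A", "A", "B", "B", "B"])
        assert got == pytest.approx(expected, abs=1e-9)

    def test_bounded_by_log2_k(self, rng):
        for _ in range(20):
            vals = rng.normal(size=12)
            labs = rng.choice(["a", "b", "c"], size=12)
            ig = information_gain(vals, labs)
            assert 0.0 <= ig <= math.log2(3) + 1e-12

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        st.lists(st.integers(0, 5), min_size=4, max_size=12),
        st.data(),
    )
    def test_invariant_under_monotone_transforms(self, raw, data):
        labels = data.draw(
            st.lists(st.sampled_from(["A", "B"]), min_size=len(raw), max_size=len(raw))
        )
        vals = np.asarray(raw, dtype=float)
        base = information_gain(vals, labels)
        assert information_gain(3.0 * vals + 7.0, labels) == pytest.approx(base)
        assert information_gain(np.exp(vals / 5.0), labels) == pytest.approx(base)

    def test_matches_independent_rederivation_exhaustively(self):
        # every dataset with n <= 4 over values {0,1,2} and binary labels,
        # plus a random sample of larger ones
        for n in (2, 3, 4):
            for vals in itertools.product(range(3), repeat=n):
                for labs in itertools.product("AB", repeat=n):
                    got = information_gain(list(vals), list(labs))
                    want = reference_information_gain(list(vals), list(labs))
                    assert got == pytest.approx(want, abs=1e-9), (vals, labs)
        rng = np.random.default_rng(0)
        for _ in range(300):
            n = int(rng.integers(5, 9))
            vals = rng.integers(0, 4, size=n).tolist()
            labs = rng.choice(list("AB"), size=n).tolist()
            assert information_gain(vals, labs) == pytest.approx(
                reference_information_gain(vals, labs), abs=1e-9
            )


class TestTTest:
    def _two_class_panel(self, a_vals, b_vals, n=4):
        mats = [ContactMatrix.from_dense(np.full((n, n), v)) for v in a_vals + b_vals]
        return _panel(mats, ["fusion"] * len(a_vals) + ["wt"] * len(b_vals))

    def test_identical_groups_fail_with_p_one(self):
        panel = self._two_class_panel([2.0, 2.0], [2.0, 2.0])
        df = ttest_contacts(panel, "mll_status")
        assert np.allclose(df["t_stat"], 0.0)
        assert np.allclose(df["p_value"], 1.0)
        assert not df["passes"].any()

    def test_zero_variance_unequal_means_warns_and_passes(self, caplog):
        panel = self._two_class_panel([2.0, 2.0], [5.0, 5.0])
        with caplog.at_level("WARNING"):
            df = ttest_contacts(panel, "mll_status")
        assert np.allclose(df["p_value"], 0.0)
        assert df["passes"].all()
        assert any("zero variance" in r.message for r in caplog.records)

    def test_label_swap_flips_t_and_keeps_p(self, paper_panel):
        panel, _ = paper_panel
        df = ttest_contacts(panel, "mll_status")
        swapped = panel.with_labels(
            "mll_status",
            ["wt" if s == "fusion" else "fusion" for s in panel.labels("mll_status")],
        )
        df2 = ttest_contacts(swapped, "mll_status")
        assert np.allclose(df["t_stat"].to_numpy(), -df2["t_stat"].to_numpy())
        assert np.allclose(df["p_value"].to_numpy(), df2["p_value"].to_numpy())

    def test_planted_features_pass_filter(self):
        design = SimulationDesign(
            n_fragments=20,
            planted_effects=(
                PlantedEffect((3, 12), 3.0, "fusion"),
                PlantedEffect((5, 17), 3.0, "wt"),
            ),
            class_sizes=(("AF9", 15), ("wt", 15)),
            noise_sigma=0.2,
            efficiency_sigma=0.0,
            array_scale_range=(1.0, 1.0),
            seed=13,
        )
        panel, _ = simulate_panel(design)
        df = ttest_contacts(panel, "mll_status")
        planted = df[
            ((df.frag_i == 3) & (df.frag_j == 12)) | ((df.frag_i == 5) & (df.frag_j == 17))
        ]
        assert planted["passes"].all()


class TestRanking:
    def test_row_count_equals_feature_index_size(self, paper_panel):
        panel, _ = paper_panel
        df = rank_informative_contacts(panel, "mll_status")
        assert len(df) == 40 * 39 // 2

    def test_sorted_by_gain_with_pair_tiebreak(self, paper_panel):
        panel, _ = paper_panel
        df = rank_informative_contacts(panel, "mll_status")
        gains = df["info_gain_bits"].to_numpy()
        assert np.all(np.diff(gains) <= 1e-12)

    def test_informative_requires_both_criteria(self, paper_panel):
        panel, _ = paper_panel
        df = rank_informative_contacts(panel, "mll_status")
        assert (df["informative"] == (df["passes"] & (df["info_gain_bits"] > 0))).all()

    def test_scores_project_back_to_symmetric_grid(self, paper_panel):
        panel, _ = paper_panel
        df = rank_informative_contacts(panel, "mll_status")
        grid = scores_to_matrix(df, 40)
        assert np.allclose(np.nan_to_num(grid), np.nan_to_num(grid.T))
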