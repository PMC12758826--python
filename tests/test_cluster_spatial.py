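"""Threshold computation, cluster calling, lateralization map and
contiguity summaries against hand arithmetic and planted truth."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from l1mosaic import cluster_spatial as cs, synthetic as syn
from l1mosaic.cluster_spatial import CALL_BILATERAL, CALL_LEFT, CALL_NONE, CALL_RIGHT

L, R = cs.PSEUDO_LEFT, cs.PSEUDO_RIGHT


def make_counts(per_animal, genotype="L1-EGFP", n_sections=None):
    """Build a count table from {animal: {(section, hemisphere): count}}
    or {animal: total-spread-evenly} shorthand."""
    rows = []
    for animal, cells in per_animal.items():
        for (s, hemi), c in cells.items():
            rows.append(
                {
                    "animal_id": animal,
                    "genotype": genotype,
                    "age_months": 6.0,
                    "section_index": s,
                    "bregma_mm": 2.3 - 0.2 * s,
                    "hemisphere": hemi,
                    "gfp_count": c,
                }
            )
    return pd.DataFrame(rows)


def uniform_animal(total_per_cell, n_sections=2):
    return {(s, h): total_per_cell for s in range(n_sections) for h in (L, R)}


class TestThresholds:
    def test_hand_arithmetic(self):
        # per-animal totals {4, 6, 8}: mean 6, SD 2, threshold 12
        counts = make_counts(
            {
                "c1": {(0, L): 1, (0, R): 1, (1, L): 1, (1, R): 1},
                "c2": {(0, L): 2, (0, R): 2, (1, L): 1, (1, R): 1},
                "c3": {(0, L): 2, (0, R): 2, (1, L): 2, (1, R): 2},
            }
        )
        t = cs.compute_thresholds(counts)
        assert t.global_mean == pytest.approx(6.0)
        assert t.global_sd == pytest.approx(2.0)
        assert t.global_threshold == pytest.approx(12.0)
        # section 0 totals {2,4,4}: mean 10/3, sd 2/sqrt(3)... recompute
        sec0 = np.array([2, 4, 4], dtype=float)
        assert t.per_section_threshold[0] == pytest.approx(sec0.mean() + 3 * sec0.std(ddof=1))

    def test_identical_controls_degenerate_sd(self):
        counts = make_counts({f"c{i}": uniform_animal(2) for i in range(3)})
        t = cs.compute_thresholds(counts)
        assert t.global_sd == 0.0
        assert t.global_threshold == t.global_mean

    def test_single_control_rejected(self):
        counts = make_counts({"c1": uniform_animal(2)})
        with pytest.raises(ValueError, match="2 control"):
            cs.compute_thresholds(counts)

    def test_missing_section_named(self):
        counts = make_counts(
            {"c1": uniform_animal(2, 3), "c2": {(s, h): 2 for s in range(2) for h in (L, R)}}
        )
        with pytest.raises(ValueError, match="c2"):
            cs.compute_thresholds(counts)

    def test_matches_naive_recomputation(self):
        # independent plain-python recomputation on Poisson controls
        rng = np.random.default_rng(9)
        data = {
            f"c{i}": {(s, h): int(rng.poisson(2)) for s in range(14) for h in (L, R)}
            for i in range(10)
        }
        t = cs.compute_thresholds(make_counts(data), k_sd=3.0)
        totals = [sum(v.values()) for v in data.values()]
        mean = sum(totals) / len(totals)
        var = sum((x - mean) ** 2 for x in totals) / (len(totals) - 1)
        assert t.global_threshold == pytest.approx(mean + 3 * var**0.5)
        for s in range(14):
            sect = [d[(s, L)] + d[(s, R)] for d in data.values()]
            m = sum(sect) / len(sect)
            v = sum((x - m) ** 2 for x in sect) / (len(sect) - 1)
            assert t.per_section_threshold[s] == pytest.approx(m + 3 * v**0.5)

    def test_raising_k_sd_never_adds_calls(self, spatial_sim):
        counts = spatial_sim.counts
        controls = counts[counts["genotype"] == "L1-EGFP"]
        affected = counts[counts["genotype"] != "L1-EGFP"]
        previous = None
        for k in (1.0, 2.0, 3.0, 5.0, 10.0):
            t = cs.compute_thresholds(controls, k_sd=k)
            n_calls = sum(
                cs.call_animal(g, t).has_cluster for _, g in affected.groupby("animal_id")
            )
            if previous is not None:
                assert n_calls <= previous
            previous = n_calls


class TestAnimalCall:
    def _thresholds(self, value):
        return cs.ThresholdSet(
            global_threshold=value,
            per_section_threshold={0: 1.0, 1: 1.0},
            k_sd=3.0,
            control_n=3,
            global_mean=value,
            global_sd=0.0,
        )

    def test_tie_is_not_a_cluster(self):
        animal = make_counts({"a": uniform_animal(3)}, genotype="TDP43")
        assert cs.call_animal(animal, self._thresholds(12.0)).has_cluster is False
        assert cs.call_animal(animal, self._thresholds(11.9)).has_cluster is True

    def test_zero_total(self):
        animal = make_counts({"a": uniform_animal(0)}, genotype="TDP43")
        call = cs.call_animal(animal, self._thresholds(0.0))
        assert call.total == 0 and not call.has_cluster

    def test_planted_clusters_detected(self):
        hits = 0
        n_aff = 0
        for seed in range(20):
            sim = syn.simulate_section_counts(syn.SpatialSimConfig(seed=seed, n_affected=5))
            controls = sim.counts[sim.counts["genotype"] == "L1-EGFP"]
            t = cs.compute_thresholds(controls)
            for _, g in sim.counts[sim.counts["genotype"] != "L1-EGFP"].groupby("animal_id"):
                n_aff += 1
                hits += cs.call_animal(g, t).has_cluster
        assert hits / n_aff >= 0.95


class TestSectionCalls:
    def _thresholds(self, per_section):
        return cs.ThresholdSet(
            global_threshold=0.0,
            per_section_threshold=per_section,
            k_sd=3.0,
            control_n=3,
            global_mean=0.0,
            global_sd=0.0,
            bregma_mm={s: 2.3 - 0.2 * s for s in per_section},
        )

    def test_rule_application(self):
        # per-section threshold 7 -> hemisphere share 0.5 -> hemi cutoff 3.5
        animal = make_counts(
            {"a": {(0, L): 10, (0, R): 1, (1, L): 0, (1, R): 0, (2, L): 5, (2, R): 4}},
            genotype="TDP43",
        )
        out = cs.call_sections(animal, self._thresholds({0: 7.0, 1: 7.0, 2: 7.0}))
        assert list(out["call"]) == [CALL_LEFT, CALL_NONE, CALL_BILATERAL]
        assert list(out["size"]) == [10, 0, 9]

    def test_full_hemisphere_rule(self):
        animal = make_counts({"a": {(0, L): 5, (0, R): 4}}, genotype="TDP43")
        out = cs.call_sections(
            animal, self._thresholds({0: 4.5}), hemisphere_rule="full"
        )
        assert list(out["call"]) == [CALL_LEFT]

    def test_mirror_symmetry(self):
        rng = np.random.default_rng(4)
        cells = {(s, h): int(rng.poisson(3)) for s in range(5) for h in (L, R)}
        mirrored = {(s, R if h == L else L): c for (s, h), c in cells.items()}
        t = self._thresholds({s: 4.0 for s in range(5)})
        a = cs.call_sections(make_counts({"a": cells}, genotype="x"), t)
        b = cs.call_sections(make_counts({"a": mirrored}, genotype="x"), t)
        swap = {CALL_LEFT: CALL_RIGHT, CALL_RIGHT: CALL_LEFT}
        assert [swap.get(c, c) for c in a["call"]] == list(b["call"])
        assert list(a["size"]) == list(b["size"])

    def test_planted_laterality_recovered(self):
        correct = total = 0
        hemi2call = {L: CALL_LEFT, R: CALL_RIGHT}
        for seed in range(20):
            sim = syn.simulate_section_counts(syn.SpatialSimConfig(seed=seed))
            controls = sim.counts[sim.counts["genotype"] == "L1-EGFP"]
            t = cs.compute_thresholds(controls)
            for animal, g in sim.counts[sim.counts["genotype"] != "L1-EGFP"].groupby("animal_id"):
                calls = cs.call_sections(g, t).set_index("section_index")["call"]
                for _, row in sim.truth[sim.truth["animal_id"] == animal].iterrows():
                    total += 1
                    correct += calls[row["section_index"]] == hemi2call[row["hemisphere"]]
        assert correct / total >= 0.90

    def test_noiseless_cluster_exact(self):
        # zero control baseline: caller recovers exactly the planted span
        sim = syn.simulate_section_counts(
            syn.SpatialSimConfig(seed=3, control_rate=0.0, cluster_amplitude=20.0, n_affected=3)
        )
        controls = sim.counts[sim.counts["genotype"] == "L1-EGFP"]
        t = cs.compute_thresholds(controls)
        hemi2call = {L: CALL_LEFT, R: CALL_RIGHT}
        for animal, g in sim.counts[sim.counts["genotype"] != "L1-EGFP"].groupby("animal_id"):
            calls = cs.call_sections(g, t).set_index("section_index")["call"]
            planted = sim.truth[sim.truth["animal_id"] == animal]
            expected = {r["section_index"]: hemi2call[r["hemisphere"]] for _, r in planted.iterrows()}
            for s in range(14):
                assert calls[s] == expected.get(s, CALL_NONE)


class TestMapAndContiguity:
    def test_no_passing_animal_empty_map(self):
        counts = make_counts({"a": uniform_animal(0)}, genotype="TDP43")
        t = cs.ThresholdSet(100.0, {0: 5.0, 1: 5.0}, 3.0, 3, 50.0, 10.0)
        m = cs.build_map(counts, t)
        assert m.animals == []

    def test_single_animal_row_matches_call_sections(self, spatial_sim):
        counts = spatial_sim.counts
        controls = counts[counts["genotype"] == "L1-EGFP"]
        t = cs.compute_thresholds(controls)
        one = counts[counts["animal_id"] == "aff_00"]
        m = cs.build_map(one, t)
        direct = cs.call_sections(one, t)
        assert list(m.calls.loc["aff_00"]) == list(direct["call"])
        assert list(m.sizes.loc["aff_00"]) == list(direct["size"])

    def test_sizes_bounded_by_animal_totals(self, spatial_sim):
        counts = spatial_sim.counts
        controls = counts[counts["genotype"] == "L1-EGFP"]
        affected = counts[counts["genotype"] != "L1-EGFP"]
        m = cs.build_map(affected, cs.compute_thresholds(controls))
        totals = affected.groupby("animal_id")["gfp_count"].sum()
        for animal in m.animals:
            assert m.sizes.loc[animal].sum() <= totals[animal]

    def test_hand_counted_contiguity(self):
        calls = pd.DataFrame(
            [[CALL_LEFT, CALL_LEFT, CALL_LEFT, CALL_NONE, CALL_RIGHT]], index=["a"]
        )
        sizes = pd.DataFrame([[3, 4, 5, 0, 2]], index=["a"])
        m = cs.LateralizationMap(calls, sizes, {})
        s = cs.summarize_contiguity(m).iloc[0]
        assert s["n_runs"] == 2
        assert s["max_run_length"] == 3
        assert s["unilateral_fraction"] == pytest.approx(0.75)
        assert s["total_size"] == 14

    def test_all_none(self):
        m = cs.LateralizationMap(
            pd.DataFrame([[CALL_NONE] * 4], index=["a"]),
            pd.DataFrame([[0] * 4], index=["a"]),
            {},
        )
        s = cs.summarize_contiguity(m).iloc[0]
        assert s["n_runs"] == 0 and s["max_run_length"] == 0

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from([CALL_NONE, CALL_LEFT, CALL_RIGHT, CALL_BILATERAL]),
                    min_size=1, max_size=14))
    def test_run_count_matches_naive_scan(self, calls):
        m = cs.LateralizationMap(
            pd.DataFrame([calls], index=["a"]),
            pd.DataFrame([[1] * len(calls)], index=["a"]),
            {},
        )
        s = cs.summarize_contiguity(m).iloc[0]
        # brute-force run counter
        runs = []
        for c in calls:
            if c != CALL_NONE:
                if runs and runs[-1][-1] is True:
                    runs[-1].append(True)
                else:
                    runs.append([True])
            else:
                if runs:
                    runs[-1].append(False)
        lengths = [sum(1 for x in r if x) for r in runs if any(r)]
        assert s["n_runs"] == len(lengths)
        assert s["max_run_length"] == (max(lengths) if lengths else 0)

    def test_layouts_separate(self):
        # unilateral-contiguous cohorts show longer runs, fewer runs and
        # higher laterality consistency than bilateral-small cohorts
        import scipy.stats as ss

        summaries = {}
        for layout in (syn.LAYOUT_UNILATERAL, syn.LAYOUT_BILATERAL):
            frames = []
            for seed in range(5):
                sim = syn.simulate_section_counts(
                    syn.SpatialSimConfig(seed=seed, layout=layout, n_affected=10)
                )
                controls = sim.counts[sim.counts["genotype"] == "L1-EGFP"]
                aff = sim.counts[sim.counts["genotype"] != "L1-EGFP"]
                m = cs.build_map(aff, cs.compute_thresholds(controls))
                frames.append(cs.summarize_contiguity(m))
            summaries[layout] = pd.concat(frames)
        uni = summaries[syn.LAYOUT_UNILATERAL]
        bi = summaries[syn.LAYOUT_BILATERAL]
        assert len(uni) >= 45 and len(bi) >= 45
        p_run = ss.mannwhitneyu(uni["max_run_length"], bi["max_run_length"]).pvalue
        assert p_run < 0.05
        assert uni["max_run_length"].median() > bi["max_run_length"].median()
        assert uni["n_runs"].median() < bi["n_runs"].median()
        assert uni["unilateral_fraction"].mean() > bi["unilateral_fraction"].mean()


class TestCompareCounts:
    def test_identical_groups_flat(self):
        rep = cs.compare_counts({"a": [3, 4, 5], "b": [3, 4, 5]})
        assert rep["anova"]["F"] == pytest.approx(0.0)
        assert rep["anova"]["pvalue"] == pytest.approx(1.0, abs=1e-9)

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 20) ** 2  # nonnegative counts-like data
        b = rng.normal(5, 1, 20) ** 2
        rep = cs.compare_counts({"lo": a, "hi": b})
        assert rep["anova"]["pvalue"] < 0.001
        assert rep["posthoc"][0]["pvalue"] < 0.001

    def test_hand_sized_anova(self):
        # lambda=1, offset=0 makes Box-Cox an affine map: F unchanged
        rep = cs.compare_counts(
            {"g1": [1, 2, 3], "g2": [4, 5, 6], "g3": [7, 8, 9]},
            lambda_bc=1.0,
            offset=0.0,
        )
        # hand ANOVA on raw data: between SS 54, within SS 6 -> F = 27
        assert rep["anova"]["F"] == pytest.approx(27.0)

    def test_short_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            cs.compare_counts({"a": [1], "b": [1, 2]})
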