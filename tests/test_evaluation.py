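"""Metrics, fold construction, cross-validation and trade-off curves."""

import math

import numpy as np
import pandas as pd
import pytest

from mostsim.curation import CuratedPair, TargetPanel, temporal_new_pairs
from mostsim.evaluation import (
    ConfusionCounts,
    accuracy,
    confusion_from_trace,
    cross_validate,
    mcc,
    sevenfold_split,
    temporal_validate,
    tradeoff_curve,
)
from mostsim.models import ModelSpec
from mostsim.simulate import GeneratorConfig, generate_panel


def brute_force_mcc(tp, tn, fp, fn):
    num = tp * tn - fp * fn
    den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return 0.0 if den == 0 else num / den


class TestMetrics:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            (ConfusionCounts(9, 1, 0, 0), 1.0),
            (ConfusionCounts(90, 5, 3, 2), 0.95),
            (ConfusionCounts(0, 0, 1, 1), 0.0),
        ],
    )
    def test_accuracy_examples(self, counts, expected):
        assert accuracy(counts) == pytest.approx(expected)

    def test_accuracy_undefined_for_empty_counts(self):
        with pytest.raises(ValueError):
            accuracy(ConfusionCounts())

    def test_mcc_examples(self):
        assert mcc(ConfusionCounts(10, 20, 0, 0)) == pytest.approx(1.0)
        assert mcc(ConfusionCounts(5, 5, 5, 5)) == pytest.approx(0.0)
        assert mcc(ConfusionCounts(90, 5, 3, 2)) == pytest.approx(
            brute_force_mcc(90, 5, 3, 2)
        )

    def test_mcc_zero_margin_convention(self):
        assert mcc(ConfusionCounts(10, 0, 0, 5)) == 0.0

    def test_metrics_against_formula_on_random_counts(self):
        rng = np.random.default_rng(2)
        for _ in range(300):
            tp, tn, fp, fn = rng.integers(0, 200, 4)
            c = ConfusionCounts(int(tp), int(tn), int(fp), int(fn))
            assert mcc(c) == brute_force_mcc(tp, tn, fp, fn)
            assert -1.0 <= mcc(c) <= 1.0
            if c.total:
                assert accuracy(c) == (tp + tn) / (tp + tn + fp + fn)


class TestSevenfoldSplit:
    def test_partition_is_disjoint_and_covers(self, small_panel):
        splits = sevenfold_split(small_panel, seed=1)
        assert len(splits) == 7
        for t in small_panel.targets:
            all_ids = {p.ligand_id for p in small_panel.ligands(t)}
            test_sets = [
                {p.ligand_id for p in test.ligands(t)} for _, test in splits
            ]
            union = set().union(*test_sets)
            assert union == all_ids
            assert sum(len(s) for s in test_sets) == len(all_ids)  # pairwise disjoint
            for train, test in splits:
                train_ids = {p.ligand_id for p in train.ligands(t)}
                assert train_ids.isdisjoint({p.ligand_id for p in test.ligands(t)})
                assert train_ids | {p.ligand_id for p in test.ligands(t)} == all_ids

    def test_fourteen_ligands_give_two_per_fold(self):
        panel = TargetPanel([CuratedPair("T", f"L{i:02d}", "CCO", 6.0) for i in range(14)])
        splits = sevenfold_split(panel, seed=0)
        assert [len(test.ligands("T")) for _, test in splits] == [2] * 7

    def test_same_seed_reproduces_split(self, small_panel):
        a = sevenfold_split(small_panel, seed=9)
        b = sevenfold_split(small_panel, seed=9)
        for (_, ta), (_, tb) in zip(a, b):
            assert [p.ligand_id for p in ta.pairs()] == [p.ligand_id for p in tb.pairs()]

    def test_resample15_draws_fifteen_percent(self):
        panel = TargetPanel([CuratedPair("T", f"L{i:02d}", "CCO", 6.0) for i in range(40)])
        splits = sevenfold_split(panel, seed=3, mode="resample15")
        for _, test in splits:
            assert len(test.ligands("T")) == 6  # round(0.15 * 40)

    def test_unknown_mode_rejected(self, small_panel):
        with pytest.raises(ValueError):
            sevenfold_split(small_panel, seed=0, mode="loocv")


@pytest.fixture(scope="module")
def summary(small_panel, cache):
    spec = ModelSpec(activity_mode="explicit", threshold=6.0, seed=20170311)
    return cross_validate(small_panel, spec, cache=cache)


class TestCrossValidate:
    def test_learns_planted_association(self, summary, small_sim):
        # strong similarity/potency signal: far better than the base rate
        base = max(small_sim.truth.label.mean(), 1 - small_sim.truth.label.mean())
        assert summary.accuracy_mean > max(0.85, base)
        assert summary.mcc_mean > 0.5

    def test_summary_matches_per_fold_values(self, summary):
        accs = [f.accuracy for f in summary.folds]
        mccs = [f.mcc for f in summary.folds]
        assert summary.accuracy_mean == pytest.approx(np.mean(accs))
        assert summary.accuracy_sd == pytest.approx(np.std(accs, ddof=1))
        assert summary.mcc_mean == pytest.approx(np.mean(mccs))
        assert summary.mcc_sd == pytest.approx(np.std(mccs, ddof=1))

    def test_fold_metrics_recomputable_from_trace(self, summary):
        for fold in summary.folds:
            counts = confusion_from_trace(fold.trace)
            assert counts == fold.counts
            assert fold.accuracy == pytest.approx(accuracy(counts))
            assert fold.mcc == pytest.approx(mcc(counts))

    def test_each_ligand_tested_exactly_once(self, summary, small_panel):
        trace = summary.pooled_trace
        keys = list(zip(trace.target_id, trace.ligand_id))
        assert len(keys) == len(set(keys)) == small_panel.n_pairs()

    def test_reproducible_with_same_seed(self, summary, small_panel):
        spec = ModelSpec(activity_mode="explicit", threshold=6.0, seed=20170311)
        again = cross_validate(small_panel, spec)
        pd.testing.assert_frame_equal(summary.pooled_trace, again.pooled_trace)

    def test_explicit_and_implicit_share_neighbor_pairs(self, small_panel, summary, cache):
        """The two activity encodings differ only downstream of identical
        nearest-neighbor searches."""
        spec = ModelSpec(activity_mode="implicit", threshold=6.0, seed=20170311)
        implicit = cross_validate(small_panel, spec, cache=cache)
        cols = ["target_id", "ligand_id", "nn_ligand_id", "tc_most", "pki_most", "truth"]
        pd.testing.assert_frame_equal(
            summary.pooled_trace[cols], implicit.pooled_trace[cols]
        )


class TestTemporalValidate:
    def test_empty_new_pairs_give_zero_counts(self, small_panel, cache):
        spec = ModelSpec(seed=1)
        result = temporal_validate(small_panel, [], spec, cache=cache)
        assert result.counts.total == 0 and math.isnan(result.accuracy)

    def test_known_ligand_resurfaces_with_unit_similarity(self, small_panel, cache):
        spec = ModelSpec(seed=1)
        old = small_panel.ligands(small_panel.targets[0])[0]
        new = CuratedPair(old.target_id, "brand_new_id", old.smiles, old.pki)
        result = temporal_validate(small_panel, [new], spec, cache=cache)
        assert result.trace.iloc[0].tc_most == 1.0

    def test_pair_on_unknown_target_skipped(self, small_panel, cache):
        spec = ModelSpec(seed=1)
        stray = CuratedPair("no_such_target", "L", "CCO", 7.0)
        result = temporal_validate(small_panel, [stray], spec, cache=cache)
        assert result.counts.total == 0 and result.n_skipped == 1

    def test_counts_match_hand_enumeration_on_two_release_fixture(self, cache):
        """Hold out a third of each target's probes as the 'new release';
        every held-out pair must be scored exactly once."""
        sim = generate_panel(GeneratorConfig(seed=77, n_targets=6), cache=cache)
        truth = sim.truth
        probes = truth[truth.role == "probe"]
        held = probes.groupby("target_id", group_keys=False).head(4)
        held_keys = set(zip(held.target_id, held.ligand_id))
        old = sim.panel.subset(
            {
                t: [
                    p.ligand_id
                    for p in sim.panel.ligands(t)
                    if (t, p.ligand_id) not in held_keys
                ]
                for t in sim.panel.targets
            }
        )
        new_pairs = temporal_new_pairs(old, sim.panel)
        assert {(p.target_id, p.ligand_id) for p in new_pairs} == held_keys
        spec = ModelSpec(activity_mode="explicit", threshold=6.0, seed=77)
        result = temporal_validate(old, new_pairs, spec, cache=cache)
        assert result.counts.total == len(held_keys)
        truth_map = {
            (r.target_id, r.ligand_id): r.label for r in held.itertuples(index=False)
        }
        for row in result.trace.itertuples(index=False):
            assert row.truth == truth_map[(row.target_id, row.ligand_id)]


class TestTradeoffCurve:
    @pytest.fixture()
    def six_records(self):
        # hand-built: 3 TPs, 2 FPs, 1 FN
        return pd.DataFrame(
            {
                "tc_most": [0.9, 0.8, 0.3, 0.95, 0.2, 0.5],
                "p_value": [0.05, 0.2, 0.4, 0.45, 0.1, 0.3],
                "truth": [1, 1, 1, 0, 0, 1],
                "predicted": [1, 1, 1, 1, 1, 0],
            }
        )

    def test_tc_axis_fractions_match_manual_counting(self, six_records):
        curve = tradeoff_curve(six_records, "tc", thresholds=[0.0, 0.5, 0.85, 1.1])
        # TPs at tc {0.9, 0.8, 0.3}; FPs at tc {0.95, 0.2}
        assert curve.f_tp == pytest.approx([1.0, 2 / 3, 1 / 3, 0.0])
        assert curve.f_fp == pytest.approx([1.0, 1 / 2, 1 / 2, 0.0])

    def test_pvalue_axis_fractions_match_manual_counting(self, six_records):
        curve = tradeoff_curve(six_records, "pvalue", thresholds=[0.5, 0.15, 0.01])
        # TPs at p {0.05, 0.2, 0.4}; FPs at p {0.45, 0.1}
        assert curve.f_tp == pytest.approx([1.0, 1 / 3, 0.0])
        assert curve.f_fp == pytest.approx([1.0, 1 / 2, 0.0])

    def test_no_filter_keeps_everything(self, six_records):
        curve = tradeoff_curve(six_records, "tc")
        assert curve.f_tp[0] == 1.0 and curve.f_fp[0] == 1.0
        assert curve.f_tp[-1] == 0.0 and curve.f_fp[-1] == 0.0  # k > max tc

    def test_fractions_monotone_as_filter_tightens(self, small_panel, cache):
        spec = ModelSpec(activity_mode="explicit", threshold=6.0, seed=20170311)
        trace = cross_validate(small_panel, spec, cache=cache).pooled_trace
        tc = tradeoff_curve(trace, "tc")
        pv = tradeoff_curve(trace, "pvalue")
        for arr in (tc.f_tp, tc.f_fp, pv.f_tp, pv.f_fp):
            vals = arr[~np.isnan(arr)]
            assert np.all(np.diff(vals) <= 1e-12)

    def test_absent_class_reported_as_nan_not_zero(self):
        no_fp = pd.DataFrame(
            {"tc_most": [0.9], "p_value": [0.1], "truth": [1], "predicted": [1]}
        )
        curve = tradeoff_curve(no_fp, "tc", thresholds=[0.0, 0.5])
        assert np.all(np.isnan(curve.f_fp))
        assert curve.f_tp == pytest.approx([1.0, 1.0])

    def test_unknown_axis_rejected(self, six_records):
        with pytest.raises(ValueError):
            tradeoff_curve(six_records, "zaxis")
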