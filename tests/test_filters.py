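"""Marker-filter cascade: stage rules, telescoping, symmetry, idempotence."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from homeoscan.config import RunConfig
from homeoscan.dosage import call_dosage
from homeoscan.filters import (
    FilterConfig,
    exclude_noisy_samples,
    filter_complete,
    filter_controls,
    filter_modal_rule,
    filter_replicates,
    modal_scores,
    run_cascade,
    standardize_orientation,
)
from homeoscan.genome import build_marker_map, implant_events
from homeoscan.scenario import build_cohort
from homeoscan.simulate import ArrayNoise, simulate_array


def _frame(rows: dict[str, list], columns: list[str]) -> pd.DataFrame:
    return pd.DataFrame.from_dict(rows, orient="index", columns=columns, dtype=float)


CONTROL_COLS = ["adu", "aip", "m11a", "m11b", "m31", "m13"]
CONTROL_ROLES = pd.Series(
    {
        "adu": "A_parent",
        "aip": "B_parent",
        "m11a": "mix_1_1",
        "m11b": "mix_1_1",
        "m31": "mix_3_1",
        "m13": "mix_1_3",
    }
)


class TestStageRules:
    def test_complete_scoring(self):
        scores = _frame({"m1": [2, np.nan], "m2": [2, 2]}, ["p1", "p2"])
        keep = filter_complete(scores, ["p1", "p2"])
        assert not keep["m1"] and keep["m2"]
        with pytest.raises(ValueError, match="lineage"):
            filter_complete(scores, [])

    @pytest.mark.parametrize(
        "row, kept, reason",
        [
            ([3, 1, 2, 2, 3, 1], True, None),  # the canonical good marker
            ([2, 1, 2, 2, 3, 1], False, "parent_separation_lt_2"),
            ([3, 1, 3, 3, 3, 1], False, "mix11_modal_not_2"),
            ([3, 1, 2, 2, 3, 3], False, "mix31_equals_mix13"),
            ([3, 1, 2, 3, 3, 1], False, "controls_not_uniform"),
            ([4, 0, 2, 2, 3, 1], True, None),
        ],
    )
    def test_control_consistency(self, row, kept, reason):
        scores = _frame({"m": row}, CONTROL_COLS)
        keep, reasons = filter_controls(scores, CONTROL_ROLES)
        assert bool(keep["m"]) is kept
        if reason:
            assert reasons["m"] == reason

    def test_missing_control_role_errors(self):
        scores = _frame({"m": [3, 1]}, ["adu", "aip"])
        with pytest.raises(ValueError, match="missing control role"):
            filter_controls(scores, CONTROL_ROLES[["adu", "aip"]])

    def test_replicate_concordance(self):
        scores = _frame({"m1": [2, 2], "m2": [2, 3], "m3": [2, np.nan]}, ["a", "a_rep"])
        keep = filter_replicates(scores, [("a", "a_rep")])
        assert keep["m1"] and not keep["m2"] and not keep["m3"]
        with pytest.raises(ValueError, match="unpaired"):
            filter_replicates(scores, [("a", "ghost")])

    def test_misscored_replicate_cell_always_removed(self):
        # brute force over the mis-score model: a swap always lands on a
        # different score, so a single mis-scored replicate cell guarantees
        # discordance (removal probability 1 >= 0.5)
        for wrong in range(5):
            if wrong == 2:
                continue
            scores = _frame({"m": [2.0, float(wrong)]}, ["a", "a_rep"])
            assert not filter_replicates(scores, [("a", "a_rep")])["m"]


class TestModalRule:
    @pytest.fixture()
    def mm(self):
        from homeoscan.genome import GenomeLayout

        return build_marker_map(
            GenomeLayout(n_sets=1, set_length=500_000, markers_per_set=5),
            b_high_frac=0.0, seed=0,
        )

    def test_isolated_deviation_dropped_adjacent_kept(self, mm):
        lineage = ["p1", "p2", "p3"]
        # markers 0,4 modal 2; marker 1 isolated modal 3; markers 2,3 modal 3
        data = {
            mm.index[0]: [2, 2, 2],
            mm.index[1]: [3, 3, 2],
            mm.index[2]: [3, 3, 3],
            mm.index[3]: [4, 3, 3],
            mm.index[4]: [2, 2, 2],
        }
        scores = _frame(data, lineage)
        # runs need same direction, not same value: markers 2 and 3 (modal 3)
        keep = filter_modal_rule(scores.drop(index=mm.index[1]), lineage, mm)
        assert keep.tolist() == [True, True, True, True]
        keep_all = filter_modal_rule(scores, lineage, mm)
        # 1,2,3 all deviate toward A and are consecutive: a length-3 run
        assert keep_all.tolist() == [True, True, True, True, True]
        # but an isolated deviant flanked by modal-2 markers is dropped
        isolated = _frame(
            {
                mm.index[0]: [2, 2, 2],
                mm.index[1]: [3, 3, 3],
                mm.index[2]: [2, 2, 2],
            },
            lineage,
        )
        keep_iso = filter_modal_rule(isolated, lineage, mm)
        assert keep_iso.tolist() == [True, False, True]

    def test_opposite_directions_do_not_chain(self, mm):
        lineage = ["p1", "p2", "p3"]
        scores = _frame(
            {
                mm.index[0]: [3, 3, 3],
                mm.index[1]: [1, 1, 1],
                mm.index[2]: [2, 2, 2],
            },
            lineage,
        )
        keep = filter_modal_rule(scores, lineage, mm)
        assert keep.tolist() == [False, False, True]

    def test_flip_restores_directional_coherence(self, mm):
        # raw scores 3 and 1 on adjacent markers of opposite orientation are
        # the *same* subgenome deviation and must chain into a run
        lineage = ["p1", "p2", "p3"]
        scores = _frame(
            {
                mm.index[0]: [3, 3, 3],
                mm.index[1]: [1, 1, 1],
                mm.index[2]: [2, 2, 2],
            },
            lineage,
        )
        flip = pd.Series([False, True, False], index=scores.index)
        keep = filter_modal_rule(scores, lineage, mm, flip=flip)
        assert keep.tolist() == [True, True, True]

    def test_all_modal_2_all_kept(self, mm):
        scores = _frame({m: [2, 2, 2] for m in mm.index}, ["p1", "p2", "p3"])
        assert filter_modal_rule(scores, ["p1", "p2", "p3"], mm).all()


class TestOrientation:
    def test_flip_and_identity(self):
        scores = _frame({"flip_me": [0, 4, 1], "keep_me": [4, 0, 3]},
                        ["adu", "aip", "p1"])
        roles = pd.Series({"adu": "A_parent", "aip": "B_parent", "p1": "lineage"})
        oriented, keep, reasons = standardize_orientation(scores, roles)
        assert keep.all() and not reasons
        assert oriented.loc["flip_me"].tolist() == [4, 0, 3]
        assert oriented.loc["keep_me"].tolist() == [4, 0, 3]

    def test_equal_parents_unorientable(self):
        scores = _frame({"m": [2, 2, 3]}, ["adu", "aip", "p1"])
        roles = pd.Series({"adu": "A_parent", "aip": "B_parent", "p1": "lineage"})
        oriented, keep, reasons = standardize_orientation(scores, roles)
        assert not keep["m"] and reasons["m"] == "unorientable_equal_parents"
        assert "m" not in oriented.index

    def test_mixture_ordering_postcondition_on_cohort(self, zero_noise_study):
        cascade = zero_noise_study.genotype.cascade
        scores = cascade.calls.scores
        roles = zero_noise_study.cohort.signals.roles
        m31 = [s for s in scores.columns if roles.get(s) == "mix_3_1"]
        m13 = [s for s in scores.columns if roles.get(s) == "mix_1_3"]
        assert ((scores[m31].mean(axis=1) - scores[m13].mean(axis=1)) > 0).all()


class TestSampleExclusion:
    def test_scattered_noise_dropped_event_carrier_kept(
        self, small_pedigree, small_marker_map, small_layout
    ):
        carrier = small_pedigree.by_generation(2)[0]
        events = implant_events(
            small_pedigree,
            [{"plant": carrier.label, "kind": "ABBB", "chrom_set": 2,
              "start": 0, "end": 1_000_000, "heritable": False}],
            layout=small_layout,
        )
        noisy = small_pedigree.by_generation(3)[-1].label
        sig = simulate_array(
            small_pedigree, events, small_marker_map,
            noise=ArrayNoise.none(), seed=0,
            extra_cell_noise={noisy: 0.3},
        )
        calls = call_dosage(sig)
        cascade = run_cascade(
            calls, sig.roles, sig.replicate_pairs, small_marker_map, FilterConfig()
        )
        assert noisy in cascade.report.excluded_samples
        assert carrier.label in cascade.lineage_samples


class TestCascade:
    def test_telescoping_and_counts(self, default_noise_study):
        report = default_noise_study.genotype.cascade.report
        report.validate_telescoping()
        frame = report.to_frame()
        assert (frame["markers_in"] - frame["markers_out"] == frame["dropped"]).all()

    def test_zero_noise_drops_nothing(self, zero_noise_study):
        report = zero_noise_study.genotype.cascade.report
        assert report.to_frame()["dropped"].sum() == 0
        assert len(zero_noise_study.genotype.cascade.calls.scores) == 1400

    def test_implanted_bad_markers_all_removed_clean_mostly_kept(self):
        # quality rules only: no missing calls, so completeness is neutral
        cfg = RunConfig(
            seed=9,
            noise=ArrayNoise(missing_rate=0.0),
            n_qc_fail_samples=0,
            n_noisy_samples=0,
        )
        cohort = build_cohort(cfg)
        calls = call_dosage(cohort.signals)
        cascade = run_cascade(
            calls, cohort.signals.roles, cohort.signals.replicate_pairs,
            cohort.marker_map, FilterConfig(),
        )
        kept = set(cascade.calls.scores.index)
        bad = set(cohort.signals.bad_markers)
        assert not (kept & bad), "every implanted bad marker must be removed"
        clean = set(cohort.marker_map.index) - bad
        assert len(kept & clean) / len(clean) >= 0.99

    def test_idempotent(self, zero_noise_study):
        first = zero_noise_study.genotype.cascade
        cohort = zero_noise_study.cohort
        again = run_cascade(
            first.calls,
            cohort.signals.roles[first.calls.samples],
            cohort.signals.replicate_pairs,
            cohort.marker_map,
            FilterConfig(),
        )
        assert again.calls.scores.equals(first.calls.scores)
        assert not again.report.excluded_samples

    def test_ab_relabel_symmetry(self, small_pedigree, small_marker_map, small_layout):
        """Renaming the subgenomes (theta -> 1-theta plus swapped control
        roles) must retain the same markers with oriented scores s -> 4-s."""
        carrier = small_pedigree.by_generation(1)[0]
        events = implant_events(
            small_pedigree,
            [{"plant": carrier.label, "kind": "ABBB", "chrom_set": 2,
              "start": 0, "end": 1_000_000, "heritable": True}],
            layout=small_layout,
        )
        sig = simulate_array(
            small_pedigree, events, small_marker_map, noise=ArrayNoise.none(), seed=0
        )
        swap = {"A_parent": "B_parent", "B_parent": "A_parent",
                "mix_3_1": "mix_1_3", "mix_1_3": "mix_3_1"}
        mirrored = type(sig)(
            theta=1.0 - sig.theta,
            intensity=sig.intensity,
            roles=sig.roles.map(lambda r: swap.get(r, r)),
            replicate_pairs=sig.replicate_pairs,
        )
        res_a = run_cascade(
            call_dosage(sig), sig.roles, sig.replicate_pairs, small_marker_map,
            FilterConfig(exclude_noisy_samples=False),
        )
        res_b = run_cascade(
            call_dosage(mirrored), mirrored.roles, sig.replicate_pairs,
            small_marker_map, FilterConfig(exclude_noisy_samples=False),
        )
        assert list(res_a.calls.scores.index) == list(res_b.calls.scores.index)
        lin = res_a.lineage_samples
        assert res_b.calls.scores[lin].equals(4.0 - res_a.calls.scores[lin])
        # the event region reads ABBB in one labeling and AAAB in the other
        region = res_a.marker_map.index[res_a.marker_map["chrom_set"] == 2]
        assert (res_a.lineage_scores.loc[region, carrier.label] == 1).all()
        assert (res_b.calls.scores.loc[region, carrier.label] == 3).all()

    def test_complete_filter_matches_binomial_expectation(
        self, small_pedigree, small_marker_map
    ):
        miss = 0.02
        sig = simulate_array(
            small_pedigree, [], small_marker_map,
            noise=ArrayNoise(0, 0, 0, 0, missing_rate=miss), seed=21,
        )
        calls = call_dosage(sig)
        lineage = sig.lineage_samples
        kept = filter_complete(calls.scores, lineage)
        n, m = len(lineage), len(small_marker_map)
        p_keep = (1 - miss) ** n
        se = np.sqrt(p_keep * (1 - p_keep) / m)
        assert abs(kept.mean() - p_keep) < 3 * se + 1e-9


def test_modal_scores_ties_break_toward_two():
    scores = _frame({"m": [1, 1, 3, 3]}, ["a", "b", "c", "d"])
    assert modal_scores(scores)["m"] == 1  # 1 is closer in preference order
    scores2 = _frame({"m": [2, 2, 3, 3]}, ["a", "b", "c", "d"])
    assert modal_scores(scores2)["m"] == 2
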