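"""Run calling, background separation, inheritance tracing, rate arithmetic."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from homeoscan.events import (
    EventCall,
    call_runs,
    classify_background,
    compute_rate,
    trace_inheritance,
)
from homeoscan.genome import GenomeLayout, build_marker_map
from homeoscan.pedigree import Pedigree, parse_plant_id


@pytest.fixture(scope="module")
def mm():
    return build_marker_map(
        GenomeLayout(n_sets=2, set_length=1_000_000, markers_per_set=10),
        b_high_frac=0.0, seed=0,
    )


def _row(mm, values_by_set):
    row = pd.Series(2.0, index=mm.index)
    for cs, vals in values_by_set.items():
        idx = mm.index[mm["chrom_set"] == cs]
        row[idx] = vals
    return row


class TestCallRuns:
    def test_whole_set_abbb(self, mm):
        row = _row(mm, {2: 1.0})
        calls = call_runs("p", row, mm)
        assert len(calls) == 1
        (c,) = calls
        assert c.composition == "ABBB" and c.chrom_set == 2 and c.n_markers == 10
        assert c.start == int(mm[mm["chrom_set"] == 2]["position"].iloc[0])
        assert c.end == int(mm[mm["chrom_set"] == 2]["position"].iloc[-1]) + 1

    def test_all_euploid_row_has_no_calls(self, mm):
        assert call_runs("p", _row(mm, {}), mm) == []

    def test_singleton_deviation_ignored(self, mm):
        row = _row(mm, {})
        row[mm.index[3]] = 3.0
        assert call_runs("p", row, mm) == []

    def test_flagged_run_is_deletion_candidate(self, mm):
        # the array miscall: terminal score-3 run whose intensity collapsed
        row = _row(mm, {})
        region = mm.index[:4]
        row[region] = 3.0
        flags = pd.Series(False, index=mm.index)
        flags[region[:2]] = True  # 50% coverage is enough
        (c,) = call_runs("p", row, mm, flags_row=flags)
        assert c.composition == "DELETION_CANDIDATE"
        assert c.n_markers == 4

    def test_missing_breaks_runs(self, mm):
        row = _row(mm, {})
        row[mm.index[0]] = 4.0
        row[mm.index[1]] = np.nan
        row[mm.index[2]] = 4.0
        assert call_runs("p", row, mm) == []

    def test_min_run_must_be_at_least_two(self, mm):
        with pytest.raises(ValueError, match="min_run"):
            call_runs("p", _row(mm, {}), mm, min_run=1)

    def test_unordered_markers_error(self, mm):
        shuffled = mm.sample(frac=1.0, random_state=0)
        row = _row(mm, {2: 1.0})[shuffled.index]
        with pytest.raises(ValueError, match="unordered"):
            call_runs("p", row, shuffled)


def _call(plant, cs=1, start=0, end=100, comp="ABBB", status=None):
    return EventCall(plant, cs, start, end, comp, n_markers=2, status=status)


class TestClassifyBackground:
    def test_cohort_wide_composition_is_background(self):
        calls = [_call(f"p{i}") for i in range(10)]
        out = classify_background(calls, n_plants=10)
        assert all(c.status == "background" for c in out)

    def test_unique_composition_is_candidate(self):
        calls = [_call("p0")] + [_call(f"p{i}", comp="AAAA") for i in range(1, 10)]
        out = classify_background(calls, n_plants=10)
        assert out[0].status == "candidate"
        assert all(c.status == "background" for c in out[1:])

    def test_reference_profile_mode(self):
        calls = [_call("p0", cs=3, start=0, end=500), _call("p0", cs=4)]
        out = classify_background(
            calls, n_plants=1, reference_profile=[(3, 0, 1000, "ABBB")]
        )
        assert out[0].status == "background" and out[1].status == "candidate"

    def test_empty_input_gives_empty_output(self):
        assert classify_background([], n_plants=5) == []


@pytest.fixture(scope="module")
def ped():
    labels = [
        "T.1_G1", "T.2_G1",
        "T.1.1_G1", "T.2.1_G1",
        "T.1.1.1_G1", "T.2.1.1_G1",
    ]
    return Pedigree(parse_plant_id(lab) for lab in labels)


class TestTraceInheritance:

    def test_origin_then_inherited(self, ped):
        cand = [
            _call("T.1_G1", status="candidate"),
            _call("T.1.1_G1", status="candidate"),
            _call("T.1.1.1_G1", status="candidate"),
        ]
        final, ledger = trace_inheritance(cand, ped)
        assert [c.status for c in final] == ["novel", "inherited", "inherited"]
        assert len(ledger) == 1 and ledger[0].plant == "T.1_G1"

    def test_transient_event_counts_once(self, ped):
        cand = [_call("T.1.1_G1", status="candidate")]
        final, ledger = trace_inheritance(cand, ped)
        assert final[0].status == "novel" and len(ledger) == 1

    def test_disjoint_subtrees_are_independent_origins(self, ped):
        cand = [
            _call("T.1.1_G1", status="candidate"),
            _call("T.2.1_G1", status="candidate"),
        ]
        _, ledger = trace_inheritance(cand, ped)
        assert len(ledger) == 2

    def test_different_composition_not_inherited(self, ped):
        cand = [
            _call("T.1_G1", comp="ABBB", status="candidate"),
            _call("T.1.1_G1", comp="AAAA", status="candidate"),
        ]
        _, ledger = trace_inheritance(cand, ped)
        assert len(ledger) == 2

    def test_missing_plant_errors(self, ped):
        with pytest.raises(KeyError, match="ghost"):
            trace_inheritance([_call("T.9.9_G1".replace("9.9", "ghost"))], ped)

    def test_novel_count_matches_ledger(self, default_noise_study):
        g = default_noise_study.genotype
        n_novel = sum(1 for c in g.final_calls if c.status == "novel")
        assert n_novel == len(g.ledger) == g.rate.n_events


class TestComputeRate:
    @pytest.mark.parametrize(
        "origins, plants, expected",
        [
            (3, 233, 1.3),
            (9, 166, 5.4),
            (2, 202, 1.0),
            (8, 202, 4.0),
            (0, 100, 0.0),
            (1, 40, 2.5),  # exact half rounds away from zero
        ],
    )
    def test_printed_rates(self, origins, plants, expected):
        assert compute_rate(origins, plants).rate_percent == expected

    def test_invalid_inputs_error(self):
        with pytest.raises(ValueError):
            compute_rate(1, 0)
        with pytest.raises(ValueError):
            compute_rate(-1, 10)
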