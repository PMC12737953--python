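"""WGS dosage: site selection, baseline normalization, window classes,
reconciliation with array calls."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from homeoscan.events import EventCall
from homeoscan.genome import implant_events
from homeoscan.simulate import ReadCounts, default_sites, simulate_wgs
from homeoscan.wgs import (
    classify_sample,
    normalize_counts,
    reconcile,
    select_sites,
    window_classify,
)


class TestSelectSites:
    def _cand(self, **kw):
        base = {
            "a_allele": "G", "a_consensus": 1.0, "a_depth": 10,
            "b_allele": "T", "b_consensus": 1.0, "b_depth": 10,
        }
        base.update(kw)
        return pd.DataFrame([base])

    def test_clean_divergent_site_kept(self):
        assert len(select_sites(self._cand())) == 1

    def test_equal_alleles_dropped(self):
        assert len(select_sites(self._cand(b_allele="G"))) == 0

    def test_low_consensus_dropped(self):
        assert len(select_sites(self._cand(a_consensus=0.9))) == 0
        assert len(select_sites(self._cand(a_consensus=0.95))) == 1

    def test_min_depth(self):
        assert len(select_sites(self._cand(b_depth=0))) == 0
        assert len(select_sites(self._cand(b_depth=0), min_depth=0)) == 1

    def test_empty_result_allowed(self):
        empty = self._cand().iloc[:0]
        assert len(select_sites(empty)) == 0


class TestNormalizeCounts:
    def test_baseline_against_itself_is_exactly_two(self, small_pedigree, sites):
        rc = simulate_wgs([small_pedigree.plants[0]], [], sites, depth=50, seed=0)
        norm = normalize_counts(rc, rc.baseline)
        assert (norm["norm_a"] == 2.0).all()
        assert (norm["norm_b"] == 2.0).all()

    def test_zero_baseline_sites_masked(self, small_pedigree, sites):
        rc = simulate_wgs([small_pedigree.plants[0]], [], sites, depth=5, seed=0)
        norm = normalize_counts(rc, small_pedigree.labels[0])
        base_ok = (rc.raw_a[rc.baseline] > 0) & (rc.raw_b[rc.baseline] > 0)
        assert len(norm) == int(base_ok.sum())

    def test_no_usable_sites_errors(self, small_pedigree, sites):
        rc = simulate_wgs([small_pedigree.plants[0]], [], sites, depth=5, seed=0)
        rc.raw_a[rc.baseline] = 0
        with pytest.raises(ValueError, match="usable"):
            normalize_counts(rc, small_pedigree.labels[0])

    def test_mean_normalized_counts_converge_to_copies(
        self, small_pedigree, small_layout
    ):
        # invariant: per-composition means approach (a, b) as depth grows.
        # the per-site ratio estimator has an O(1/depth) upward bias (~1% at
        # depth 200, halving each doubling), so the panel is sized such that
        # Monte-Carlo error dominates that known remainder at this depth
        origin = small_pedigree.by_generation(1)[0]
        events = implant_events(
            small_pedigree,
            [{"plant": origin.label, "kind": "ABBB", "chrom_set": 2,
              "start": 0, "end": 1_000_000, "heritable": False}],
            layout=small_layout,
        )
        panel = default_sites(small_layout, spacing=6000, seed=1)
        rc = simulate_wgs([origin], events, panel, depth=200, seed=2)
        norm = normalize_counts(rc, origin.label)
        for cs, (ea, eb) in ((1, (2.0, 2.0)), (2, (1.0, 3.0))):
            sub = norm[norm["chrom_set"] == cs]
            se_a = sub["norm_a"].std() / np.sqrt(len(sub))
            se_b = sub["norm_b"].std() / np.sqrt(len(sub))
            assert abs(sub["norm_a"].mean() - ea) < 3 * se_a
            assert abs(sub["norm_b"].mean() - eb) < 3 * se_b

    def test_depth_rescaling_is_absorbed(self, small_pedigree, sites):
        plant = small_pedigree.plants[0]
        rc = simulate_wgs([plant], [], sites, depth=30, seed=3)
        scaled = ReadCounts(
            rc.sites, rc.raw_a.assign(**{plant.label: rc.raw_a[plant.label] * 5}),
            rc.raw_b.assign(**{plant.label: rc.raw_b[plant.label] * 5}),
        )
        a = classify_sample(rc, plant.label, min_sites=5)
        b = classify_sample(scaled, plant.label, min_sites=5)
        assert (a["composition"] == b["composition"]).all()


class TestWindowClassify:
    def _normalized(self, centers, n=30, cs=1):
        rows = []
        for w, (a, b) in enumerate(centers):
            for i in range(n):
                rows.append(
                    {"chrom_set": cs, "position": w * 1_000_000 + i * 1000,
                     "norm_a": a, "norm_b": b}
                )
        return pd.DataFrame(rows)

    @pytest.mark.parametrize(
        "center, expected",
        [
            ((2.01, 1.98), "AABB"),
            ((1.95, 0.04), "AA_DELETION"),
            ((1.02, 2.97), "ABBB"),
            ((2.9, 1.1), "AAAB"),
            ((0.1, 3.8), "BBBB"),
            ((3.1, 2.1), "TRISOMY_A"),
            ((2.5, 2.5), "UNCLASSIFIED"),  # equidistant and out of tolerance
        ],
    )
    def test_center_assignment(self, center, expected):
        out = window_classify(self._normalized([center]))
        assert out.loc[0, "composition"] == expected

    def test_sparse_window_unclassified(self):
        out = window_classify(self._normalized([(2.0, 2.0)], n=10), min_sites=20)
        assert out.loc[0, "composition"] == "UNCLASSIFIED"

    def test_bad_window_size_errors(self):
        with pytest.raises(ValueError, match="window_size"):
            window_classify(self._normalized([(2, 2)]), window_size=0)

    def test_euploid_conservation(self, small_pedigree, sites):
        plant = small_pedigree.plants[0]
        rc = simulate_wgs([plant], [], sites, depth=30, seed=4)
        w = classify_sample(rc, plant.label, min_sites=5)
        assert ((w["norm_a"] + w["norm_b"] - 4.0).abs() < 0.7).all()

    def test_ab_swap_mirrors_classes(self, small_pedigree, small_layout):
        origin = small_pedigree.by_generation(1)[0]
        events = implant_events(
            small_pedigree,
            [
                {"plant": origin.label, "kind": "ABBB", "chrom_set": 1,
                 "start": 0, "end": 1_000_000, "heritable": False},
                {"plant": origin.label, "kind": "DELETION_B", "chrom_set": 2,
                 "start": 0, "end": 1_000_000, "heritable": False},
            ],
            layout=small_layout,
        )
        dense = default_sites(small_layout, spacing=2000, seed=5)
        rc = simulate_wgs([origin], events, dense, depth=30, seed=6)
        swapped = ReadCounts(rc.sites, rc.raw_b, rc.raw_a)
        w = classify_sample(rc, origin.label)
        ws = classify_sample(swapped, origin.label)
        mirror = {
            "AABB": "AABB", "ABBB": "AAAB", "AAAB": "ABBB", "AAAA": "BBBB",
            "BBBB": "AAAA", "AA_DELETION": "BB_DELETION",
            "BB_DELETION": "AA_DELETION", "TRISOMY_A": "TRISOMY_B",
            "TRISOMY_B": "TRISOMY_A", "UNCLASSIFIED": "UNCLASSIFIED",
        }
        assert ws["composition"].tolist() == [
            mirror[c] for c in w["composition"]
        ]


class TestReconcile:
    def _windows(self, comp, cs=1, n=3):
        return pd.DataFrame(
            [
                {"chrom_set": cs, "start": w * 1_000_000, "end": (w + 1) * 1_000_000,
                 "n_sites": 100, "norm_a": 2.0, "norm_b": 0.0, "composition": comp}
                for w in range(n)
            ]
        )

    def test_array_miscalled_deletion_relabeled(self):
        call = EventCall("p", 1, 0, 3_000_000, "AAAB", 40, status="novel")
        out = reconcile([call], self._windows("AA_DELETION"), "p")
        assert out.loc[0, "verdict"] == "relabeled"
        assert out.loc[0, "final_composition"] == "DELETION_B"

    def test_agreeing_composition_confirmed(self):
        call = EventCall("p", 1, 0, 3_000_000, "ABBB", 40, status="novel")
        out = reconcile([call], self._windows("ABBB"), "p")
        assert out.loc[0, "verdict"] == "confirmed"

    def test_no_overlap_is_no_coverage(self):
        call = EventCall("p", 5, 0, 3_000_000, "ABBB", 40, status="novel")
        out = reconcile([call], self._windows("ABBB", cs=1), "p")
        assert out.loc[0, "verdict"] == "no_coverage"
        assert out.loc[0, "final_composition"] == "ABBB"

    def test_disagreement_is_conflict(self):
        call = EventCall("p", 1, 0, 3_000_000, "AAAA", 40, status="novel")
        out = reconcile([call], self._windows("BBBB"), "p")
        assert out.loc[0, "verdict"] == "conflict"

    def test_wrong_plant_errors(self):
        call = EventCall("q", 1, 0, 1, "ABBB", 2)
        with pytest.raises(ValueError, match="reconcile"):
            reconcile([call], self._windows("ABBB"), "p")
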