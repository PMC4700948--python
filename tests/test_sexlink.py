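"""Coverage-based and marker-based X/autosome assignment."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hemix import sexlink
from hemix.io_tables import CoverageRecord, MarkerHit
from hemix.sexlink import (
    AUTOSOME,
    EXCLUDED,
    X,
    InsufficientDataError,
    LinkageModel,
    assign_by_markers,
    classify_scaffolds,
    estimate_autosomal_mode,
    gene_linkage,
    log2_coverage_ratio,
    stringent_classify,
)
from hemix.simulate import SimulationConfig, simulate_coverage


class TestLog2Ratio:
    @pytest.mark.parametrize(
        "male,female,expected",
        [(10.0, 10.0, 0.0), (5.0, 10.0, -1.0), (20.0, 10.0, 1.0)],
    )
    def test_finite_ratios(self, male, female, expected):
        assert log2_coverage_ratio(CoverageRecord("s", male, female)) == pytest.approx(expected)

    @pytest.mark.parametrize("male,female", [(0.0, 7.0), (7.0, 0.0), (0.0, 0.0)])
    def test_zero_coverage_is_excluded(self, male, female):
        assert log2_coverage_ratio(CoverageRecord("s", male, female)) is None


class TestAutosomalMode:
    def test_two_spike_mixture(self):
        ratios = [0.0] * 90 + [-1.0] * 10
        model = estimate_autosomal_mode(ratios, bin_width=0.1)
        assert abs(model.a_median) <= 0.05  # within half a bin of the big spike
        assert model.threshold == pytest.approx(model.a_median - 0.5)

    def test_single_spike(self):
        model = estimate_autosomal_mode([0.3] * 25, bin_width=0.1)
        assert abs(model.a_median - 0.3) <= 0.05

    def test_gaussian_mixture_mode_recovered(self, rng):
        # known mixture: 90% N(0, 0.1) + 10% N(-1, 0.1) -> mode at 0
        ratios = np.concatenate(
            [rng.normal(0.0, 0.1, 9000), rng.normal(-1.0, 0.1, 1000)]
        )
        model = estimate_autosomal_mode(ratios, bin_width=0.05)
        assert abs(model.a_median) < 0.05

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            estimate_autosomal_mode([0.1], bin_width=0.05)

    def test_tie_broken_toward_zero_with_warning(self):
        ratios = [-1.02, -1.03, 0.02, 0.03]  # two bins of two at width 0.1
        with pytest.warns(UserWarning, match="tie"):
            model = estimate_autosomal_mode(ratios, bin_width=0.1)
        assert abs(model.a_median) < 0.1

    def test_weights_can_move_the_mode(self):
        ratios = [0.0] * 5 + [-1.0] * 5
        weighted = estimate_autosomal_mode(ratios, 0.1, weights=[1] * 5 + [10] * 5)
        assert abs(weighted.a_median - (-1.0)) <= 0.051  # within half a bin


class TestClassification:
    model = LinkageModel(a_median=0.0)

    @pytest.mark.parametrize(
        "ratio,expected",
        [(-1.0, X), (-0.75, X), (-0.25, AUTOSOME), (0.0, AUTOSOME), (0.75, AUTOSOME)],
    )
    def test_interior_calls(self, ratio, expected):
        rec = CoverageRecord("s", 10 * 2.0**ratio, 10.0)
        (call,) = classify_scaffolds([rec], self.model)
        assert call.linkage == expected

    def test_ratio_exactly_at_threshold_is_autosomal(self):
        # threshold sits at 0 for a_median = 0.5; equal coverage gives an
        # exact 0 ratio, which is "not less than" the cut -> autosome
        model = LinkageModel(a_median=0.5)
        (call,) = classify_scaffolds([CoverageRecord("s", 10.0, 10.0)], model)
        assert call.log2_mf_coverage == 0.0 and call.linkage == AUTOSOME

    def test_zero_coverage_scaffold_excluded(self):
        (call,) = classify_scaffolds([CoverageRecord("s", 0.0, 5.0)], self.model)
        assert call.linkage == EXCLUDED and math.isnan(call.log2_mf_coverage)

    def test_mixture_recovers_x_fraction(self):
        cfg = SimulationConfig(n_scaffolds=5000, x_fraction=0.10, seed=5)
        records, truth = simulate_coverage(cfg)
        ratios = [r for r in map(log2_coverage_ratio, records) if r is not None]
        calls = classify_scaffolds(records, estimate_autosomal_mode(ratios))
        called = [c for c in calls if c.linkage != EXCLUDED]
        est = sum(c.linkage == X for c in called) / len(called)
        true_frac = sum(v == X for v in truth.values()) / len(truth)
        assert est == pytest.approx(true_frac, abs=0.02)

    def test_stringent_margin_zero_excludes_only_boundary(self):
        # threshold at an exactly representable 0 (a_median = 0.5)
        model = LinkageModel(a_median=0.5)
        records = [
            CoverageRecord("at_thresh", 10.0, 10.0),
            CoverageRecord("below", 5.0, 10.0),
            CoverageRecord("above", 20.0, 10.0),
        ]
        loose = {c.scaffold_id: c.linkage for c in classify_scaffolds(records, model)}
        strict = {c.scaffold_id: c.linkage for c in stringent_classify(records, model, 0.0)}
        assert loose == {"at_thresh": AUTOSOME, "below": X, "above": AUTOSOME}
        assert strict == {"at_thresh": EXCLUDED, "below": X, "above": AUTOSOME}

    def test_stringent_band_excludes_intermediate(self):
        rec = CoverageRecord("s", 10 * 2.0**-0.6, 10.0)
        (call,) = stringent_classify([rec], self.model, margin=0.25)
        assert call.linkage == EXCLUDED

    def test_stringent_mixture_recovers_fraction_among_called(self):
        cfg = SimulationConfig(n_scaffolds=5000, x_fraction=0.10, seed=6)
        records, _ = simulate_coverage(cfg)
        ratios = [r for r in map(log2_coverage_ratio, records) if r is not None]
        calls = stringent_classify(records, estimate_autosomal_mode(ratios), margin=0.25)
        called = [c for c in calls if c.linkage != EXCLUDED]
        est = sum(c.linkage == X for c in called) / len(called)
        assert est == pytest.approx(0.10, abs=0.02)


class TestProperties:
    coverage_records = st.lists(
        st.builds(
            CoverageRecord,
            scaffold_id=st.uuids().map(str),
            male_coverage=st.floats(0, 100, allow_nan=False),
            female_coverage=st.floats(0, 100, allow_nan=False),
        ),
        min_size=1,
        max_size=30,
        unique_by=lambda r: r.scaffold_id,
    )

    @given(coverage_records)
    def test_partition_every_scaffold_called_once(self, records):
        model = LinkageModel(a_median=0.0)
        calls = classify_scaffolds(records, model)
        assert [c.scaffold_id for c in calls] == [r.scaffold_id for r in records]
        assert all(c.linkage in (X, AUTOSOME, EXCLUDED) for c in calls)

    @given(
        st.floats(0.01, 100, allow_nan=False),
        st.floats(0.01, 100, allow_nan=False),
        st.floats(0.1, 0.99),
    )
    def test_lowering_male_coverage_never_moves_x_to_autosome(self, male, female, factor):
        model = LinkageModel(a_median=0.0)
        (before,) = classify_scaffolds([CoverageRecord("s", male, female)], model)
        (after,) = classify_scaffolds([CoverageRecord("s", male * factor, female)], model)
        if before.linkage == X:
            assert after.linkage == X

    def test_shift_equivariance(self, rng):
        ratios = np.concatenate([rng.normal(0, 0.1, 900), rng.normal(-1, 0.1, 100)])
        shift = 0.7
        base = estimate_autosomal_mode(ratios, 0.05)
        shifted = estimate_autosomal_mode(ratios + shift, 0.05)
        assert shifted.a_median == pytest.approx(base.a_median + shift, abs=0.05)
        # classifications against the shifted model are unchanged
        records = [CoverageRecord(f"s{i}", 10 * 2.0**r, 10.0) for i, r in enumerate(ratios)]
        shifted_records = [
            CoverageRecord(f"s{i}", 10 * 2.0 ** (r + shift), 10.0)
            for i, r in enumerate(ratios)
        ]
        base_calls = [c.linkage for c in classify_scaffolds(records, base)]
        shifted_calls = [c.linkage for c in classify_scaffolds(shifted_records, shifted)]
        assert base_calls == shifted_calls

    def test_parameter_recovery_across_fractions(self):
        # fuller 100-replicate sweep at the harshest noise level lives in
        # the acceptance suite; this covers the default conditions
        for frac in (0.05, 0.10, 0.15):
            for seed in range(10):
                cfg = SimulationConfig(n_scaffolds=1000, x_fraction=frac, seed=seed)
                records, truth = simulate_coverage(cfg)
                ratios = [r for r in map(log2_coverage_ratio, records) if r is not None]
                calls = classify_scaffolds(records, estimate_autosomal_mode(ratios))
                called = [c for c in calls if c.linkage != EXCLUDED]
                est = sum(c.linkage == X for c in called) / len(called)
                true_frac = sum(v == X for v in truth.values()) / len(truth)
                assert est == pytest.approx(true_frac, abs=0.02)


def marker(marker_id, end, scaffold, evalue, cls=X):
    return MarkerHit(marker_id, end, scaffold, evalue, cls)


class TestMarkerAssignment:
    def test_unambiguous_marker(self):
        hits = [marker("m1", "forward", "s1", 1e-20), marker("m1", "reverse", "s1", 1e-18)]
        assert assign_by_markers(hits).assignments == {"s1": X}

    def test_only_scaffold_hit_by_both_ends_wins(self):
        hits = [
            marker("m1", "forward", "s1", 1e-10),
            marker("m1", "forward", "s2", 1e-30),  # better hit, but one end only
            marker("m1", "reverse", "s1", 1e-9),
        ]
        assert assign_by_markers(hits).assignments == {"s1": X}

    def test_lowest_combined_evalue_wins(self):
        hits = [
            marker("m1", "forward", "s1", 1e-30),
            marker("m1", "reverse", "s1", 1e-28),
            marker("m1", "forward", "s2", 1e-10),
            marker("m1", "reverse", "s2", 1e-9),
        ]
        assert assign_by_markers(hits).assignments == {"s1": X}

    def test_combined_evalue_matches_enumeration_oracle(self, rng):
        # random multi-scaffold hits; oracle ranks candidates by summed e-value
        scaffolds = [f"s{i}" for i in range(6)]
        hits = []
        per_scaffold: dict[str, dict[str, float]] = {}
        for s in scaffolds:
            fwd, rev = rng.uniform(1e-30, 1e-5, 2)
            per_scaffold[s] = {"forward": fwd, "reverse": rev}
            hits.append(marker("m", "forward", s, fwd))
            hits.append(marker("m", "reverse", s, rev))
        expected = min(
            scaffolds, key=lambda s: per_scaffold[s]["forward"] + per_scaffold[s]["reverse"]
        )
        assert assign_by_markers(hits).assignments == {expected: X}

    def test_single_end_marker_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="both primer ends"):
            result = assign_by_markers([marker("m1", "forward", "s1", 1e-20)])
        assert result.assignments == {} and result.skipped[0][0] == "m1"

    def test_conflicting_marker_classes_reported(self):
        hits = [
            marker("mx", "forward", "s1", 1e-20, X),
            marker("mx", "reverse", "s1", 1e-20, X),
            marker("ma", "forward", "s1", 1e-20, AUTOSOME),
            marker("ma", "reverse", "s1", 1e-20, AUTOSOME),
        ]
        with pytest.warns(UserWarning, match="conflicting"):
            result = assign_by_markers(hits)
        assert "s1" not in result.assignments and "s1" in result.conflicts


class TestGeneLinkage:
    def test_genes_inherit_scaffold_class_and_excluded_propagates(self):
        calls = [
            sexlink.LinkageCall("s1", -1.0, X),
            sexlink.LinkageCall("s2", 0.0, AUTOSOME),
            sexlink.LinkageCall("s3", math.nan, EXCLUDED),
        ]
        locations = {"g1": "s1", "g2": "s2", "g3": "s3", "g4": "unplaced"}
        assert gene_linkage(locations, calls) == {
            "g1": X, "g2": AUTOSOME, "g3": EXCLUDED, "g4": EXCLUDED,
        }
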