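"""Plan model: serialization round-trips, validation, and the two plan
edits (bank-error injection, gantry collapse)."""

import json

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import arcqa
from arcqa.plan import MAX_CROSSPLANE_CM


def assert_plans_close(p, q, edge_atol=5e-7, mu_atol=1e-8):
    assert p.plan_id == q.plan_id
    assert p.n_leaf_pairs == q.n_leaf_pairs
    assert p.variant_label == q.variant_label
    assert p.delivery_mode == q.delivery_mode
    assert len(p.control_points) == len(q.control_points)
    for a, b in zip(p.control_points, q.control_points):
        assert a.index == b.index
        assert a.gantry_angle_deg == pytest.approx(b.gantry_angle_deg,
                                                   abs=edge_atol)
        assert a.mu_weight == pytest.approx(b.mu_weight, abs=mu_atol)
        np.testing.assert_allclose(a.bankA_edges, b.bankA_edges,
                                   atol=edge_atol)
        np.testing.assert_allclose(a.bankB_edges, b.bankB_edges,
                                   atol=edge_atol)


class TestSerialization:
    def test_round_trip_identity(self, seeded_plan, tmp_path):
        path = tmp_path / "plan.json"
        arcqa.write_plan(seeded_plan, path)
        assert_plans_close(arcqa.read_plan(path), seeded_plan)

    def test_forty_leaf_pairs_read_back(self, seeded_plan, tmp_path):
        path = tmp_path / "plan.json"
        arcqa.write_plan(seeded_plan, path)
        plan = arcqa.read_plan(path)
        assert plan.n_leaf_pairs == 40
        assert all(cp.bankA_edges.shape == (40,)
                   for cp in plan.control_points)

    def test_crossed_edges_rejected_with_pair_indices(self, seeded_plan,
                                                      tmp_path):
        path = tmp_path / "bad.json"
        arcqa.write_plan(seeded_plan, path)
        doc = json.loads(path.read_text())
        doc["control_points"][0]["bankA_edges"][19] = 9.0  # beyond B_19
        path.write_text(json.dumps(doc))
        with pytest.raises(arcqa.PlanValidationError, match=r"\b19\b"):
            arcqa.read_plan(path)

    def test_missing_key_names_field(self, seeded_plan, tmp_path):
        path = tmp_path / "bad.json"
        arcqa.write_plan(seeded_plan, path)
        doc = json.loads(path.read_text())
        del doc["control_points"][3]["mu_weight"]
        path.write_text(json.dumps(doc))
        with pytest.raises(arcqa.PlanSchemaError, match="mu_weight"):
            arcqa.read_plan(path)

    def test_csv_export_row_count(self, seeded_plan, tmp_path):
        path = tmp_path / "plan.csv"
        arcqa.export_plan_csv(seeded_plan, path)
        n_rows = len(path.read_text().splitlines())
        assert n_rows == 1 + len(seeded_plan.control_points) * 40


class TestInjectBankError:
    def test_zero_offset_changes_only_label(self, seeded_plan):
        out = arcqa.inject_bank_error(
            seeded_plan, arcqa.PerturbationSpec(offset_cm=0.0))
        assert out.variant_label == "MLC1PE"
        for a, b in zip(seeded_plan.control_points, out.control_points):
            assert np.array_equal(a.bankA_edges, b.bankA_edges)
            assert np.array_equal(a.bankB_edges, b.bankB_edges)

    def test_bank_a_edges_shift_open_and_widths_grow(self, seeded_plan):
        out = arcqa.inject_bank_error(
            seeded_plan, arcqa.PerturbationSpec(offset_cm=0.1))
        for cp0, cp1 in zip(seeded_plan.control_points, out.control_points):
            open_ = cp0.open_pairs
            np.testing.assert_allclose(
                cp1.bankA_edges[open_], cp0.bankA_edges[open_] - 0.1)
            assert np.array_equal(cp1.bankB_edges, cp0.bankB_edges)
            w0 = cp0.bankB_edges[open_] - cp0.bankA_edges[open_]
            w1 = cp1.bankB_edges[open_] - cp1.bankA_edges[open_]
            np.testing.assert_allclose(w1 - w0, 0.1)
            # parked pairs stay closed
            closed = ~open_
            assert np.array_equal(cp1.bankA_edges[closed],
                                  cp1.bankB_edges[closed])

    def test_aperture_area_bookkeeping(self, seeded_plan):
        """Summed aperture area grows by offset x leaf width x n_open,
        both analytically and by rasterization integral."""
        offset = 0.1
        out = arcqa.inject_bank_error(
            seeded_plan, arcqa.PerturbationSpec(offset_cm=offset))
        cp0 = seeded_plan.control_points[10]
        cp1 = out.control_points[10]
        n_open = int(cp0.open_pairs.sum())
        area0 = float(np.sum(cp0.bankB_edges - cp0.bankA_edges))
        area1 = float(np.sum(cp1.bankB_edges - cp1.bankA_edges))
        assert area1 - area0 == pytest.approx(offset * 1.0 * n_open)
        grid = arcqa.GridSpec(0.05, 13.5)
        i0 = arcqa.rasterize_aperture(cp0, grid).integral_cm2
        i1 = arcqa.rasterize_aperture(cp1, grid).integral_cm2
        assert i1 - i0 == pytest.approx(offset * 1.0 * n_open, rel=1e-9)

    def test_offset_beyond_travel_raises(self, seeded_plan):
        with pytest.raises(arcqa.LeafRangeError):
            arcqa.inject_bank_error(
                seeded_plan,
                arcqa.PerturbationSpec(offset_cm=MAX_CROSSPLANE_CM))

    @given(a=st.floats(-0.2, 0.2), b=st.floats(-0.2, 0.2))
    def test_offsets_compose_additively(self, seeded_plan, a, b):
        spec = arcqa.PerturbationSpec
        once = arcqa.inject_bank_error(seeded_plan, spec(offset_cm=a + b))
        twice = arcqa.inject_bank_error(
            arcqa.inject_bank_error(seeded_plan, spec(offset_cm=a)),
            spec(offset_cm=b))
        for p, q in zip(once.control_points, twice.control_points):
            np.testing.assert_allclose(p.bankA_edges, q.bankA_edges,
                                       atol=1e-12)

    def test_bank_b_convention(self, seeded_plan):
        out = arcqa.inject_bank_error(
            seeded_plan, arcqa.PerturbationSpec(bank="B", offset_cm=0.1))
        for cp0, cp1 in zip(seeded_plan.control_points, out.control_points):
            open_ = cp0.open_pairs
            np.testing.assert_allclose(
                cp1.bankB_edges[open_], cp0.bankB_edges[open_] + 0.1)
            assert np.array_equal(cp1.bankA_edges, cp0.bankA_edges)


class TestCollapseGantry:
    def test_all_angles_zero(self, seeded_plan):
        out = arcqa.collapse_gantry(seeded_plan)
        assert all(cp.gantry_angle_deg == 0.0 for cp in out.control_points)
        assert out.delivery_mode == "collapsed"

    def test_idempotent(self, seeded_plan):
        once = arcqa.collapse_gantry(seeded_plan)
        assert arcqa.collapse_gantry(once) == once

    def test_leaves_mu_and_edges_untouched(self, seeded_plan):
        out = arcqa.collapse_gantry(seeded_plan)
        for a, b in zip(seeded_plan.control_points, out.control_points):
            assert a.mu_weight == b.mu_weight
            assert np.array_equal(a.bankA_edges, b.bankA_edges)
            assert np.array_equal(a.bankB_edges, b.bankB_edges)

    def test_commutes_with_injection(self, seeded_plan):
        spec = arcqa.PerturbationSpec(offset_cm=0.1)
        left = arcqa.collapse_gantry(arcqa.inject_bank_error(seeded_plan,
                                                             spec))
        right = arcqa.inject_bank_error(arcqa.collapse_gantry(seeded_plan),
                                        spec)
        assert left == right


class TestValidation:
    def test_unnormalized_mu_rejected(self, seeded_plan):
        import dataclasses
        cps = [dataclasses.replace(cp, mu_weight=cp.mu_weight * 2)
               for cp in seeded_plan.control_points]
        bad = dataclasses.replace(seeded_plan, control_points=cps)
        with pytest.raises(arcqa.PlanValidationError, match="MU"):
            bad.validate()

    def test_collapsed_mode_with_nonzero_angle_rejected(self, seeded_plan):
        import dataclasses
        bad = dataclasses.replace(seeded_plan, delivery_mode="collapsed")
        with pytest.raises(arcqa.PlanValidationError):
            bad.validate()
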