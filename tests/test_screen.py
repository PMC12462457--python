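"""Plate normalization, robust Z-scores and hit calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from senoscreen.screen import (
    DegenerateDistributionError,
    PlateNormalizationError,
    analyze_screen,
    call_hits,
    intersect_hits,
    normalize_to_vehicle,
    robust_z,
    score_screen,
    summarize_replicates,
)
from senoscreen.synthetic import design_screen_layout, gen_screen_plates, make_screen_truth

from conftest import brute_median_mad


class TestRobustZ:
    def test_worked_vector(self):
        # median 1.0, raw MAD 0.1 -> z(0.1) = -9
        values = [0.1, 0.2, 1.0, 1.0, 1.0, 1.1, 5.0]
        z = robust_z(values)
        assert z[0] == pytest.approx(-9.0)

    def test_median_value_scores_zero(self):
        z = robust_z([1.0, 2.0, 3.0, 4.0, 5.0])
        assert z[2] == 0.0

    def test_translation_invariance(self, rng):
        x = rng.normal(0, 1, 50)
        assert np.allclose(robust_z(x + 17.0), robust_z(x))

    def test_matches_sortbased_oracle(self, rng):
        for _ in range(20):
            x = rng.normal(0, 1, int(rng.integers(5, 40)))
            med, mad = brute_median_mad(list(x))
            assert np.allclose(robust_z(x), (x - med) / mad)

    def test_output_has_zero_median_unit_mad(self, rng):
        z = robust_z(rng.normal(3, 2, 101))
        assert np.median(z) == pytest.approx(0.0)
        assert np.median(np.abs(z - np.median(z))) == pytest.approx(1.0)

    def test_scaled_mad_option(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 10.0])
        assert np.allclose(robust_z(x, scaled=True) * 1.4826, robust_z(x))

    def test_degenerate_inputs_raise(self):
        with pytest.raises(DegenerateDistributionError):
            robust_z([1.0, 2.0])
        with pytest.raises(DegenerateDistributionError):
            robust_z([5.0] * 10)


def _toy_screen(counts_by_well):
    """One CP plate: 4 DMSO wells and sample wells from a dict."""
    rows = []
    for i, (comp, count) in enumerate(counts_by_well.items()):
        rows.append(("P1", f"A{i+1:02d}", "sample", comp, 1.0, "CP", 1, count))
    for j, c in enumerate([100, 110, 90, 100]):
        rows.append(("P1", f"B{j+1:02d}", "dmso", "DMSO", 0.0, "CP", 1, c))
    df = pd.DataFrame(rows, columns=["plate_id", "well_id", "role", "compound_id",
                                     "concentration_uM", "condition", "replicate",
                                     "count"])
    return df.drop(columns="count"), df[["plate_id", "well_id", "count"]]


class TestNormalizeToVehicle:
    def test_fold_change_against_dmso_median(self):
        # DMSO median 100; a well at 16 is an 84% viability decrease
        pm, counts = _toy_screen({"A": 16, "B": 100})
        fc = normalize_to_vehicle(counts, pm).set_index("compound_id")
        assert fc.loc["A", "fold_change"] == pytest.approx(0.16)
        assert fc.loc["B", "fold_change"] == pytest.approx(1.0)

    def test_rescaling_a_plate_leaves_fold_changes_unchanged(self):
        pm, counts = _toy_screen({"A": 40, "B": 70, "C": 130})
        base = normalize_to_vehicle(counts, pm).fold_change.to_numpy()
        scaled = counts.copy()
        scaled["count"] *= 3
        assert np.allclose(
            normalize_to_vehicle(scaled, pm).fold_change.to_numpy(), base
        )

    def test_missing_dmso_names_plate(self):
        pm, counts = _toy_screen({"A": 40})
        pm = pm[pm.role != "dmso"]
        with pytest.raises(PlateNormalizationError, match="P1"):
            normalize_to_vehicle(counts[counts.well_id.isin(pm.well_id)], pm)

    def test_zero_dmso_median_names_plate(self):
        pm, counts = _toy_screen({"A": 40})
        counts.loc[counts.well_id.str.startswith("B"), "count"] = 0
        with pytest.raises(PlateNormalizationError, match="P1"):
            normalize_to_vehicle(counts, pm)


class TestSummarizeReplicates:
    def test_mean_across_replicates(self):
        df = pd.DataFrame({
            "role": ["sample"] * 2, "compound_id": ["A"] * 2,
            "concentration_uM": [1.0] * 2, "condition": ["CP"] * 2,
            "replicate": [1, 2], "fold_change": [0.2, 0.4],
        })
        out = summarize_replicates(df)
        assert out.mean_fold_change.iloc[0] == pytest.approx(0.3)
        assert out.n_replicates.iloc[0] == 2

    def test_single_replicate_passes_through(self):
        df = pd.DataFrame({
            "role": ["sample"], "compound_id": ["A"], "concentration_uM": [1.0],
            "condition": ["CP"], "replicate": [1], "fold_change": [0.5],
        })
        assert summarize_replicates(df).mean_fold_change.iloc[0] == 0.5

    def test_replicate_order_irrelevant(self, rng):
        fcs = rng.random(4)
        rows = [("sample", "A", 1.0, "CP", i + 1, f) for i, f in enumerate(fcs)]
        df = pd.DataFrame(rows, columns=["role", "compound_id", "concentration_uM",
                                         "condition", "replicate", "fold_change"])
        a = summarize_replicates(df).mean_fold_change.iloc[0]
        b = summarize_replicates(df.iloc[::-1]).mean_fold_change.iloc[0]
        assert a == pytest.approx(b)


class TestCallHits:
    def _scored(self, z_cp, z_cx):
        rows = []
        for comp, z in z_cp.items():
            rows.append((comp, 1.0, "CP", z))
        for comp, z in z_cx.items():
            rows.append((comp, 1.0, "CX", z))
        return pd.DataFrame(rows, columns=["compound_id", "concentration_uM",
                                           "condition", "robust_z"])

    def test_requires_both_conditions(self):
        scored = self._scored({"A": -5, "B": -2}, {"A": -4, "B": -6})
        assert call_hits(scored) == {"A"}

    def test_either_concentration_suffices(self):
        rows = [("A", 1.0, "CP", -1.0), ("A", 5.0, "CP", -4.0),
                ("A", 1.0, "CX", -3.5), ("A", 5.0, "CX", -1.0)]
        scored = pd.DataFrame(rows, columns=["compound_id", "concentration_uM",
                                             "condition", "robust_z"])
        assert call_hits(scored) == {"A"}

    def test_compound_missing_a_condition_excluded(self, caplog):
        scored = self._scored({"A": -5}, {})
        assert call_hits(scored) == set()

    def test_threshold_boundary_inclusive(self):
        scored = self._scored({"A": -3.0}, {"A": -3.0})
        assert call_hits(scored) == {"A"}

    def test_monotone_in_fold_change(self, rng):
        # lowering one compound's mean fold change never removes it from the hits
        fc = rng.normal(1.0, 0.1, 30)
        rows = []
        for cond in ("CP", "CX"):
            for i, f in enumerate(fc):
                rows.append((f"C{i}", 1.0, cond, f))
        df = pd.DataFrame(rows, columns=["compound_id", "concentration_uM",
                                         "condition", "mean_fold_change"])
        df["n_replicates"] = 2
        hits_before = call_hits(score_screen(df))
        df.loc[df.compound_id == "C0", "mean_fold_change"] = 0.01
        hits_after = call_hits(score_screen(df))
        assert hits_before - {"C0"} <= hits_after


class TestIntersectHits:
    def test_overlap(self):
        assert intersect_hits({"A", "B"}, {"B", "C"}) == {"B"}

    def test_disjoint(self):
        assert intersect_hits({"A"}, {"B"}) == set()


class TestEndToEndScreen:
    def test_planted_senolytics_recovered(self):
        compounds = [f"C{i:03d}" for i in range(120)]
        pm = design_screen_layout(compounds)
        truth = make_screen_truth(pm, senolytic_ids=compounds[:4], seed=2)
        counts = gen_screen_plates(pm, truth)
        _, hits = analyze_screen(counts, pm)
        assert set(compounds[:4]) <= hits

    def test_full_pipeline_scale_invariance(self):
        compounds = [f"C{i:03d}" for i in range(60)]
        pm = design_screen_layout(compounds)
        truth = make_screen_truth(pm, senolytic_ids=compounds[:2], seed=4)
        counts = gen_screen_plates(pm, truth)
        scored, hits = analyze_screen(counts, pm)
        boosted = counts.copy()
        plate = pm.plate_id.unique()[0]
        boosted.loc[boosted.plate_id == plate, "count"] *= 5
        scored2, hits2 = analyze_screen(boosted, pm)
        assert hits2 == hits
        assert np.allclose(scored.robust_z.to_numpy(), scored2.robust_z.to_numpy())
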