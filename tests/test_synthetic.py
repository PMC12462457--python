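"""Generator invariants: determinism, conservation, closed forms."""

import numpy as np
import pytest

from senoscreen.doseresponse import FourPL, four_pl
from senoscreen.synthetic import (
    ExpressionTruth,
    FieldTruth,
    LayoutError,
    PackingError,
    ScreenTruth,
    design_screen_layout,
    gen_dose_response,
    gen_expression,
    gen_field,
    gen_screen_plates,
    make_screen_truth,
    random_field_truth,
)
from skimage import measure


def _blob_count(channel, background=100.0):
    mask = channel.astype(float) > background + 500
    return int(measure.label(mask).max())


class TestFieldGeneration:
    def test_empty_truth_gives_pure_background(self):
        truth = FieldTruth(live_centroids=(), shape=(128, 128), seed=0)
        field = gen_field(truth)
        assert field.nuclei_channel.mean() == pytest.approx(100, rel=0.05)
        assert _blob_count(field.nuclei_channel) == 0
        assert _blob_count(field.cytoplasm_channel) == 0

    def test_channel_blob_counts_match_truth(self):
        truth = random_field_truth(10, 3, seed=4)
        field = gen_field(truth)
        assert _blob_count(field.nuclei_channel) == 13
        assert _blob_count(field.cytoplasm_channel) == 10

    def test_same_seed_bit_identical(self):
        truth = random_field_truth(12, 2, seed=9)
        a, b = gen_field(truth), gen_field(truth)
        assert np.array_equal(a.nuclei_channel, b.nuclei_channel)
        assert np.array_equal(a.cytoplasm_channel, b.cytoplasm_channel)

    def test_overpacked_field_raises(self):
        with pytest.raises(PackingError):
            random_field_truth(500, shape=(128, 128), min_separation=24.0, seed=0)

    def test_radius_ordering_enforced(self):
        with pytest.raises(ValueError):
            FieldTruth(live_centroids=(), nucleus_radius_px=8, cytoplasm_radius_px=5)


class TestScreenGeneration:
    def test_null_kill_counts_track_plate_effect(self):
        pm = design_screen_layout(["C1", "C2"], n_replicates=1, conditions=("CP",))
        truth = ScreenTruth(
            kill_fraction={}, plate_effect={p: 1.3 for p in pm.plate_id.unique()},
            well_noise_cv=0.0, baseline_count=1000, seed=0,
        )
        counts = gen_screen_plates(pm, truth)
        assert (counts["count"] == 1300).all()

    def test_strong_kill_gives_expected_fold_change(self):
        pm = design_screen_layout(["C1"], concentrations=(1.0,),
                                  conditions=("CP",), n_replicates=1)
        kill = {("C1", 1.0, "CP"): 0.9, ("ABT-263", 10.0, "CP"): 0.0}
        truth = ScreenTruth(kill, {p: 1.0 for p in pm.plate_id.unique()},
                            well_noise_cv=0.0, baseline_count=1000, seed=0)
        counts = gen_screen_plates(pm, truth).merge(pm, on=["plate_id", "well_id"])
        dmso_median = counts.loc[counts.role == "dmso", "count"].median()
        c1 = counts.loc[counts.compound_id == "C1", "count"].iloc[0]
        assert c1 / dmso_median == pytest.approx(0.1)

    def test_zero_noise_plate_effects_cancel_in_fold_change(self):
        # two plates with effects 1.0 and 2.0: raw counts differ exactly 2x,
        # normalized fold changes are identical
        pm = design_screen_layout(["C1"], concentrations=(1.0,),
                                  conditions=("CP",), n_replicates=2)
        plates = list(pm.plate_id.unique())
        kill = {("C1", 1.0, "CP"): 0.4, ("ABT-263", 10.0, "CP"): 0.0}
        truth = ScreenTruth(kill, {plates[0]: 1.0, plates[1]: 2.0},
                            well_noise_cv=0.0, baseline_count=1000, seed=0)
        counts = gen_screen_plates(pm, truth).merge(pm, on=["plate_id", "well_id"])
        raw = counts[counts.compound_id == "C1"].set_index("plate_id")["count"]
        assert raw[plates[1]] == 2 * raw[plates[0]]
        fc = {
            p: raw[p] / counts[(counts.plate_id == p) & (counts.role == "dmso")]["count"].median()
            for p in plates
        }
        assert fc[plates[0]] == pytest.approx(fc[plates[1]])

    def test_expected_fold_change_monotone_in_kill(self):
        pm = design_screen_layout(["C1"], concentrations=(1.0,),
                                  conditions=("CP",), n_replicates=1)
        fcs = []
        for k in (0.0, 0.3, 0.6, 0.9):
            truth = ScreenTruth({("C1", 1.0, "CP"): k},
                                {p: 1.0 for p in pm.plate_id.unique()},
                                well_noise_cv=0.0, baseline_count=1000, seed=0)
            counts = gen_screen_plates(pm, truth).merge(pm, on=["plate_id", "well_id"])
            med = counts.loc[counts.role == "dmso", "count"].median()
            fcs.append(counts.loc[counts.compound_id == "C1", "count"].iloc[0] / med)
        assert all(a > b for a, b in zip(fcs, fcs[1:]))

    def test_plate_without_dmso_rejected(self):
        pm = design_screen_layout(["C1"], n_replicates=1, conditions=("CP",))
        pm = pm[pm.role != "dmso"]
        truth = make_screen_truth(pm, seed=0)
        with pytest.raises(LayoutError):
            gen_screen_plates(pm, truth)

    def test_duplicate_well_rejected(self):
        pm = design_screen_layout(["C1"], n_replicates=1, conditions=("CP",))
        import pandas as pd
        pm = pd.concat([pm, pm.iloc[[0]]], ignore_index=True)
        with pytest.raises(LayoutError):
            gen_screen_plates(pm, make_screen_truth(pm.drop_duplicates(["plate_id", "well_id"]), seed=0))

    def test_same_seed_identical_counts(self):
        pm = design_screen_layout([f"C{i}" for i in range(20)])
        truth = make_screen_truth(pm, senolytic_ids=["C0"], seed=5)
        a, b = gen_screen_plates(pm, truth), gen_screen_plates(pm, truth)
        assert a.equals(b)


class TestExpressionGeneration:
    def test_same_seed_identical_matrices(self):
        truth = ExpressionTruth(planted_up=("A",), planted_down=("B",),
                                n_genes=50, n_celllines=2, n_replicates=2, seed=3)
        (c1, s1), (c2, s2) = gen_expression(truth), gen_expression(truth)
        assert c1.equals(c2) and s1.equals(s2)

    def test_planted_gene_strongest_signal(self):
        from senoscreen.rnaseq import log_cpm, simple_de

        # private per-line responses off: with a single contrast they can
        # rival the shared program and this test targets the shared signal
        truth = ExpressionTruth(planted_up=("HIT",), planted_down=(),
                                n_genes=300, n_celllines=1, n_replicates=5,
                                lfc_up=4.0, dispersion=0.05,
                                frac_private_response=0.0, seed=8)
        counts, samples = gen_expression(truth)
        for (_, _), grp in samples.groupby(["cell_line", "drug"]):
            logcpm = log_cpm(counts[grp.sample_id.tolist()])
            de = simple_de(logcpm, grp.group.to_numpy()).set_index("gene_id")
            assert de.adj_p.idxmin() == "HIT"
            assert de.loc["HIT", "log2_fc"] > 2

    def test_overlapping_up_down_sets_rejected(self):
        with pytest.raises(ValueError):
            ExpressionTruth(planted_up=("A",), planted_down=("A",), n_genes=10)

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            ExpressionTruth(planted_up=("A",), planted_down=(), n_genes=10,
                            n_replicates=1)


class TestDoseResponseGeneration:
    def test_noiseless_midpoint(self):
        d = gen_dose_response(FourPL(1, 0, 1, 1), np.array([1.0]), noise_sd=0)
        assert d.response.iloc[0] == pytest.approx(0.5)

    def test_low_dose_approaches_top(self):
        d = gen_dose_response(FourPL(1, 0, 1, 1), np.array([1e-6]), noise_sd=0)
        assert d.response.iloc[0] == pytest.approx(1.0, abs=1e-5)

    def test_seeded_noise_reproducible(self):
        doses = np.array([0.1, 1.0, 10.0])
        a = gen_dose_response(FourPL(1, 0, 1, 1), doses, noise_sd=0.1, seed=2)
        b = gen_dose_response(FourPL(1, 0, 1, 1), doses, noise_sd=0.1, seed=2)
        assert a.equals(b)

    def test_nonpositive_or_unsorted_doses_rejected(self):
        with pytest.raises(ValueError):
            gen_dose_response(FourPL(1, 0, 1, 1), np.array([0.0, 1.0]))
        with pytest.raises(ValueError):
            gen_dose_response(FourPL(1, 0, 1, 1), np.array([1.0, 0.5]))
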