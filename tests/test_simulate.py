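"""Generator correctness: determinism, ledger consistency, mixing linearity."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cytoplate as cp
from cytoplate.simulate import (
    PlacementError,
    draw_ground_truth,
    well_seed,
)


def tiny_params(**kw):
    defaults = dict(n_cells=40, image_shape=(512, 512), seed=11)
    defaults.update(kw)
    return cp.WellSimParams(**defaults)


class TestSimulateWell:
    def test_deterministic_given_seed(self):
        p = tiny_params(marker_models={"m": cp.MarkerModel(0.5)},
                        dead_fraction=0.2, viability_stains=True)
        im1, gt1 = cp.simulate_well(p)
        im2, gt2 = cp.simulate_well(dataclasses.replace(p))
        pd.testing.assert_frame_equal(gt1, gt2)
        for ch in im1.channels:
            np.testing.assert_array_equal(im1[ch], im2[ch])

    def test_different_seeds_differ(self):
        im1, _ = cp.simulate_well(tiny_params(seed=1))
        im2, _ = cp.simulate_well(tiny_params(seed=2))
        assert not np.array_equal(im1["hoechst"], im2["hoechst"])

    def test_empty_well_is_pure_background(self):
        p = tiny_params(n_cells=0, noise_sd=0.0)
        images, gt = cp.simulate_well(p)
        assert len(gt) == 0
        np.testing.assert_allclose(images["hoechst"], p.background_level)

    def test_degenerate_phase_distribution(self):
        p = tiny_params(phase_fractions=(1.0, 0.0, 0.0), dna_cv=0.0)
        _, gt = cp.simulate_well(p)
        np.testing.assert_allclose(gt["true_hoechst"], p.g1_dna_intensity)
        assert (gt["phase"] == "G0/G1").all()

    def test_total_signal_matches_ledger(self):
        """Noiseless Hoechst image mass equals the summed per-cell ledger."""
        p = tiny_params(n_cells=60, image_shape=(768, 768), noise_sd=0.0)
        images, gt = cp.simulate_well(p)
        rendered = images["hoechst"].sum() - p.background_level * images["hoechst"].size
        assert rendered == pytest.approx(gt["true_hoechst"].sum(), rel=5e-3)

    def test_bleedthrough_is_linear_mixing(self):
        markers = {"m": cp.MarkerModel(0.5)}
        m = np.array([[1.0, 0.2], [0.0, 1.0]])
        base = tiny_params(marker_models=markers, noise_sd=0.0,
                           background_level=0.0)
        mixed = tiny_params(marker_models=markers, noise_sd=0.0,
                            background_level=0.0, bleedthrough=m)
        im0, _ = cp.simulate_well(base)
        im1, _ = cp.simulate_well(mixed)
        expected_m = im0["m"] + 0.2 * im0["hoechst"]
        np.testing.assert_allclose(im1["m"], expected_m, rtol=0, atol=1e-9)
        np.testing.assert_allclose(im1["hoechst"], im0["hoechst"], atol=1e-9)

    def test_placement_failure_names_density(self):
        p = tiny_params(n_cells=400, image_shape=(128, 128))
        with pytest.raises(PlacementError, match="density"):
            cp.simulate_well(p)

    def test_dead_cells_swap_stains_but_keep_hoechst(self):
        p = tiny_params(dead_fraction=0.5, viability_stains=True, n_cells=60,
                        image_shape=(768, 768))
        _, gt = cp.simulate_well(p)
        dead = gt["viability"] == "dead"
        assert (gt.loc[dead, "true_pi"] > 0).all()
        assert (gt.loc[dead, "true_calcein"] == 0).all()
        assert (gt.loc[~dead, "true_pi"] == 0).all()
        assert (gt.loc[~dead, "true_calcein"] > 0).all()
        assert (gt["true_hoechst"] > 0).all()  # dead cells still counted

    def test_category_counts_match_stated_fractions(self):
        """Pooled phase/marker/viability counts pass a chi-square GOF test."""
        phase_counts = np.zeros(3)
        marker_pos = 0
        dead = 0
        total = 0
        for seed in range(20):
            p = cp.WellSimParams(
                n_cells=300, image_shape=(2048, 2048),
                phase_fractions=(0.5, 0.3, 0.2),
                marker_models={"m": cp.MarkerModel(0.4)},
                dead_fraction=0.25, seed=seed,
            )
            gt = draw_ground_truth(p, np.random.default_rng(seed))
            for i, ph in enumerate(("G0/G1", "S", "G2/M")):
                phase_counts[i] += (gt["phase"] == ph).sum()
            marker_pos += gt["m_positive"].sum()
            dead += (gt["viability"] == "dead").sum()
            total += len(gt)
        p_phase = stats.chisquare(phase_counts,
                                  total * np.array([0.5, 0.3, 0.2])).pvalue
        p_marker = stats.binomtest(int(marker_pos), total, 0.4).pvalue
        p_dead = stats.binomtest(int(dead), total, 0.25).pvalue
        assert min(p_phase, p_marker, p_dead) > 0.001


class TestParamValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"phase_fractions": (0.6, 0.3, 0.2)},
            {"phase_fractions": (1.2, -0.1, -0.1)},
            {"dead_fraction": 1.5},
            {"n_cells": -1},
        ],
    )
    def test_invalid_params_rejected(self, kw):
        with pytest.raises(ValueError):
            tiny_params(**kw)

    def test_marker_model_ordering_enforced(self):
        with pytest.raises(ValueError, match="positive_mean"):
            cp.MarkerModel(0.5, negative_mean=100.0, positive_mean=50.0)

    def test_bleedthrough_must_have_unit_diagonal(self):
        with pytest.raises(ValueError, match="diagonal"):
            tiny_params(bleedthrough=np.array([[0.9]]))


class TestDosePlate:
    def test_requires_untreated_well(self):
        with pytest.raises(ValueError, match="zero"):
            cp.simulate_dose_plate(cp.DrugResponseModel(), [0.1, 1.0], 2, seed=1)

    def test_growth_curve_closed_form(self):
        m = cp.DrugResponseModel(ic50_true=1.0, hill=1.0, max_inhibition=1.0)
        assert m.expected_growth(0.0) == 1.0
        assert m.expected_growth(1.0) == pytest.approx(0.5)
        assert m.expected_dead_fraction(0.0) == pytest.approx(m.baseline_dead)

    def test_wells_deterministic_and_order_independent(self):
        m = cp.DrugResponseModel(baseline_cells_per_well=50)
        base = cp.WellSimParams(n_cells=50, image_shape=(640, 640),
                                viability_stains=True)
        w1 = cp.simulate_dose_plate(m, [0.0, 1.0], 2, seed=5, base_params=base,
                                    render=False)
        w2 = cp.simulate_dose_plate(m, [0.0, 1.0], 2, seed=5, base_params=base,
                                    render=False)
        for a, b in zip(w1, w2):
            assert a.well_id == b.well_id
            pd.testing.assert_frame_equal(a.ground_truth, b.ground_truth)
        # per-well seed depends only on master seed + well id
        assert well_seed(5, "C00R1") == w1[0].params.seed - 1

    def test_cell_number_tracks_inhibition_curve(self):
        m = cp.DrugResponseModel(ic50_true=1.0, hill=2.0,
                                 baseline_cells_per_well=150)
        wells = cp.simulate_dose_plate(
            m, [0.0, 1.0, 100.0], replicates=4, seed=9,
            base_params=cp.WellSimParams(image_shape=(1024, 1024),
                                         viability_stains=True),
            count_cv=0.0, render=False,
        )
        by_conc = {}
        for w in wells:
            by_conc.setdefault(w.concentration, []).append(len(w.ground_truth))
        assert np.mean(by_conc[0.0]) == pytest.approx(150, abs=1)
        assert np.mean(by_conc[1.0]) == pytest.approx(75, abs=1)
        assert np.mean(by_conc[100.0]) <= 2


class TestScenarioLibrary:
    def test_g2m_arrest_scenarios(self):
        treated = cp.scenario_library("etoposide-treated")
        untreated = cp.scenario_library("etoposide-untreated")
        assert treated.phase_fractions[2] == pytest.approx(0.66)
        assert untreated.phase_fractions[2] == pytest.approx(0.22)

    def test_multiplex_scenario_fractions(self):
        p = cp.scenario_library("SN38-multiplex")
        pf = {name: m.positive_fraction for name, m in p.marker_models.items()}
        assert pf == {"gH2AX": 0.90, "pATM": 0.80, "pATR": 0.60}

    def test_unknown_scenario_raises(self):
        with pytest.raises(KeyError, match="available"):
            cp.scenario_library("nonexistent-drug")


class TestImageIO:
    def test_tiff_roundtrip_quantizes_to_uint16(self, tmp_path):
        p = tiny_params(noise_sd=0.0)
        images, _ = cp.simulate_well(p)
        cp.write_well_images(images, tmp_path, "B2")
        back = cp.read_well_images(tmp_path, "B2", images.channels)
        for ch in images.channels:
            np.testing.assert_allclose(back[ch], np.rint(images[ch]), atol=0.5)

    def test_missing_channel_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="B9"):
            cp.read_well_images(tmp_path, "B9", ["hoechst"])
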