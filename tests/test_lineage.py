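import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from microtrack.lineage import (aggregate_by_pole_history, cell_endpoints,
                                cell_length, check_lineage_integrity,
                                fluorescence, generation_growth_rates,
                                growth_rate)
from microtrack.simulate import SimConfig, run_colony, trace_to_feature_table


def _rect_mask(h=8, w=40, shape=(60, 60), angle=0.0):
    mask = np.zeros(shape, dtype=bool)
    r0 = (shape[0] - h) // 2
    c0 = (shape[1] - w) // 2
    mask[r0:r0 + h, c0:c0 + w] = True
    if angle:
        mask = ndimage.rotate(mask.astype(float), angle, order=0,
                              reshape=False) > 0.5
    return mask


class TestCellLength:
    def test_horizontal_rod(self):
        # 40 x 8 px rectangle at 0.129 um/px -> about 5.16 um
        length = cell_length(_rect_mask(), pixel_size=0.129)
        assert length == pytest.approx(40 * 0.129, rel=0.10)

    def test_rotation_invariance(self):
        flat = cell_length(_rect_mask())
        tilted = cell_length(_rect_mask(angle=45.0))
        assert tilted == pytest.approx(flat, rel=0.05)

    def test_simulator_lengths_recovered(self, small_colony):
        result, masks, _, _ = small_colony
        cfg = result.config
        errs = []
        t = len(result.trace) - 1
        for lab, aid in result.registry[t].items():
            agent = next(a for a in result.trace[t] if a.id == aid)
            measured = cell_length(masks[t] == lab, cfg.pixel_size_um)
            errs.append(abs(measured - agent.length) / agent.length)
        assert np.median(errs) < 0.05

    def test_tiny_mask_rejected(self):
        with pytest.raises(ValueError):
            cell_length(np.zeros((5, 5), dtype=bool))

    def test_endpoints_at_rod_ends(self):
        a, b = cell_endpoints(_rect_mask())
        assert abs(a[1] - b[1]) > 25  # separated along the long axis


class TestFluorescence:
    def test_uniform_channel(self):
        mask = _rect_mask()
        assert fluorescence(mask, np.full(mask.shape, 3.7)) == 3.7

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            fluorescence(np.zeros((5, 5), dtype=bool), np.zeros((5, 5)))

    def test_two_strain_separation(self):
        from microtrack.simulate import simulate
        cfg = SimConfig(
            seed=13, n_founders=4, n_frames=15, noise_sigma=0.02,
            strain_table={
                "res": {"growth": 1.0, "fluor": {"rfp": 0.5}},
                "sus": {"growth": 1.0, "fluor": {"gfp": 0.5}},
            },
            founder_strains=("res", "sus", "res", "sus"))
        res = simulate(cfg)
        t = cfg.n_frames - 1
        rfp = res.movie.channel("rfp", t)
        by_strain = {"res": [], "sus": []}
        agents = {a.id: a for a in res.trace[t]}
        for lab, aid in res.registry[t].items():
            by_strain[agents[aid].strain].append(
                fluorescence(res.masks[t] == lab, rfp))
        assert min(by_strain["res"]) > max(by_strain["sus"])


class TestGrowthRate:
    def test_printed_arithmetic_example(self):
        # 2.0 -> 2.1 um over 0.083 hr: (0.1 / 2.0) / 0.083 = 0.602
        assert growth_rate([2.0, 2.1], 0.083) == \
            pytest.approx((0.1 / 2.0) / 0.083, abs=1e-12)

    def test_constant_length_zero_rate(self):
        assert growth_rate([3.0, 3.0, 3.0], 0.083) == 0.0

    def test_exponential_discretisation_bias_reproduced(self):
        r, dt = 0.6, 5 / 60.0
        t = np.arange(10) * dt
        lengths = 2.0 * np.exp(r * t)
        expected = (np.exp(r * dt) - 1.0) / dt
        assert growth_rate(lengths, dt) == pytest.approx(expected, abs=1e-9)

    def test_dt_must_be_positive(self):
        with pytest.raises(ValueError):
            growth_rate([1.0, 2.0], 0.0)


class TestGenerationWindowing:
    def _features(self):
        # hand-enumerated fixture: cell 1 spans 4 frames, cell 2 only 2
        # (excluded), cell 3 exactly 3 frames
        rows = []
        for t, L in enumerate([2.0, 2.2, 2.42, 2.662]):
            rows.append({"cell_id": 1, "frame": t, "length_um": L,
                         "pole_history": "O"})
        for t, L in [(4, 2.0), (5, 2.1)]:
            rows.append({"cell_id": 2, "frame": t, "length_um": L,
                         "pole_history": "N"})
        for t, L in [(4, 2.0), (5, 2.2), (6, 2.42)]:
            rows.append({"cell_id": 3, "frame": t, "length_um": L,
                         "pole_history": "N"})
        return pd.DataFrame(rows)

    def test_short_cells_excluded_and_rates_exact(self):
        per_cell = generation_growth_rates(self._features(), dt_hr=0.083)
        assert sorted(per_cell["cell_id"]) == [1, 3]
        rate1 = per_cell.set_index("cell_id").loc[1, "growth_rate"]
        assert rate1 == pytest.approx(0.1 / 0.083, rel=1e-9)

    def test_first_frame_cutoff(self):
        per_cell = generation_growth_rates(self._features(), dt_hr=0.083,
                                           min_first_frame_cutoff=3)
        assert sorted(per_cell["cell_id"]) == [1]


class TestPoleAgeAggregation:
    def _null_features(self, seed=0, penalty=0.0):
        cfg = SimConfig(seed=seed, n_founders=40, n_frames=45,
                        mechanics=False, old_pole_penalty=penalty)
        return trace_to_feature_table(run_colony(cfg))

    def test_groups_and_tests_reported(self):
        feats = self._null_features(seed=2)
        report = aggregate_by_pole_history(feats, dt_hr=5 / 60.0)
        assert {"O", "N"} <= set(report.groups["pole_history"])
        assert 1 in set(report.tests["generation"])
        gen2 = report.groups[report.groups["generation"] == 2]
        assert set(gen2["pole_history"]) <= {"OO", "ON", "NO", "NN"}

    def test_penalty_slows_old_pole_daughters(self):
        feats = self._null_features(seed=3, penalty=0.15)
        report = aggregate_by_pole_history(feats, dt_hr=5 / 60.0)
        g = report.groups.set_index("pole_history")
        assert g.loc["O", "mean"] < g.loc["N", "mean"]

    def test_small_groups_dropped_with_warning(self):
        rows = []
        for i in range(5):
            for t in range(3):
                rows.append({"cell_id": i, "frame": t,
                             "length_um": 2.0 * 1.05**t,
                             "pole_history": "O"})
        rows += [{"cell_id": 99, "frame": t, "length_um": 2.0 * 1.04**t,
                  "pole_history": "N"} for t in range(3)]
        with pytest.warns(UserWarning, match="n < 2"):
            aggregate_by_pole_history(pd.DataFrame(rows), dt_hr=0.083)


class TestLineageIntegrity:
    def test_violations_detected(self):
        good = pd.DataFrame([
            {"cell_id": 0, "mother_id": -1, "first_frame": 0,
             "last_frame": 4, "pole_history": ""},
            {"cell_id": 1, "mother_id": 0, "first_frame": 5,
             "last_frame": 9, "pole_history": ""},
        ])
        check_lineage_integrity(good)
        bad_frame = good.copy()
        bad_frame.loc[1, "first_frame"] = 7
        with pytest.raises(AssertionError, match="last frame"):
            check_lineage_integrity(bad_frame)
        bad_mother = good.copy()
        bad_mother.loc[1, "mother_id"] = 42
        with pytest.raises(AssertionError, match="unknown mother"):
            check_lineage_integrity(bad_mother)
        bad_history = good.copy()
        bad_history.loc[1, "pole_history"] = "ON"
        with pytest.raises(AssertionError, match="more than one letter"):
            check_lineage_integrity(bad_history)
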