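import numpy as np
import pytest
from dataclasses import replace

from microtrack.simulate import (CellAgent, SimConfig, relax_overlaps,
                                 render_frame, run_colony, simulate,
                                 step_colony, trace_to_feature_table)


def _agent(**kwargs) -> CellAgent:
    defaults = dict(id=0, center=np.array([16.0, 16.0]), orientation=0.3,
                    length=3.0, width=1.0, elongation_rate=0.6,
                    division_length=100.0)
    defaults.update(kwargs)
    return CellAgent(**defaults)


def _cfg(**kwargs) -> SimConfig:
    defaults = dict(seed=0, division_asymmetry_sd=0.0, elongation_cv=0.0,
                    orientation_jitter_sd=0.0, mechanics=False)
    defaults.update(kwargs)
    return SimConfig(**defaults)


class TestStepColony:
    def test_exponential_elongation(self, rng):
        cell = _agent(length=2.0, elongation_rate=0.7)
        out, events, _ = step_colony([cell], 0.25, rng, _cfg())
        assert not events
        assert out[0].length == pytest.approx(2.0 * np.exp(0.7 * 0.25))

    def test_dt_must_be_positive(self, rng):
        with pytest.raises(ValueError):
            step_colony([_agent()], 0.0, rng, _cfg())

    def test_symmetric_division_conserves_length(self, rng):
        mother = _agent(length=4.4, width=1.0, division_length=4.0,
                        elongation_rate=0.0, poles_assigned=True,
                        pole_old_sign=+1, pole_history="O")
        old_pole = mother.pole_old.copy()
        out, events, _ = step_colony([mother], 1e-9, rng, _cfg())
        assert len(events) == 1
        assert len(out) == 2
        total = mother.length * np.exp(mother.elongation_rate * 1e-9)
        d_old = next(a for a in out if a.pole_history.endswith("O"))
        d_new = next(a for a in out if a.pole_history.endswith("N"))
        # daughters' lengths sum to mother length minus one cap width
        assert d_old.length + d_new.length == pytest.approx(total - 1.0)
        assert d_old.length == pytest.approx(d_new.length)
        # the O daughter keeps the end nearest the mother's old pole
        assert (np.linalg.norm(d_old.pole_old - old_pole)
                < np.linalg.norm(d_new.pole_old - old_pole))

    def test_founder_division_appends_no_letter(self, rng):
        mother = _agent(length=5.0, division_length=4.0)
        assert not mother.poles_assigned
        out, events, _ = step_colony([mother], 1e-9, rng, _cfg())
        assert [a.pole_history for a in out] == ["", ""]
        assert all(a.poles_assigned for a in out)

    def test_one_letter_per_division_afterwards(self, rng):
        mother = _agent(length=5.0, division_length=4.0, poles_assigned=True,
                        pole_history="ON")
        out, _, _ = step_colony([mother], 1e-9, rng, _cfg())
        assert sorted(a.pole_history for a in out) == ["ONN", "ONO"]


class TestMechanics:
    def test_overlapping_pair_separates(self):
        a = _agent(id=0, center=np.array([10.0, 10.0]), orientation=0.0)
        b = _agent(id=1, center=np.array([10.3, 10.2]), orientation=0.1)
        relax_overlaps([a, b], tol=0.05, max_iter=200)
        d = np.linalg.norm(a.center - b.center)
        assert d > 0.5  # centres pushed out to about one cell width


class TestRenderFrame:
    def test_empty_field(self, rng):
        cfg = _cfg(noise_sigma=0.02)
        phase, fluor, labels, reg = render_frame([], cfg, rng)
        assert labels.max() == 0 and not reg
        assert abs(phase.mean() - cfg.background) < 0.01

    def test_single_cell_dark_interior(self, rng):
        cfg = _cfg()
        cell = _agent(center=np.array([16.5, 16.5]) * cfg.pixel_size_um * 8)
        phase, _, labels, reg = render_frame([cell], cfg, rng)
        assert len(reg) == 1
        inside = labels > 0
        assert inside.any()
        assert phase[inside].mean() < cfg.background

    def test_touching_cells_keep_distinct_labels(self, rng):
        cfg = _cfg()
        ps = cfg.pixel_size_um
        a = _agent(id=0, center=np.array([100 * ps, 100 * ps]),
                   orientation=0.0)
        b = _agent(id=1, center=np.array([100 * ps, 100 * ps + 3.05]),
                   orientation=0.0)
        _, _, labels, reg = render_frame([a, b], cfg, rng)
        assert len(reg) == 2
        assert set(np.unique(labels)) == {0, 1, 2}

    def test_pixel_size_must_be_positive(self, rng):
        with pytest.raises(ValueError):
            render_frame([], _cfg(pixel_size_um=0.0), rng)


class TestGroundTruth:
    def test_seeded_determinism(self):
        cfg = SimConfig(seed=42, n_founders=3, n_frames=12)
        a = simulate(cfg)
        b = simulate(replace(cfg))
        for t in range(cfg.n_frames):
            np.testing.assert_array_equal(a.movie.phase(t), b.movie.phase(t))
            np.testing.assert_array_equal(a.masks[t], b.masks[t])

    def test_count_increases_by_one_per_division(self, small_colony):
        result, _, _, _ = small_colony
        for t in range(1, len(result.trace)):
            divs = sum(1 for e in result.events if e.frame == t)
            assert (len(result.trace[t]) - len(result.trace[t - 1])) == divs

    def test_mask_agent_bijection(self, small_colony):
        result, masks, _, _ = small_colony
        for t, reg in enumerate(result.registry):
            labels = set(np.unique(masks[t])) - {0}
            assert labels == set(reg)
            assert len(set(reg.values())) == len(reg)

    def test_referential_integrity(self, small_colony):
        _, _, _, lineage = small_colony
        by_id = lineage.set_index("cell_id")
        for cid, row in by_id.iterrows():
            if row["mother_id"] < 0:
                continue
            assert row["mother_id"] in by_id.index
            assert (by_id.loc[row["mother_id"], "last_frame"] + 1
                    == row["first_frame"])

    def test_founder_history_empty(self, small_colony):
        _, _, _, lineage = small_colony
        founders = lineage[lineage["mother_id"] < 0]
        assert (founders["pole_history"].fillna("") == "").all()

    def test_elongation_rate_recovery(self):
        # per-cell log-length regression on the simulator's own trace must
        # recover the configured mean elongation rate within 2 SE
        cfg = SimConfig(seed=8, n_founders=30, n_frames=40, mechanics=False,
                        elongation_cv=0.05)
        result = run_colony(cfg)
        feats = trace_to_feature_table(result)
        dt = cfg.interval_min / 60.0
        rates = []
        for _, grp in feats.groupby("cell_id"):
            if len(grp) < 5:
                continue
            t = grp["frame"].to_numpy() * dt
            rates.append(np.polyfit(t, np.log(grp["length_um"]), 1)[0])
        rates = np.array(rates)
        se = rates.std(ddof=1) / np.sqrt(len(rates))
        assert abs(rates.mean() - cfg.mean_elongation_rate) < 2 * se + 1e-3
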