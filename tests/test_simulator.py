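"""Stochastic sheet integration: determinism, noise structure, schedules,
resection freezing and persistence."""

import numpy as np
import pytest

import ictalsheet as ish
from ictalsheet.model_core import DEFAULT_Q, background_equilibrium
from ictalsheet.simulator import (Event, EventSchedule, NoiseModel,
                                  make_onset_schedule,
                                  make_stimulation_schedule,
                                  default_stimulation_sites,
                                  run_with_halved_step, save_result,
                                  load_result, _apply_schedule_step)
from ictalsheet.connectivity import ResectionMask


def _uniform_fields(geom, P, Q=DEFAULT_Q):
    return dict(P=ish.ParameterField.uniform(geom, P),
                Q=ish.ParameterField.uniform(geom, Q, name="Q"))


class TestDeterminism:
    def test_identical_seed_gives_bit_identical_trajectories(self, conn20,
                                                             geom20):
        kw = dict(geometry=geom20, **_uniform_fields(geom20, -2.5))
        a = ish.simulate(ish.DEFAULT_PARAMS, conn20, EventSchedule(), 1000.0,
                         NoiseModel(seed=5), **kw)
        b = ish.simulate(ish.DEFAULT_PARAMS, conn20, EventSchedule(), 1000.0,
                         NoiseModel(seed=5), **kw)
        c = ish.simulate(ish.DEFAULT_PARAMS, conn20, EventSchedule(), 1000.0,
                         NoiseModel(seed=6), **kw)
        assert np.array_equal(a.E, b.E) and np.array_equal(a.I, b.I)
        assert not np.array_equal(a.E, c.E)

    def test_deterministic_limit_reaches_root_found_equilibrium(self, conn30,
                                                                geom30):
        res = ish.simulate(ish.DEFAULT_PARAMS.with_(A_s=0.0), conn30,
                           EventSchedule(), 4000.0, NoiseModel(seed=0),
                           geometry=geom30, **_uniform_fields(geom30, -4.0))
        cfg = ish.ConnectivityConfig()
        E0, _ = background_equilibrium(
            -4.0, DEFAULT_Q,
            lateral_E_gain=cfg.w_EE_local + cfg.w_EE_remote,
            lateral_I_gain=cfg.w_EI_local)
        assert np.abs(res.E[-1] - E0).max() < 1e-6
        # ECoG of the settled background is flat
        sig = ish.ecog(res)
        assert np.abs(sig[len(sig) // 2:]).max() < 1e-3

    def test_halved_step_equilibrium_agreement(self, conn30, geom30):
        kw = dict(geometry=geom30, **_uniform_fields(geom30, -4.0))
        quiet = ish.DEFAULT_PARAMS.with_(A_s=0.0)
        a = ish.simulate(quiet, conn30, EventSchedule(), 3000.0,
                         NoiseModel(seed=0), dt=2.0, **kw)
        b = run_with_halved_step(quiet, conn30, EventSchedule(), 3000.0,
                                 NoiseModel(seed=0), **kw)
        assert np.abs(a.E[-1].astype(float) - b.E[-1].astype(float)).max() \
            < 1e-4

    def test_stochastic_runs_differ_across_step_sizes(self, conn20, geom20):
        kw = dict(geometry=geom20, **_uniform_fields(geom20, -2.5))
        a = ish.simulate(ish.DEFAULT_PARAMS, conn20, EventSchedule(), 1000.0,
                         NoiseModel(seed=5), dt=2.0, **kw)
        b = run_with_halved_step(ish.DEFAULT_PARAMS, conn20, EventSchedule(),
                                 1000.0, NoiseModel(seed=5), stride=2, **kw)
        assert not np.array_equal(a.E[-1], b.E[-1])


class TestNoiseStructure:
    def test_macrocolumn_sharing(self, geom20):
        """All minicolumns of one macrocolumn receive the same stream; with
        lateral coupling disabled their trajectories are identical."""
        cfg = ish.ConnectivityConfig(local_radius=0.0, n_remote_clusters=0.0,
                                     remote_distance_range=(1.0, 2.0))
        conn = ish.build_connectivity(geom20, cfg)
        res = ish.simulate(ish.DEFAULT_PARAMS, conn, EventSchedule(), 500.0,
                           NoiseModel(seed=3), geometry=geom20,
                           **_uniform_fields(geom20, -2.0))
        macro = geom20.macro_index()
        for mid in range(geom20.n_macro):
            cols = np.flatnonzero(macro == mid)
            assert np.array_equal(res.E[:, cols[0]], res.E[:, cols[-1]])
        # different macrocolumns see different noise
        first = [np.flatnonzero(macro == m)[0] for m in range(4)]
        assert not np.array_equal(res.E[:, first[0]], res.E[:, first[1]])
        assert res.noise.shape[1] == geom20.n_macro

    def test_state_bounded(self, conn30, geom30):
        sched = make_onset_schedule(
            [np.arange(400, 440)], P_patch_end=1.0, P_surround=-1.5)
        res = ish.simulate(ish.DEFAULT_PARAMS, conn30, sched, 5000.0,
                           NoiseModel(seed=11), geometry=geom30,
                           **_uniform_fields(geom30, -1.5))
        assert res.E.min() >= -0.05 and res.E.max() <= 1.05
        assert res.I.min() >= -0.05 and res.I.max() <= 1.05

    def test_additive_mode_runs_and_differs(self, conn20, geom20):
        kw = dict(geometry=geom20, **_uniform_fields(geom20, -4.0))
        a = ish.simulate(ish.DEFAULT_PARAMS, conn20, EventSchedule(), 500.0,
                         NoiseModel(seed=5, mode="additive"), **kw)
        b = ish.simulate(ish.DEFAULT_PARAMS, conn20, EventSchedule(), 500.0,
                         NoiseModel(seed=5), **kw)
        assert not np.array_equal(a.E, b.E)

    def test_nan_state_aborts(self, conn20, geom20):
        bad = ish.SheetState(np.full(geom20.n_columns, np.nan),
                             np.zeros(geom20.n_columns))
        with pytest.raises(FloatingPointError):
            ish.simulate(ish.DEFAULT_PARAMS, conn20, EventSchedule(), 500.0,
                         NoiseModel(seed=0), geometry=geom20, init=bad,
                         **_uniform_fields(geom20, -4.0))


class TestSchedules:
    def test_ramp_is_linear_and_holds_end_value(self):
        base = np.zeros(4)
        ev = Event("ramp", "P", (1, 2), t_start=100.0, duration=200.0,
                   value=-2.0, end_value=2.0)
        sched = EventSchedule([ev])
        for t, expect in [(0.0, 0.0), (100.0, -2.0), (200.0, 0.0),
                          (300.0, 2.0), (500.0, 2.0)]:
            P = base.copy()
            _apply_schedule_step(sched, P, base.copy(), base, base, t, 2.0,
                                 np.ones(4, bool))
            assert P[1] == pytest.approx(expect)
            assert P[0] == 0.0

    def test_onset_schedule_structure(self):
        patches = [np.array([1, 2]), np.array([5, 6]), np.array([8, 9])]
        sched = make_onset_schedule(patches, P_patch_end=1.0, ramp_ms=3000.0,
                                    gap_ms=50.0, P_surround=-2.5)
        kinds = [e.kind for e in sched.events]
        assert kinds == ["set", "ramp", "ramp", "ramp"]
        starts = [e.t_start for e in sched.events if e.kind == "ramp"]
        assert starts == [0.0, 50.0, 100.0]
        assert all(e.duration == 3000.0 for e in sched.events
                   if e.kind == "ramp")

    def test_onset_schedule_single_patch_and_zero_gap(self):
        one = make_onset_schedule([np.array([3])], 1.0, P_surround=-1.5)
        assert len(one.events) == 2
        sim = make_onset_schedule([np.array([1]), np.array([2])], 1.0,
                                  gap_ms=0.0, P_surround=-1.5)
        ramps = [e for e in sim.events if e.kind == "ramp"]
        assert ramps[0].t_start == ramps[1].t_start == 0.0

    def test_overlapping_patches_rejected(self):
        with pytest.raises(ValueError):
            make_onset_schedule([np.array([1, 2]), np.array([2, 3])], 1.0,
                                P_surround=-1.5)

    def test_stimulation_schedule_timing(self):
        geom = ish.SheetGeometry()
        sites = default_stimulation_sites(geom)
        assert len(sites) == 9
        rr, cc = geom.rc(np.array(sites))
        assert sorted(set(rr)) == [25, 75, 125]
        assert sorted(set(cc)) == [25, 75, 125]
        sched = make_stimulation_schedule(sites, total_ms=1200.0)
        pulses = sched.pulses()
        assert len(pulses) == 9 * 3  # 9 per 400 ms cycle
        first_cycle = sorted(p.t_start for p in pulses if p.t_start < 400)
        assert np.allclose(np.diff(first_cycle), 12.0)  # 6 ms on + 6 ms gap
        assert all(p.duration == 6.0 and p.value == 5.0 for p in pulses)
        # one site at a time: intervals never overlap
        iv = sorted((p.t_start, p.t_start + p.duration) for p in pulses)
        assert all(b0 >= a1 for (_, a1), (b0, _) in zip(iv, iv[1:]))

    def test_stimulation_overlap_rejected(self):
        with pytest.raises(ValueError):
            make_stimulation_schedule(list(range(9)), total_ms=400.0,
                                      pulse_ms=50.0)
        with pytest.raises(ValueError):
            make_stimulation_schedule([1], total_ms=100.0)


class TestResectionFreezing:
    def test_masked_columns_frozen_and_excluded(self, geom20):
        conn = ish.build_connectivity(geom20, ish.ConnectivityConfig(seed=1))
        mask = ResectionMask.strip(geom20, col_start=0, width=4)
        cut = ish.apply_resection(conn, mask)
        res = ish.simulate(ish.DEFAULT_PARAMS, cut, EventSchedule(), 1000.0,
                           NoiseModel(seed=4), geometry=geom20,
                           resection_mask=mask,
                           **_uniform_fields(geom20, -1.5))
        frozen = res.E[:, mask.indices]
        assert (frozen == frozen[0]).all()
        assert not res.active_mask[mask.indices].any()
        # the ECoG averages active columns only
        sig_len = len(ish.mean_lfp(res))
        assert sig_len == res.E.shape[0]

    def test_schedule_on_masked_columns_rejected(self, geom20):
        conn = ish.build_connectivity(geom20, ish.ConnectivityConfig(seed=1))
        mask = ResectionMask.strip(geom20, col_start=0, width=4)
        sched = EventSchedule([Event("pulse", "P", (0,), 0.0, 10.0, 5.0)])
        with pytest.raises(ValueError):
            ish.simulate(ish.DEFAULT_PARAMS, conn, sched, 100.0,
                         NoiseModel(seed=0), geometry=geom20,
                         resection_mask=mask,
                         **_uniform_fields(geom20, -1.5))


class TestPersistence:
    def test_hdf5_roundtrip(self, conn20, geom20, tmp_path):
        res = ish.simulate(ish.DEFAULT_PARAMS, conn20, EventSchedule(),
                           500.0, NoiseModel(seed=5), geometry=geom20,
                           **_uniform_fields(geom20, -2.5))
        path = str(tmp_path / "run.h5")
        save_result(res, path)
        back = load_result(path)
        assert np.array_equal(res.E, back.E)
        assert np.array_equal(res.noise, back.noise)
        assert back.geometry == geom20
        assert back.provenance["noise"]["seed"] == 5
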