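"""Pacing sites, reentry detection and morphology counting."""
import numpy as np
import pytest

from virtuheart import induction as ind, monodomain as md, synthetic
from virtuheart.induction import (PacingProtocol, ReentryDescriptor,
                                  SECTOR_NAMES, count_unique_morphologies,
                                  detect_reentry, place_pacing_sites)
from virtuheart.monodomain import ActivationRecord


def make_record(times_list, coords, t_end, status=0, n_state=21):
    n = len(times_list)
    k = max((len(ts) for ts in times_list), default=1)
    times = np.full((n, max(k, 1)), np.nan)
    counts = np.zeros(n, dtype=np.int64)
    for i, ts in enumerate(times_list):
        times[i, :len(ts)] = ts
        counts[i] = len(ts)
    return ActivationRecord(times=times, counts=counts,
                            coords=np.asarray(coords, dtype=float),
                            t_start=0.0, t_end=t_end, last_stim_end=0.0,
                            status=status,
                            final_state=np.zeros((n_state, n)))


class TestPlacePacingSites:
    def test_seven_distinct_sectors_on_annulus(self, annulus_grid):
        sites = place_pacing_sites(annulus_grid)
        assert len(sites) == 7
        assert sorted(s.sector for s in sites) == list(range(7))
        names = {s.name for s in sites}
        assert "mid anteroseptal" in names
        assert "basal inferolateral" in names

    def test_sites_on_endocardial_boundary(self, annulus_grid):
        from virtuheart.geometry import find_transmural_boundaries
        endo, _ = find_transmural_boundaries(annulus_grid)
        for s in place_pacing_sites(annulus_grid):
            assert np.isin(s.grid_nodes, endo).all()

    def test_slab_without_cavity_rejected(self, slab_grid):
        with pytest.raises(ValueError):
            place_pacing_sites(slab_grid)


class TestDetectReentry:
    coords = [[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]] * 5

    def test_quiescent_record_negative(self):
        rec = make_record([[100.0]] * 15, self.coords, 3000.0)
        induced, desc = detect_reentry(rec, 500.0, 2000.0)
        assert not induced and desc is None

    def test_single_echo_beat_negative(self):
        """One extra reactivation then silence fails the >=2-cycle rule."""
        rec = make_record([[520.0, 800.0]] * 15, self.coords, 3000.0)
        induced, _ = detect_reentry(rec, 510.0, 2000.0)
        assert not induced

    def test_sustained_cycles_positive_with_cycle_length(self):
        times = [[520.0 + i, 820.0 + i, 1120.0 + i, 1420.0 + i, 1720.0 + i]
                 for i in range(15)]
        rec = make_record(times, self.coords, 3000.0)
        induced, desc = detect_reentry(rec, 510.0, 2000.0,
                                       center=np.array([0.0, 0.0]),
                                       inducing_site=2)
        assert induced
        assert desc.cycle_length_ms == pytest.approx(300.0, abs=5.0)
        assert desc.inducing_site == 2

    def test_activity_dying_early_negative(self):
        """Cycles that stop well before the window's midpoint do not count
        as sustained."""
        times = [[520.0, 700.0, 880.0]] * 15
        rec = make_record(times, self.coords, 3000.0)
        induced, _ = detect_reentry(rec, 510.0, 2000.0)
        assert not induced

    def test_truncated_record_rejected(self):
        rec = make_record([[100.0]] * 15, self.coords, 900.0)
        with pytest.raises(ValueError):
            detect_reentry(rec, 500.0, 2000.0)

    def test_cross_field_rotor_detected_with_core(self):
        """A rotating activation sequence around a core yields detection and
        localizes the core sector."""
        n = 24
        ang = np.linspace(-np.pi, np.pi, n, endpoint=False)
        # rotor at center of a ring of radius 10 centered at origin: nodes
        # activate in angular order, period 240 ms, 5 laps
        coords = np.stack([10 * np.cos(ang), 10 * np.sin(ang)], axis=1)
        times = []
        for a in ang:
            first = 520.0 + (a + np.pi) / (2 * np.pi) * 240.0
            times.append([first + k * 240.0 for k in range(5)])
        rec = make_record(times, coords, 3000.0)
        induced, desc = detect_reentry(rec, 510.0, 2000.0,
                                       center=np.array([0.0, 0.0]))
        assert induced
        assert desc.cycle_length_ms == pytest.approx(240.0, abs=2.0)
        # core = earliest re-activated region, i.e. angle ~ -pi -> sector 0
        assert desc.core_sector == 0


class TestMorphologyCounting:
    def d(self, cl, sector, site=0):
        return ReentryDescriptor(cycle_length_ms=cl, core_sector=sector,
                                 core_xy=(0.0, 0.0), inducing_site=site)

    def test_empty(self):
        assert count_unique_morphologies([]) == 0

    def test_same_core_and_cl_from_two_sites_is_one(self):
        assert count_unique_morphologies(
            [self.d(300.0, 2, site=1), self.d(310.0, 2, site=5)]) == 1

    def test_three_distinct_cores(self):
        assert count_unique_morphologies(
            [self.d(300.0, 0), self.d(300.0, 3), self.d(300.0, 5)]) == 3

    def test_cl_difference_splits(self):
        assert count_unique_morphologies(
            [self.d(300.0, 2), self.d(400.0, 2)]) == 2


class TestProtocol:
    def test_couplings_strictly_decreasing(self):
        p = PacingProtocol.desk()
        c = p.s2_couplings()
        assert (np.diff(c) < 0).all()
        assert c.min() >= p.s2_minimum_ms

    def test_invalid_protocols_rejected(self):
        with pytest.raises(ValueError):
            PacingProtocol(s1_count=0)
        with pytest.raises(ValueError):
            PacingProtocol(s2_decrement_ms=-5.0)

    def test_zero_extrastimuli_never_induces(self):
        """The drive train alone (no premature beats) cannot induce."""
        cfg = md.desk_config()
        lm = synthetic.generate_substrate_phantom("scar_isthmus",
                                                  remodeled_channel=True)
        grid, mesh = ind.build_substrate(lm, cfg)
        proto = PacingProtocol(s1_count=2, s1_cycle_ms=500.0,
                               s2_initial_fraction=0.63,
                               s2_decrement_ms=15.0, s2_minimum_ms=255.0,
                               max_extrastimuli=0,
                               observation_window_ms=1500.0)
        for site in place_pacing_sites(grid)[:3]:
            res = ind.run_protocol(mesh, site, proto, cfg)
            assert not res.induced

    def test_protocol_deterministic(self):
        """Identical substrate and protocol give identical results."""
        cfg = md.desk_config()
        lm = synthetic.generate_substrate_phantom("scar_isthmus",
                                                  remodeled_channel=True)
        grid, mesh = ind.build_substrate(lm, cfg)
        proto = PacingProtocol.desk()
        site = place_pacing_sites(grid)[4]
        r1 = ind.run_protocol(mesh, site, proto, cfg)
        r2 = ind.run_protocol(mesh, site, proto, cfg)
        assert r1.induced == r2.induced
        assert r1.coupling_ms == r2.coupling_ms
        if r1.descriptor:
            assert r1.descriptor.cycle_length_ms == \
                r2.descriptor.cycle_length_ms
            assert r1.descriptor.core_sector == r2.descriptor.core_sector
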