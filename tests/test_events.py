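"""T1 / T2 / division events and their bookkeeping invariants."""

import numpy as np
import pytest

from sphervert import core, events, mesh
from sphervert.core import validate_topology


def counts(st):
    top = st.topology
    return top.n_vertices, top.n_edges, top.n_cells


class TestT1:
    def test_swap_changes_neighbour_counts(self, mesh200):
        st = mesh200
        top = st.topology
        e = tuple(map(int, top.edge_rows[40]))
        shared = [int(top.cell_ids[c]) for c in top.edge_cells[40]]
        ring_before = {c: len(st.ring(c)) for c in st.alive_cells}
        v, ed, f = counts(st)
        assert events.t1_transition(st, e, check_length=False)
        assert counts(st) == (v, ed, f)
        assert validate_topology(st).ok
        for c in shared:
            assert len(st.ring(c)) == ring_before[c] - 1
        gained = [c for c in st.alive_cells
                  if len(st.ring(c)) == ring_before[int(c)] + 1]
        assert len(gained) == 2

    def test_new_junction_opens_above_trigger(self, mesh200):
        st = mesh200
        top = st.topology
        thr = events.EventThresholds()
        e = tuple(map(int, top.edge_rows[13]))
        assert events.t1_transition(st, e, thr, check_length=False)
        L = np.linalg.norm(st.positions[e[1]] - st.positions[e[0]])
        assert L == pytest.approx(thr.t1_new_edge)
        assert L > thr.t1_min_edge

    def test_triangle_incident_edge_is_skipped(self, mesh200):
        st = mesh200
        # divide cells until a triangle appears, then target one of its
        # edges: the swap would create a 2-gon and must be refused
        rng = np.random.default_rng(0)
        tri = None
        for _ in range(300):
            events.divide_cell(st, int(rng.choice(st.alive_cells)))
            tri = next((c for c in st.alive_cells
                        if len(st.ring(c)) == 3), None)
            if tri is not None:
                break
        assert tri is not None
        ring = st.ring(tri)
        before = [list(st.ring(c)) for c in st.alive_cells]
        assert not events.t1_transition(st, (ring[0], ring[1]),
                                        check_length=False)
        assert [list(st.ring(c)) for c in st.alive_cells] == before

    def test_length_gate(self, mesh200):
        st = mesh200
        top = st.topology
        e = tuple(map(int, top.edge_rows[0]))
        # fixture edges are far longer than the 3 um trigger
        assert not events.t1_transition(st, e)


class TestT2:
    @staticmethod
    def make_triangle(st, rng):
        tri = None
        while tri is None:
            events.divide_cell(st, int(rng.choice(st.alive_cells)))
            tri = next((c for c in st.alive_cells
                        if len(st.ring(c)) == 3), None)
        return tri

    def test_extrusion_bookkeeping(self, mesh200):
        st = mesh200
        rng = np.random.default_rng(1)
        tri = self.make_triangle(st, rng)
        nbr_len = {}
        vmap = events.VertexCellMap(st)
        for v in st.ring(tri):
            for c in vmap[v]:
                if c != tri:
                    nbr_len[c] = len(st.ring(c))
        v0, e0, f0 = counts(st)
        assert events.t2_extrusion(st, tri, check_area=False)
        assert counts(st) == (v0 - 2, e0 - 3, f0 - 1)
        assert validate_topology(st).ok
        for c, n in nbr_len.items():
            assert len(st.ring(c)) == n - 1

    def test_area_threshold_respected(self, mesh200):
        st = mesh200
        rng = np.random.default_rng(2)
        tri = self.make_triangle(st, rng)
        area, _, _, _ = core.cell_geometry(st, tri)
        thr = events.EventThresholds(t2_min_area=50.0)
        if area >= 50.0:
            assert not events.t2_extrusion(st, tri, thr)
        thr_big = events.EventThresholds(t2_min_area=area + 1)
        assert events.t2_extrusion(st, tri, thr_big)

    def test_non_triangles_never_extrude(self, mesh200):
        st = mesh200
        quad = next(c for c in st.alive_cells if len(st.ring(c)) >= 4)
        assert not events.t2_extrusion(st, quad, check_area=False)


class TestDivision:
    def test_rectangle_splits_into_equal_halves(self):
        # 2:1 rectangle on top of a closed pillow: the cut runs along
        # the short axis, giving daughters of equal area
        from conftest import make_pillow
        st, ids, front = make_pillow(
            [[0, 0, 50], [2, 0, 50], [2, 1, 50], [0, 1, 50]])
        a_parent, _, _, _ = core.cell_geometry(st, front)
        st.area0[front] = 2.0
        res = events.divide_cell(st, front)
        assert res is not None
        d1, d2 = res
        a1, _, _, _ = core.cell_geometry(st, d1)
        a2, _, _, _ = core.cell_geometry(st, d2)
        assert a1 == pytest.approx(a2, rel=1e-6)
        assert a1 + a2 == pytest.approx(a_parent, rel=1e-9)
        assert st.area0[d1] == st.area0[d2] == pytest.approx(1.0)
        # cut perpendicular to the long (x) side
        shared = set(st.ring(d1)) & set(st.ring(d2))
        p = st.positions[sorted(shared)]
        cut = p[1] - p[0]
        assert abs(cut[0]) < 1e-9 * abs(cut[1])

    def test_euler_bookkeeping_and_inheritance(self, mesh200):
        st = mesh200
        c = int(st.alive_cells[10])
        st.polarity[c] = [0.0, 0.4, 0.1]
        st.molecules[c] = [1.0, 2.0, 3.0]
        a0 = st.area0[c]
        v0, e0, f0 = counts(st)
        res = events.divide_cell(st, c, next_times=(0.7, 0.9))
        assert res is not None
        d1, d2 = res
        assert counts(st) == (v0 + 2, e0 + 3, f0 + 1)
        assert validate_topology(st).ok
        for d in (d1, d2):
            assert st.area0[d] == pytest.approx(a0 / 2)
            assert st.molecules[d] == pytest.approx([1.0, 2.0, 3.0])
            assert st.polarity[d] == pytest.approx([0.0, 0.4, 0.1])
        assert st.next_division[d1] == 0.7
        assert st.next_division[d2] == 0.9
        assert not st._c_alive[c]

    def test_division_conserves_total_area(self, mesh200):
        st = mesh200
        area0, _, _, _ = core.cell_geometry_arrays(st)
        total0 = area0.sum()
        rng = np.random.default_rng(4)
        for _ in range(50):
            events.divide_cell(st, int(rng.choice(st.alive_cells)))
        area1, _, _, _ = core.cell_geometry_arrays(st)
        assert area1.sum() == pytest.approx(total0, rel=0.01)

    def test_triangles_are_deferred(self, mesh200):
        st = mesh200
        rng = np.random.default_rng(5)
        tri = TestT2.make_triangle(st, rng)
        assert events.divide_cell(st, tri) is None


class TestScheduling:
    def test_first_divisions_fill_the_window(self, mesh200):
        st = mesh200
        st.divides[st.alive_cells] = True
        sched = events.DivisionSchedule(first_division_window=0.25)
        events.initialize_division_times(st, sched)
        t = st.next_division[st.alive_cells]
        assert (t >= 0).all() and (t <= 0.25).all()
        assert t.std() > 0.01

    def test_target_above_current_required(self, mesh20):
        mesh20.divides[mesh20.alive_cells] = True
        with pytest.raises(ValueError):
            events.initialize_division_times(
                mesh20, events.DivisionSchedule(target_count=10))

    def test_truncated_cycles_are_positive(self):
        rng = np.random.default_rng(0)
        sched = events.DivisionSchedule(cycle_mean=0.2, cycle_sd=0.3)
        draws = [events.draw_cycle(rng, sched) for _ in range(500)]
        assert min(draws) > sched.min_cycle

    def test_sweep_is_seed_deterministic(self, mesh200_master):
        logs = []
        for _ in range(2):
            st = mesh200_master.copy()
            st.rng = np.random.default_rng(11)
            st.divides[st.alive_cells] = True
            sched = events.DivisionSchedule(cycle_mean=0.2, cycle_sd=0.05,
                                            target_count=260)
            events.initialize_division_times(st, sched)
            st.time = 0.3
            for _ in range(5):
                events.sweep_events(st, events.EventThresholds(), sched)
                st.time += 0.05
            logs.append(st.event_log)
        assert logs[0] == logs[1]

    def test_divisions_stop_exactly_at_target(self, mesh200):
        st = mesh200
        st.rng = np.random.default_rng(3)
        st.divides[st.alive_cells] = True
        sched = events.DivisionSchedule(cycle_mean=0.05, cycle_sd=0.01,
                                        target_count=321)
        events.initialize_division_times(st, sched)
        for _ in range(40):
            st.time += 0.05
            events.sweep_events(st, events.EventThresholds(), sched)
        assert st.n_cells == 321


class TestGrowth:
    def test_phase_scoped_growth(self, mesh20):
        st = mesh20
        cells = st.alive_cells
        st.cell_type[cells[0]] = core.ABEMBRYONIC
        st.cell_type[cells[1]] = core.EXTRAEMBRYONIC
        a0 = st.area0[cells].copy()
        st.phase = "germ_disc"
        events.grow_preferred_area(st, 0.5, rate_abembryonic=200.0,
                                   rate_extraembryonic=4800.0)
        assert st.area0[cells[0]] == pytest.approx(a0[0] + 100.0)
        assert st.area0[cells[1]] == a0[1]
        assert (st.area0[cells[2:]] == a0[2:]).all()
        st.phase = "germ_band"
        events.grow_preferred_area(st, 0.25, rate_abembryonic=200.0,
                                   rate_extraembryonic=4800.0)
        assert st.area0[cells[1]] == pytest.approx(a0[1] + 1200.0)
        assert st.area0[cells[0]] == pytest.approx(a0[0] + 100.0)


def test_stress_mixed_events_preserve_topology(mesh200):
    """~10^4 mixed forced T1 / T2 / division events keep the closed-mesh
    invariants and the exact lineage count identity."""
    st = mesh200
    rng = np.random.default_rng(7)
    n_events = {"t1": 0, "t2": 0, "division": 0}
    start = st.n_cells
    for step in range(10_000):
        kind = rng.choice(["t1", "division", "t2"], p=[0.6, 0.3, 0.1])
        if kind == "t1":
            top = st.topology
            e = tuple(map(int, top.edge_rows[
                rng.integers(top.n_edges)]))
            if events.t1_transition(st, e, check_length=False):
                n_events["t1"] += 1
        elif kind == "division":
            c = int(rng.choice(st.alive_cells))
            if events.divide_cell(st, c) is not None:
                n_events["division"] += 1
        else:
            tris = [c for c in st.alive_cells if len(st.ring(c)) == 3]
            if tris:
                c = int(rng.choice(tris))
                if events.t2_extrusion(st, c, check_area=False):
                    n_events["t2"] += 1
        if step % 500 == 0:
            top = st.topology
            assert top.n_vertices - top.n_edges + top.n_cells == 2
    rep = validate_topology(st)
    assert rep.ok, rep.violations
    assert sum(n_events.values()) >= 10_000 * 0.5
    assert st.n_cells == start + n_events["division"] - n_events["t2"]
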