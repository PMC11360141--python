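"""Link mechanics: elastic and constant-tension energies, Poisson
turnover, lamellipodium and follower-substrate lifecycles."""

import math

import numpy as np
import pytest

from mesocpm import SimConfig
from mesocpm.links import (Link, LinkKind, elastic_energy, tension_energy,
                           turnover_fires, turnover_probability,
                           cycle_lamellipodium, cycle_follower_substrate,
                           mark_satisfied, place_lamellipodium)
from mesocpm.potts import monte_carlo_step
from mesocpm.state import CellType
from mesocpm.geometry import make_dmz_state

from conftest import make_single_cube_state, make_two_cell_state


def spring(lam=3.0, L=5.0):
    return Link(id=1, kind=LinkKind.CELL_CELL, cell_a=1, cell_b=2,
                lam=lam, target_length=L)


def lamellipodium(lam=4.0, anchor=(0.0, 0.0, 0.0)):
    return Link(id=2, kind=LinkKind.LAMELLIPODIUM, cell_a=1,
                anchor=np.asarray(anchor, float), lam=lam)


class TestEnergies:
    @pytest.mark.parametrize("lam, L, pa, pb, expected", [
        (7.0, 5.0, (0, 0, 0), (5, 0, 0), 0.0),     # at rest length
        (0.0, 5.0, (0, 0, 0), (9, 0, 0), 0.0),     # zero stiffness
        (3.0, 5.0, (0, 0, 0), (7, 0, 0), 12.0),    # 3 * (7-5)^2
    ])
    def test_elastic_quadratic_form(self, lam, L, pa, pb, expected):
        assert elastic_energy(spring(lam, L), pa, pb) \
            == pytest.approx(expected)

    def test_tension_linear_in_length(self):
        l = lamellipodium(lam=4.0)
        assert tension_energy(l, (0, 0, 0), l.anchor) == 0.0
        e1 = tension_energy(l, (3, 4, 0), l.anchor)
        e2 = tension_energy(l, (6, 8, 0), l.anchor)
        assert e2 == pytest.approx(2 * e1)
        assert tension_energy(l, (0, 0, 5), l.anchor) == pytest.approx(20.0)

    @pytest.mark.parametrize("l0", [2.0, 5.0, 9.0])
    def test_tension_force_is_length_independent(self, l0):
        # numeric dE/dl must equal lambda at any length
        link = lamellipodium(lam=4.0)
        h = 1e-6
        e = lambda l: tension_energy(link, (l, 0.0, 0.0), link.anchor)
        force = (e(l0 + h) - e(l0 - h)) / (2 * h)
        assert force == pytest.approx(4.0, rel=1e-6)

    def test_satisfied_lamellipodium_exerts_no_energy(self):
        link = lamellipodium(lam=4.0)
        link.satisfied = True
        assert tension_energy(link, (10, 0, 3), link.anchor) == 0.0


class TestTurnover:
    def test_zero_rate_never_fires(self, rng):
        assert turnover_probability(0.0) == 0.0
        assert not any(turnover_fires(0.0, rng) for _ in range(1000))

    def test_probability_closed_form(self):
        assert turnover_probability(0.1) \
            == pytest.approx(1 - math.exp(-0.1))
        with pytest.raises(ValueError):
            turnover_probability(-0.5)

    def test_empirical_frequency_within_three_sigma(self):
        zeta = 0.1
        p = 1 - math.exp(-zeta)
        n = 100_000
        rng = np.random.default_rng(17)
        fires = sum(turnover_fires(zeta, rng) for _ in range(n))
        sigma = math.sqrt(n * p * (1 - p))
        assert abs(fires - n * p) <= 3 * sigma


class TestLamellipodiumCycle:
    def test_surrounded_leader_forms_no_link(self):
        # leader enclosed by followers on all sides has no free edge and
        # behaves as a follower
        st, (a, b) = make_two_cell_state(
            v_edge=3, types=(CellType.LEADER, CellType.FOLLOWER))
        # enclose cell a fully: fill all its non-cell neighbors with cell b
        vox = st.cell_voxels(a)
        for d in [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1)]:
            for v in vox:
                n = v + d
                if st.owner[tuple(n)] == 0:
                    st.owner[tuple(n)] = b
                    st.volume[b] += 1
                    st.sum_x[b] += n[0]
                    st.sum_y[b] += n[1]
                    st.sum_z[b] += n[2]
        cfg = SimConfig().replace(zeta_lamellipodia=10.0)  # fires surely
        link = cycle_lamellipodium(st, a, cfg, np.random.default_rng(0))
        assert link is None
        assert st.links.links_of(a, LinkKind.LAMELLIPODIUM) == []

    def test_zero_rate_preserves_existing_link(self):
        st, cid = make_single_cube_state(ctype=CellType.LEADER)
        cfg = SimConfig().replace(zeta_lamellipodia=0.0)
        link = place_lamellipodium(st, cid, (8, 6, 1), cfg)
        out = cycle_lamellipodium(st, cid, cfg, np.random.default_rng(0))
        assert out is None
        assert st.links.links_of(cid, LinkKind.LAMELLIPODIUM) \
            == [link]

    def test_anchor_distance_equals_chi_in_plane(self):
        st, cid = make_single_cube_state(v_edge=5, ctype=CellType.LEADER)
        cfg = SimConfig().replace(zeta_lamellipodia=10.0,
                                  chi_lamellipodia=4.0)
        rng = np.random.default_rng(21)
        for _ in range(100):
            link = cycle_lamellipodium(st, cid, cfg, rng)
            assert link is not None
            # reconstruct the selected voxel: anchor lies chi beyond it,
            # so its in-plane distance to some free-edge voxel is chi
            from mesocpm.cohesotaxis import free_edge_voxels
            free = free_edge_voxels(st, cid)
            d = np.hypot(free[:, 0] - link.anchor[0],
                         free[:, 1] - link.anchor[1])
            assert d.min() <= cfg.chi_lamellipodia + 1.0

    def test_blocked_state_deletes_without_reforming(self):
        st, cid = make_single_cube_state(ctype=CellType.LEADER)
        cfg = SimConfig().replace(zeta_lamellipodia=10.0)
        place_lamellipodium(st, cid, (8, 6, 1), cfg)
        st.lamellipodia_blocked = True
        out = cycle_lamellipodium(st, cid, cfg, np.random.default_rng(0))
        assert out is None
        assert st.links.links_of(cid, LinkKind.LAMELLIPODIUM) == []


class TestMarkSatisfied:
    def test_centroid_at_anchor_satisfies(self):
        link = lamellipodium(anchor=(4.0, 4.0, 0.0))
        mark_satisfied(link, (4.0, 4.0, 3.0), tolerance=1.0)
        assert link.satisfied

    def test_far_centroid_unchanged(self):
        link = lamellipodium(anchor=(4.0, 4.0, 0.0))
        mark_satisfied(link, (9.0, 4.0, 3.0), tolerance=1.0)
        assert not link.satisfied

    def test_satisfaction_stalls_forward_progress(self):
        """A lone leader with a never-recycled satisfied lamellipodium
        stops advancing; with an active link it advances."""
        cfg = SimConfig().replace(zeta_lamellipodia=0.0)
        gains = {}
        for satisfied in (False, True):
            disp = []
            for seed in range(5):
                st, cid = make_single_cube_state(v_edge=5,
                                                 ctype=CellType.LEADER)
                link = place_lamellipodium(st, cid, (11, 6, 1), cfg)
                link.satisfied = satisfied
                rng = np.random.default_rng(seed)
                x0 = st.centroid(cid)[0]
                for _ in range(40):
                    monte_carlo_step(st, cfg, rng)
                disp.append(st.centroid(cid)[0] - x0)
            gains[satisfied] = np.mean(disp)
        assert gains[False] > gains[True] + 0.3
        assert abs(gains[True]) < 0.5


class TestFollowerSubstrate:
    def test_follower_without_substrate_contact_holds_no_link(self):
        st, cid = make_single_cube_state(ctype=CellType.FOLLOWER,
                                         floating=True)
        cfg = SimConfig()
        out = cycle_follower_substrate(st, cid, cfg,
                                       np.random.default_rng(0))
        assert out is None
        assert st.links.links_of(cid) == []

    def test_zero_rate_anchor_never_moves(self):
        st, cid = make_single_cube_state(ctype=CellType.FOLLOWER)
        cfg = SimConfig().replace(zeta_substrate=0.0)
        rng = np.random.default_rng(0)
        first = cycle_follower_substrate(st, cid, cfg, rng)
        anchor = first.anchor.copy()
        for _ in range(50):
            cycle_follower_substrate(st, cid, cfg, rng)
        links = st.links.links_of(cid, LinkKind.FOLLOWER_SUBSTRATE)
        assert len(links) == 1
        assert np.array_equal(links[0].anchor, anchor)

    def test_faster_cycling_tracks_the_cell_more_closely(self):
        """Mean anchor-to-centroid in-plane distance decreases as
        zeta_substrate increases (faster re-anchoring)."""
        cfg0 = SimConfig()
        means = []
        for zeta in (0.01, 0.1, 0.5):
            dists = []
            for seed in range(10):
                st, info = make_dmz_state(
                    cfg0, np.random.default_rng(seed),
                    width_cells=2, length_cells=2, height_cells=1,
                    forward_margin=14, back_margin=4, side_margin=4)
                cfg = cfg0.replace(zeta_substrate=zeta)
                rng = np.random.default_rng(seed)
                for _ in range(60):
                    monte_carlo_step(st, cfg, rng)
                for l in st.links.of_kind(LinkKind.FOLLOWER_SUBSTRATE):
                    c = st.centroid(l.cell_a)
                    dists.append(np.hypot(c[0] - l.anchor[0],
                                          c[1] - l.anchor[1]))
            means.append(np.mean(dists))
        assert means[0] > means[-1]

    def test_all_zero_rates_leave_link_set_invariant(self):
        cfg = SimConfig().replace(zeta_lamellipodia=0.0, zeta_substrate=0.0,
                                  zeta_tissue=0.0)
        st, info = make_dmz_state(cfg, np.random.default_rng(0),
                                  width_cells=3, length_cells=2,
                                  height_cells=1, forward_margin=14,
                                  back_margin=4, side_margin=4)
        before = {(l.id, l.kind, l.cell_a, l.cell_b) for l in st.links}
        rng = np.random.default_rng(1)
        for _ in range(30):
            monte_carlo_step(st, cfg, rng)
        after = {(l.id, l.kind, l.cell_a, l.cell_b) for l in st.links}
        assert before == after
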