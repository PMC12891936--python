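"""Unit and property tests of the zonal school simulator."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from schooldyn import (
    SchoolState,
    SimParams,
    apply_rotational_noise,
    classify_neighbors,
    constrain_turn,
    desired_heading,
    init_random_school,
    simulate,
    step_school,
)
from schooldyn.model import _desired_headings_all


def angle_between(a, b):
    return np.arccos(np.clip(np.dot(a, b), -1.0, 1.0))


# ---------------------------------------------------------------- parameters


@pytest.mark.parametrize(
    "bad",
    [
        {"n": 0},
        {"z_r": 0.0},
        {"z_l": -1.0},
        {"alpha": 0.0},
        {"alpha": 400.0},
        {"theta_max": 200.0},
        {"speed": -1.0},
        {"sigma": -0.1},
        {"dt": 0.0},
        {"turn_limit_mode": "bogus"},
        {"term_weighting": "bogus"},
    ],
)
def test_invalid_params_rejected(bad):
    with pytest.raises(ValueError):
        SimParams(**bad)


def test_theta_cap_modes():
    p_rate = SimParams(theta_max=40.0, dt=0.2, turn_limit_mode="rate")
    p_step = SimParams(theta_max=40.0, dt=0.2, turn_limit_mode="per_step")
    assert p_rate.theta_cap == pytest.approx(np.radians(8.0))
    assert p_step.theta_cap == pytest.approx(np.radians(40.0))


# ------------------------------------------------------------ initialization


def test_random_school_in_unit_cube():
    p = SimParams(n=100)
    st = init_random_school(p, 11)
    assert st.t == 0.0
    assert np.all((st.positions >= 0.0) & (st.positions <= 1.0))
    assert np.allclose(np.linalg.norm(st.headings, axis=1), 1.0, atol=1e-12)


def test_random_school_deterministic():
    p = SimParams(n=50)
    a = init_random_school(p, 42)
    b = init_random_school(p, 42)
    assert np.array_equal(a.positions, b.positions)
    assert np.array_equal(a.headings, b.headings)


def test_random_headings_isotropic():
    # mean of many unit headings should be near zero in every component
    st = init_random_school(SimParams(n=4000), 1)
    assert np.all(np.abs(st.headings.mean(axis=0)) < 0.05)


# ------------------------------------------------------- neighbour geometry


def _two_fish_state(pos_j, heading_i=(1.0, 0.0, 0.0)):
    pos = np.array([[0.0, 0.0, 0.0], list(pos_j)])
    hdg = np.array([list(heading_i), [1.0, 0.0, 0.0]])
    hdg = hdg / np.linalg.norm(hdg, axis=1)[:, None]
    return SchoolState(0.0, pos, hdg)


def test_repulsion_zone_membership():
    p = SimParams(z_r=1.0, z_l=2.0, z_a=10.0)
    st = _two_fish_state((0.5, 0.0, 0.0))
    ns = classify_neighbors(st, 0, p)
    assert list(ns.rep_ids) == [1]
    assert len(ns.align_ids) == len(ns.attract_ids) == 0


def test_blind_cone_excludes_rear_neighbour():
    # neighbour dead astern at alignment-shell distance, alpha=270 so the
    # rear 90-degree cone is blind
    p = SimParams(z_r=1.0, z_l=2.0, z_a=10.0, alpha=270.0)
    st = _two_fish_state((-2.0, 0.0, 0.0))
    ns = classify_neighbors(st, 0, p)
    assert len(ns.align_ids) == 0 and len(ns.attract_ids) == 0
    # but repulsion-zone membership is not vision-censored
    st2 = _two_fish_state((-0.5, 0.0, 0.0))
    assert list(classify_neighbors(st2, 0, p).rep_ids) == [1]


def test_zone_boundaries_closed_right():
    p = SimParams(z_r=1.0, z_l=2.0, z_a=10.0)
    at_align_outer = _two_fish_state((3.0, 0.0, 0.0))  # d == z_r + z_l
    ns = classify_neighbors(at_align_outer, 0, p)
    assert list(ns.align_ids) == [1] and len(ns.attract_ids) == 0
    at_rep = _two_fish_state((1.0, 0.0, 0.0))  # d == z_r
    assert list(classify_neighbors(at_rep, 0, p).rep_ids) == [1]


def test_neighbor_sets_disjoint_and_exclude_focal(rng):
    p = SimParams(z_r=1.0, z_l=1.5, z_a=3.0)
    pos = rng.uniform(0, 6, size=(40, 3))
    hdg = rng.standard_normal((40, 3))
    hdg /= np.linalg.norm(hdg, axis=1)[:, None]
    st = SchoolState(0.0, pos, hdg)
    for focal in range(0, 40, 7):
        ns = classify_neighbors(st, focal, p)
        sets = [set(ns.rep_ids), set(ns.align_ids), set(ns.attract_ids)]
        assert all(focal not in s for s in sets)
        assert not (sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2])


def brute_force_neighbors(st, focal, p):
    """Independent O(N^2) reimplementation of the zone rules."""
    rep, ali, att = [], [], []
    for j in range(st.n):
        if j == focal:
            continue
        d = np.linalg.norm(st.positions[j] - st.positions[focal])
        visible = angle_between(
            st.headings[focal],
            (st.positions[j] - st.positions[focal]) / d,
        ) <= np.radians(p.alpha) / 2
        if d <= p.z_r:
            if visible or not p.blind_cone_repulsion:
                rep.append(j)
        elif d <= p.z_r + p.z_l and visible:
            ali.append(j)
        elif d <= p.z_r + p.z_l + p.z_a and visible:
            att.append(j)
    return rep, ali, att


def test_classification_matches_brute_force_oracle():
    # 200 random configurations, every focal fish
    rng = np.random.default_rng(999)
    p = SimParams(n=12, z_r=1.0, z_l=1.5, z_a=2.5)
    for _ in range(200):
        pos = rng.uniform(0, 5, size=(12, 3))
        hdg = rng.standard_normal((12, 3))
        hdg /= np.linalg.norm(hdg, axis=1)[:, None]
        st = SchoolState(0.0, pos, hdg)
        for focal in range(12):
            ns = classify_neighbors(st, focal, p)
            rep, ali, att = brute_force_neighbors(st, focal, p)
            assert list(ns.rep_ids) == rep
            assert list(ns.align_ids) == ali
            assert list(ns.attract_ids) == att


# ----------------------------------------------------------- desired heading


def test_repulsion_overrides_everything(eq1_params):
    st = _two_fish_state((0.5, 0.0, 0.0))
    d = desired_heading(st, 0, eq1_params)
    assert np.allclose(d, [-1.0, 0.0, 0.0])


def test_alignment_attraction_equal_attention(eq1_params):
    # one alignment neighbour heading +y plus one attraction neighbour
    # located toward +y: both unit responses point +y
    p = eq1_params.with_updates(z_r=1.0, z_l=2.0, z_a=10.0, alpha=360.0)
    pos = np.array([[0.0, 0.0, 0.0], [0.0, 2.0, 0.0], [0.0, 5.0, 0.0]])
    hdg = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [1.0, 0.0, 0.0]])
    st = SchoolState(0.0, pos, hdg)
    assert np.allclose(desired_heading(st, 0, p), [0.0, 1.0, 0.0], atol=1e-12)


def test_no_neighbours_keeps_heading():
    p = SimParams()  # default (count weighting) — contract holds in all modes
    st = SchoolState(
        0.0,
        np.array([[0.0, 0.0, 0.0], [500.0, 0.0, 0.0]]),
        np.array([[0.0, 0.0, 1.0], [1.0, 0.0, 0.0]]),
    )
    assert np.allclose(desired_heading(st, 0, p), [0.0, 0.0, 1.0])


def test_cancelling_alignment_keeps_heading(eq1_params):
    p = eq1_params.with_updates(z_r=1.0, z_l=2.0, z_a=0.0, alpha=360.0)
    pos = np.array([[0.0, 0.0, 0.0], [0.0, 2.0, 0.0], [0.0, -2.0, 0.0]])
    hdg = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, -1.0, 0.0]])
    st = SchoolState(0.0, pos, hdg)
    assert np.allclose(desired_heading(st, 0, p), [1.0, 0.0, 0.0])


def test_count_weighting_attraction_outvotes_alignment():
    # three attraction neighbours vs one alignment neighbour: under count
    # weighting the crowd wins; under equal attention the two balance
    p = SimParams(z_r=1.0, z_l=2.0, z_a=10.0, alpha=360.0, align_self=False)
    pos = np.array([
        [0.0, 0.0, 0.0],
        [0.0, 2.0, 0.0],           # alignment neighbour, heading +y
        [6.0, 0.0, 0.0], [6.0, 0.1, 0.0], [6.0, -0.1, 0.0],  # attraction crowd +x
    ])
    hdg = np.tile([0.0, 1.0, 0.0], (5, 1))
    hdg[0] = [1.0, 0.0, 0.0]
    st = SchoolState(0.0, pos, hdg)
    d_count = desired_heading(st, 0, p)
    d_norm = desired_heading(st, 0, p.with_updates(term_weighting="normalized"))
    assert d_count[0] > d_norm[0]  # crowd pulls harder under count weighting
    assert d_norm[0] == pytest.approx(d_norm[1], abs=1e-6)  # equal attention


# -------------------------------------------------------------------- noise


def test_zero_noise_identity(rng):
    h = np.array([0.0, 0.0, 1.0])
    assert np.array_equal(apply_rotational_noise(h, 0.0, rng), h)


def test_noise_preserves_norm(rng):
    h = rng.standard_normal((200, 3))
    h /= np.linalg.norm(h, axis=1)[:, None]
    out = apply_rotational_noise(h, 0.3, rng)
    assert np.allclose(np.linalg.norm(out, axis=1), 1.0, atol=1e-12)


def test_angular_deviation_scales_with_sigma(rng):
    # small-noise relation: the angular deviation is an isotropic 3D
    # quantity with mean square 2 sigma^2, so its per-component std
    # RMS(theta)/sqrt(3) ~= sigma * sqrt(2/3)
    h = np.tile([0.0, 0.0, 1.0], (200_000, 1))
    out = apply_rotational_noise(h, 0.01, rng)
    ang = np.arccos(np.clip(out[:, 2], -1, 1))
    per_component_std = np.sqrt(np.mean(ang**2) / 3.0)
    assert per_component_std == pytest.approx(0.01 * np.sqrt(2 / 3), rel=0.03)


# ------------------------------------------------------------ turn limiting


def test_small_turn_unconstrained():
    p = SimParams(theta_max=40.0, turn_limit_mode="per_step")
    cur = np.array([1.0, 0.0, 0.0])
    des = np.array([np.cos(np.radians(10)), np.sin(np.radians(10)), 0.0])
    assert np.allclose(constrain_turn(cur, des, p), des)


def test_turn_capped_in_plane():
    p = SimParams(theta_max=40.0, turn_limit_mode="per_step")
    out = constrain_turn(np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0]), p)
    assert out == pytest.approx([np.cos(np.radians(40)), np.sin(np.radians(40)), 0.0])


def test_antiparallel_turn_is_deterministic_and_capped():
    p = SimParams(theta_max=40.0, turn_limit_mode="per_step")
    cur = np.array([1.0, 0.0, 0.0])
    out1 = constrain_turn(cur, -cur, p)
    out2 = constrain_turn(cur, -cur, p)
    assert np.array_equal(out1, out2)
    assert np.linalg.norm(out1) == pytest.approx(1.0)
    assert angle_between(cur, out1) == pytest.approx(np.radians(40.0))


# ------------------------------------------------------------------ stepping


def test_single_fish_moves_straight():
    p = SimParams(n=1, sigma=0.0, total_time=5.0)
    st = SchoolState(0.0, np.zeros((1, 3)), np.array([[1.0, 0.0, 0.0]]))
    rng = np.random.default_rng(0)
    for _ in range(10):
        st = step_school(st, p, rng)
    assert np.allclose(st.headings, [[1.0, 0.0, 0.0]])
    assert st.positions[0, 0] == pytest.approx(10 * p.speed * p.dt)
    assert np.allclose(st.positions[0, 1:], 0.0)


def test_mutual_repulsion_separates():
    p = SimParams(n=2, sigma=0.0, theta_max=180.0, turn_limit_mode="per_step")
    st = SchoolState(
        0.0,
        np.array([[0.0, 0.0, 0.0], [0.5, 0.0, 0.0]]),
        np.array([[0.0, 1.0, 0.0], [0.0, 1.0, 0.0]]),
    )
    new = step_school(st, p, np.random.default_rng(0))
    assert np.linalg.norm(new.positions[1] - new.positions[0]) > 0.5


def test_aligned_school_stays_polarized():
    # all pairwise distances inside the alignment shell: identical
    # headings are a consensus fixed point (attraction pairs would bend
    # edge fish toward the group and break exact alignment)
    from schooldyn.fixtures import make_aligned_school
    from schooldyn import polarization

    p = SimParams(n=8, z_r=1.0, z_l=4.0, z_a=10.0, sigma=0.0)
    st = make_aligned_school(8, spacing=2.0)  # 2x2x2 cube, max distance 2*sqrt(3) < 5
    new = step_school(st, p, np.random.default_rng(0))
    assert polarization(new) == pytest.approx(1.0, abs=1e-12)


def test_step_invariants_along_run(small_params):
    p = small_params.with_updates(sigma=0.05)
    rng = np.random.default_rng(3)
    st = init_random_school(p, rng)
    for _ in range(200):
        new = step_school(st, p, rng)
        assert np.allclose(np.linalg.norm(new.headings, axis=1), 1.0, atol=1e-9)
        steps = np.linalg.norm(new.positions - st.positions, axis=1)
        assert np.allclose(steps, p.speed * p.dt, atol=1e-9)
        turns = np.arccos(np.clip(
            np.einsum("ij,ij->i", new.headings, st.headings), -1, 1))
        assert np.all(turns <= p.theta_cap + 1e-9)
        st = new


def test_rotation_equivariance():
    # with sigma=0, a global rotation of the configuration commutes with
    # one synchronous step
    p = SimParams(n=15, z_l=2.0, z_a=6.0, sigma=0.0)
    st = init_random_school(p, 5)
    R = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
    rot = SchoolState(0.0, st.positions @ R.T, st.headings @ R.T)
    stepped_then_rotated = step_school(st, p, np.random.default_rng(0))
    rotated_then_stepped = step_school(rot, p, np.random.default_rng(0))
    assert np.allclose(rotated_then_stepped.positions,
                       stepped_then_rotated.positions @ R.T, atol=1e-9)
    assert np.allclose(rotated_then_stepped.headings,
                       stepped_then_rotated.headings @ R.T, atol=1e-9)


def test_desired_headings_vectorized_matches_per_focal(rng):
    p = SimParams(n=25, z_l=1.5, z_a=4.0)
    st = init_random_school(p, rng)
    st.positions *= 5.0
    all_des = _desired_headings_all(st, p)
    for focal in range(25):
        assert np.allclose(all_des[focal], desired_heading(st, focal, p))


# ---------------------------------------------------------------- simulate


def test_simulate_step_count_and_determinism(small_params):
    p = small_params.with_updates(total_time=1.0, dt=0.1)
    a = simulate(p)
    assert len(a.series.t) == 11  # initial state + 10 steps
    b = simulate(p)
    assert np.array_equal(a.series.P, b.series.P)
    assert np.array_equal(a.final_state.positions, b.final_state.positions)


def test_simulate_from_given_state_records_states(small_params):
    from schooldyn.fixtures import make_aligned_school

    st = make_aligned_school(small_params.n, spacing=2.0)
    traj = simulate(small_params.with_updates(total_time=2.0, sigma=0.0),
                    initial_state=st, record_states_every=5)
    assert traj.states is not None and len(traj.states) >= 2
    assert traj.series.P[0] == pytest.approx(1.0)
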