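import dataclasses
import math

import numpy as np
import pytest

from hemoeit.forward import (
    ForwardModel,
    Scenario,
    scenario_field,
    simulate,
    solve_forward,
    volume_to_disc,
)
from hemoeit.mesh import build_circular_mesh


def homogeneous(mesh, value=0.3):
    return np.full(mesh.n_elements, value)


def test_homogeneous_voltages_antisymmetric_across_drive_axis(coarse_mesh, protocol):
    """Drive (0, 8) lies on the x axis; mirror symmetry of the homogeneous
    disc maps measurement pair j onto pair 15-j with reversed orientation."""
    fm = ForwardModel(coarse_mesh, protocol)
    v = fm.all_pair_voltages(homogeneous(coarse_mesh))[0]
    mirrored = v[[(15 - j) % 16 for j in range(16)]]
    assert np.abs(v + mirrored).max() < 1e-10 * np.abs(v).max()


def test_uniform_conductivity_scaling_is_exact(coarse_mesh, protocol):
    sigma = homogeneous(coarse_mesh)
    v1 = solve_forward(coarse_mesh, sigma, protocol)
    v2 = solve_forward(coarse_mesh, 2.0 * sigma, protocol)
    np.testing.assert_allclose(v2, v1 / 2.0, rtol=1e-12)


def test_reciprocity_on_inhomogeneous_field(coarse_mesh, protocol, rng):
    """Swapping drive and measurement roles leaves the transfer voltage
    unchanged (symmetric stiffness matrix)."""
    sigma = homogeneous(coarse_mesh) * rng.uniform(0.5, 2.0, coarse_mesh.n_elements)
    fm = ForwardModel(coarse_mesh, protocol)
    en = coarse_mesh.electrode_nodes
    for _ in range(10):
        a, b, c, d = rng.choice(16, size=4, replace=False)
        u = fm.solve_potentials(sigma, [(en[a], en[b])], current=1.0)[:, 0]
        w = fm.solve_potentials(sigma, [(en[c], en[d])], current=1.0)[:, 0]
        v_ab = u[en[c]] - u[en[d]]
        v_cd = w[en[a]] - w[en[b]]
        assert v_ab == pytest.approx(v_cd, rel=1e-10)


def test_refinement_convergence_of_homogeneous_voltages(protocol):
    m1 = build_circular_mesh(0.1, 400)
    m2 = build_circular_mesh(0.1, 1600)
    v1 = solve_forward(m1, homogeneous(m1), protocol)
    v2 = solve_forward(m2, homogeneous(m2), protocol)
    assert np.max(np.abs(v2 - v1) / np.abs(v2)) < 0.01


def test_nonpositive_conductivity_rejected(coarse_mesh, protocol):
    sigma = homogeneous(coarse_mesh)
    sigma[0] = 0.0
    with pytest.raises(ValueError):
        solve_forward(coarse_mesh, sigma, protocol)
    with pytest.raises(ValueError):
        solve_forward(coarse_mesh, homogeneous(coarse_mesh), protocol, current=0.0)


@pytest.mark.parametrize(
    "volume_ml,h,expected",
    [(0.0, 0.05, 0.0),
     (60.0, 0.05, math.sqrt(60e-6 / (math.pi * 0.05))),
     (10.0, 0.05, math.sqrt(10e-6 / (math.pi * 0.05)))],
)
def test_volume_to_disc_radius(volume_ml, h, expected):
    assert volume_to_disc(volume_ml, h) == pytest.approx(expected, rel=1e-12)


def test_volume_to_disc_rejects_negative_volume():
    with pytest.raises(ValueError):
        volume_to_disc(-1.0, 0.05)


def test_scenario_field_phases(forward_mesh):
    sc = Scenario()
    sigma0 = scenario_field(sc, 0.0, forward_mesh)
    # end-expiration at t = 0: lung elements at the deflated conductivity,
    # no blood anywhere
    assert np.any(np.isclose(sigma0, sc.lung_conductivity_deflated))
    assert not np.any(np.isclose(sigma0, sc.blood_conductivity))
    assert sc.blood_conductivity == pytest.approx(1 / 1.43, rel=1e-12)
    assert sc.blood_conductivity > sc.lung_conductivity_deflated

    # end of injection: blood disc equivalent to the full 60 ml
    t_end = sc.baseline_s + sc.injection_duration_s
    sigma1 = scenario_field(sc, t_end, forward_mesh)
    blood_area = forward_mesh.areas[np.isclose(sigma1, sc.blood_conductivity)].sum()
    r = volume_to_disc(sc.total_volume_ml, sc.slab_thickness)
    assert blood_area == pytest.approx(math.pi * r**2, rel=0.25)

    with pytest.raises(ValueError):
        scenario_field(sc, t_end + 1.0, forward_mesh)
    with pytest.raises(ValueError):
        scenario_field(sc, -1.0, forward_mesh)


def test_scenario_conductivity_ordering_enforced():
    with pytest.raises(ValueError):
        Scenario(lung_conductivity_inflated=0.5, lung_conductivity_deflated=0.4)
    with pytest.raises(ValueError):
        Scenario(frame_rate_hz=0.0)


def test_static_noiseless_simulation_yields_identical_frames(coarse_mesh, protocol):
    sc = Scenario(respiratory_rate_cpm=0.0, total_volume_ml=0.0,
                  baseline_s=2.0, frame_rate_hz=2.0, noise_level=0.0)
    frames = simulate(sc, coarse_mesh, protocol)
    assert np.all(frames.voltages == frames.voltages[0])


def test_simulation_reproducible_for_fixed_seed(coarse_mesh, protocol):
    sc = Scenario(baseline_s=3.0, total_volume_ml=0.0, frame_rate_hz=2.0, seed=42)
    a = simulate(sc, coarse_mesh, protocol)
    b = simulate(sc, coarse_mesh, protocol)
    assert np.array_equal(a.voltages, b.voltages)
    c = simulate(dataclasses.replace(sc, seed=43), coarse_mesh, protocol)
    assert not np.array_equal(a.voltages, c.voltages)


def test_default_noise_level_is_one_per_mille(coarse_mesh, protocol):
    sc = Scenario(respiratory_rate_cpm=0.0, total_volume_ml=0.0,
                  baseline_s=50.0, frame_rate_hz=2.0, seed=5)
    noisy = simulate(sc, coarse_mesh, protocol)
    clean = simulate(dataclasses.replace(sc, noise_level=0.0),
                     coarse_mesh, protocol)
    rel = (noisy.voltages - clean.voltages) / np.abs(clean.voltages)
    assert rel.std() == pytest.approx(1e-3, rel=0.05)
    assert abs(rel.mean()) < 1e-4


def test_growing_blood_disc_changes_nearest_channel_monotonically(
        forward_mesh, protocol):
    """At zero noise the channel most affected by the bleed responds
    monotonically as the conductive disc grows."""
    sc = Scenario()
    fm = ForwardModel(forward_mesh, protocol)
    bx, by = sc.blood_center_xy
    cent = forward_mesh.centroids()
    dist = np.hypot(cent[:, 0] - bx, cent[:, 1] - by)
    base = np.full(forward_mesh.n_elements, sc.background_conductivity)
    v0 = fm.boundary_voltages(base)
    deltas = []
    for vol in [10.0, 20.0, 30.0, 40.0, 50.0, 60.0]:
        sigma = base.copy()
        sigma[dist < volume_to_disc(vol, sc.slab_thickness)] = sc.blood_conductivity
        deltas.append(np.abs(fm.boundary_voltages(sigma) - v0))
    deltas = np.array(deltas)
    ch = int(np.argmax(deltas[-1]))
    assert np.all(np.diff(deltas[:, ch]) > 0)
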