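import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hemoeit.analysis import (
    NoAnomalyError,
    RivSeries,
    anova_oneway,
    compare_groups,
    compute_riv,
    derive_roi,
    regress_riv_volume,
    riv_trajectory,
)
from hemoeit.forward import Scenario, simulate
from hemoeit.pipeline import analyze_frames
from hemoeit.mesh import build_circular_mesh


def test_roi_threshold_selects_elements_above_ten_percent_of_peak():
    roi = derive_roi(np.array([-1.0, -0.05, -0.2, 0.3]))
    assert set(roi.elements) == {0, 2}


def test_roi_includes_all_tied_elements():
    roi = derive_roi(np.full(7, -0.4))
    assert len(roi.elements) == 7


def test_roi_undefined_without_impedance_reduction():
    with pytest.raises(NoAnomalyError):
        derive_roi(np.zeros(5))
    with pytest.raises(NoAnomalyError):
        derive_roi(np.array([0.1, 0.5]))
    with pytest.raises(ValueError):
        derive_roi(np.array([-1.0]), fraction=1.5)


@given(st.lists(st.floats(-10, 10), min_size=4, max_size=40),
       st.floats(0.05, 0.45))
def test_lowering_the_roi_threshold_never_shrinks_it(values, fraction):
    img = np.array(values)
    if not np.any(-img > 0):
        img[0] = -1.0
    tight = set(derive_roi(img, fraction + 0.5).elements)
    loose = set(derive_roi(img, fraction).elements)
    assert tight <= loose


def test_riv_weights_normalize(inverse_mesh):
    n = inverse_mesh.n_elements
    roi_all = derive_roi(np.full(n, -0.3))
    assert compute_riv(np.full(n, -0.3), roi_all, inverse_mesh) == pytest.approx(-0.3)
    # ROI covering a subset with value -1 integrates to -(ROI area fraction)
    img = np.zeros(n)
    img[: n // 2] = -1.0
    roi = derive_roi(img)
    frac = inverse_mesh.areas[roi.elements].sum() / inverse_mesh.areas.sum()
    assert compute_riv(img, roi, inverse_mesh) == pytest.approx(-frac)
    # linearity
    assert compute_riv(2 * img, roi, inverse_mesh) == pytest.approx(-2 * frac)


def test_riv_stable_under_mesh_refinement():
    """RIV of a smooth anomaly changes little when the element count
    doubles (piecewise-constant quadrature of the same integral)."""
    rivs = []
    for target in (400, 800):
        mesh = build_circular_mesh(0.1, target)
        cent = mesh.centroids()
        r2 = (cent[:, 0] + 0.015) ** 2 + (cent[:, 1] - 0.07) ** 2
        img = -np.exp(-r2 / 0.02**2)
        rivs.append(compute_riv(img, derive_roi(img), mesh))
    assert rivs[0] == pytest.approx(rivs[1], rel=0.02)


def test_riv_trajectory_tracks_noiseless_injection(forward_mesh, inverse_mesh,
                                                   protocol, recon):
    sc = Scenario(baseline_s=60.0, total_volume_ml=20.0, frame_rate_hz=2.0,
                  noise_level=0.0)
    frames = simulate(sc, forward_mesh, protocol)
    res = analyze_frames(frames, inverse_mesh, recon=recon)
    riv, vols = res.riv.riv, res.riv.volumes_ml
    inj = riv[vols > 0]
    # strictly decreasing at the smoothing scale (10 s block means;
    # per-frame values carry filter-transient ripple at injection onset)
    n_blocks = len(inj) // 20
    blocks = inj[: n_blocks * 20].reshape(n_blocks, 20).mean(axis=1)
    assert np.all(np.diff(blocks) < 0)
    assert inj[-1] < inj[0]
    assert np.polyfit(vols[vols > 0], inj, 1)[0] < 0


def test_baseline_riv_small_relative_to_final(full_analysis):
    riv = full_analysis.riv
    baseline = np.abs(riv.riv[riv.volumes_ml == 0])
    assert baseline.max() < 0.05 * abs(riv.riv[-1])


def test_roi_policies_agree_in_sign(forward_mesh, inverse_mesh, protocol, recon):
    sc = Scenario(baseline_s=60.0, total_volume_ml=20.0, frame_rate_hz=2.0,
                  seed=21)
    frames = simulate(sc, forward_mesh, protocol)
    res_final = analyze_frames(frames, inverse_mesh, recon=recon)
    res_frame = analyze_frames(frames, inverse_mesh, recon=recon,
                               roi_policy="per-frame")
    inj = res_final.riv.volumes_ml > 1.0
    assert np.all(np.sign(res_final.riv.riv[inj])
                  == np.sign(res_frame.riv.riv[inj]))


def test_anova_null_distribution_is_calibrated(rng):
    """Groups drawn from one distribution should rarely reject."""
    rejections = 0
    for _ in range(100):
        groups = [rng.standard_normal(20) for _ in range(4)]
        _, p = anova_oneway(groups)
        rejections += p < 0.05
    assert rejections <= 10


def test_anova_detects_strong_separation(rng):
    base = rng.standard_normal(30) - 10.0
    others = [rng.standard_normal(30) for _ in range(3)]
    f, p = anova_oneway([base, *others])
    assert p < 1e-6


def test_anova_identical_constant_groups_give_zero_f():
    f, p = anova_oneway([np.full(5, 2.0), np.full(5, 2.0)])
    assert f == 0.0 and p == 1.0
    with pytest.raises(ValueError):
        anova_oneway([np.ones(1), np.ones(5)])


def test_compare_groups_milestones_vs_baseline(rng):
    times = np.arange(0, 480.0, 0.5)
    volumes = np.clip((times - 60.0) / 6.0, 0, 60)
    riv = -0.01 * volumes + 1e-4 * rng.standard_normal(len(times))
    series = RivSeries(times=times, riv=riv, volumes_ml=volumes)
    cmp_res = compare_groups(series, milestones=(10.0, 30.0, 60.0))
    assert cmp_res.p_omnibus < 1e-10
    assert all(p < 1e-6 for p in cmp_res.posthoc_p.values())
    with pytest.raises(ValueError):
        compare_groups(series, milestones=(90.0,))


def test_regression_exact_line():
    vols = np.concatenate([np.zeros(5), np.linspace(1, 60, 30)])
    times = np.arange(len(vols), dtype=float)
    series = RivSeries(times=times, riv=-0.01 * vols, volumes_ml=vols)
    res = regress_riv_volume(series)
    assert res.slope == pytest.approx(-0.01, rel=1e-12)
    assert res.r_squared == pytest.approx(1.0)


def test_regression_null_noise_has_low_r_squared(rng):
    low = 0
    vols = np.concatenate([np.zeros(5), np.linspace(1, 60, 60)])
    times = np.arange(len(vols), dtype=float)
    for _ in range(100):
        series = RivSeries(times=times, riv=rng.standard_normal(len(vols)),
                           volumes_ml=vols)
        low += regress_riv_volume(series).r_squared < 0.2
    assert low >= 90


def test_regression_requires_varying_volume():
    series = RivSeries(times=np.arange(5.0), riv=np.ones(5),
                       volumes_ml=np.full(5, 10.0))
    with pytest.raises(ValueError):
        regress_riv_volume(series)
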