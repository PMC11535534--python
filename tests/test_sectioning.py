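"""Sampling design and sphere-section geometry."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ovastereo import (OvaryModel, SamplingPlan, SectionFrame, cut_slabs,
                       follicles_from_specs, FollicleSpec, observe_frames,
                       observe_section, section_ovary, select_serial_runs,
                       select_slabs)
from conftest import small_config, mixed_stages
from ovastereo import generate_ovary


def _point_model(follicles, axes=(2500, 3000, 5000)):
    return OvaryModel(axes, 800, follicles_from_specs(follicles))


def _follicle(fid=0, z=1000.0, d_oo=30.0, d_nu=18.0, d_no=3.0, off_z=0.0,
              stage="primordial"):
    return FollicleSpec(id=fid, stage=stage, center=(0.0, 0.0, z),
                        follicle_diameter=max(d_oo, 35.0), oocyte_diameter=d_oo,
                        nucleus_diameter=d_nu, nucleolus_diameter=d_no,
                        nucleolus_offset=(0.0, 0.0, off_z))


# ---------------------------------------------------------------------------
# slabs
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("extent,expected_n,last_width", [
    (10_000.0, 10, 1000.0),
    (10_500.0, 11, 500.0),
])
def test_cut_slabs_ceiling_rule(extent, expected_n, last_width):
    slabs = cut_slabs(extent, SamplingPlan())
    assert len(slabs) == expected_n
    assert slabs[-1][1] - slabs[-1][0] == pytest.approx(last_width)
    # contiguous half-open tiling of the extent
    assert slabs[0][0] == 0.0 and slabs[-1][1] == pytest.approx(extent)
    for a, b in zip(slabs[:-1], slabs[1:]):
        assert a[1] == b[0]


def test_cut_slabs_degenerate_extent_is_empty():
    assert cut_slabs(0.0, SamplingPlan()) == []


@pytest.mark.parametrize("n,interval,start,expect_idx,expect_f2", [
    (9, 3, 2, [1, 4, 7], 1 / 3),
    (10, 3, 1, [0, 3, 6, 9], 0.4),
    (5, 1, 1, [0, 1, 2, 3, 4], 1.0),
])
def test_select_slabs_systematic_enumeration(n, interval, start, expect_idx,
                                             expect_f2):
    slabs = cut_slabs(n * 1000.0, SamplingPlan())
    plan = SamplingPlan(slab_interval=interval, slab_start=start)
    idx, f2 = select_slabs(slabs, plan)
    assert idx == expect_idx
    assert f2 == pytest.approx(expect_f2)


def test_select_slabs_interval_beyond_count_warns():
    slabs = cut_slabs(2000.0, SamplingPlan())
    with pytest.warns(UserWarning, match="slab_interval"):
        idx, f2 = select_slabs(slabs, SamplingPlan(slab_interval=5, slab_start=1))
    assert idx == [0] and f2 == 0.5


def test_random_slab_start_stays_in_interval_and_is_seeded():
    slabs = cut_slabs(9000.0, SamplingPlan())
    plan = SamplingPlan(slab_interval=3, slab_start="random")
    starts = {select_slabs(slabs, plan, seed)[0][0] for seed in range(30)}
    assert starts <= {0, 1, 2} and len(starts) > 1
    assert select_slabs(slabs, plan, 7) == select_slabs(slabs, plan, 7)


# ---------------------------------------------------------------------------
# serial runs
# ---------------------------------------------------------------------------

def test_serial_runs_five_of_fifty_pattern():
    frames, f3 = select_serial_runs((0.0, 1000.0), SamplingPlan(run_start=1))
    assert len(frames) == 200
    sampled = frames.loc[frames["sampled"], "section_index"].to_numpy()
    expect = np.concatenate([np.arange(k, k + 5) for k in (0, 50, 100, 150)])
    assert (sampled == expect).all()
    assert f3 == pytest.approx(0.1)


def test_serial_runs_full_run_is_identity():
    plan = SamplingPlan(run_length=50, group_size=50, run_start=1)
    frames, f3 = select_serial_runs((0.0, 1000.0), plan)
    assert frames["sampled"].all() and f3 == 1.0


def test_partial_slab_truncates_group():
    """30-section slab, group 50, run 5 at start 1: only sections 0-4 sampled."""
    frames, f3 = select_serial_runs((0.0, 150.0), SamplingPlan(run_start=1))
    assert len(frames) == 30
    assert frames.loc[frames["sampled"], "section_index"].tolist() == [0, 1, 2, 3, 4]
    # enumeration oracle over the section list
    oracle = [s for s in range(30) if s % 50 < 5]
    assert frames.loc[frames["sampled"], "section_index"].tolist() == oracle
    assert f3 == pytest.approx(5 / 30)


def test_run_overhanging_partial_group_is_truncated():
    frames, f3 = select_serial_runs((0.0, 140.0), SamplingPlan(run_start=26))
    # 28 sections; run covers sections 25..29 but only 25,26,27 exist
    assert frames.loc[frames["sampled"], "section_index"].tolist() == [25, 26, 27]
    assert f3 == pytest.approx(3 / 28)


@given(st.integers(1, 50), st.integers(2, 8), st.integers(1, 46))
def test_frames_tile_slab_exactly(n_groups_scale, _interval, run_start):
    plan = SamplingPlan(run_start=min(run_start, 46))
    width = n_groups_scale * 35.0  # arbitrary widths incl. partial groups
    if width < plan.section_thickness:
        width = plan.section_thickness
    frames, _ = select_serial_runs((0.0, width), plan)
    z_lo = frames["z_lo"].to_numpy()
    z_hi = frames["z_hi"].to_numpy()
    assert np.allclose(z_hi - z_lo, plan.section_thickness)
    assert np.allclose(z_lo[1:], z_hi[:-1])  # contiguous, non-overlapping
    assert z_lo[0] == 0.0
    assert width - z_hi[-1] < plan.section_thickness  # only a sliver uncut


# ---------------------------------------------------------------------------
# observation geometry
# ---------------------------------------------------------------------------

def test_equatorial_cut_recovers_true_diameter():
    model = _point_model([_follicle(z=1002.5, d_oo=30)])
    so = observe_section(model, SectionFrame(0, 0, 1000.0, 1005.0))
    assert len(so.profiles) == 1
    assert so.profiles[0]["oocyte_profile_diameter"] == pytest.approx(30.0)
    assert so.profiles[0]["nucleolus_visible"]


def test_off_equator_chord_formula():
    # center 2.5 um above the mid-plane: 2*sqrt(15^2 - 2.5^2)
    model = _point_model([_follicle(z=1005.0, d_oo=30)])
    so = observe_section(model, SectionFrame(0, 0, 1000.0, 1005.0))
    assert so.profiles[0]["oocyte_profile_diameter"] == pytest.approx(
        2 * math.sqrt(15**2 - 2.5**2))


def test_profile_diameter_monotone_in_offset_and_bounded():
    ds = []
    for dz in (0.0, 3.0, 6.0, 9.0, 12.0):
        model = _point_model([_follicle(z=1002.5 + dz, d_oo=30)])
        so = observe_section(model, SectionFrame(0, 0, 1000.0, 1005.0))
        ds.append(so.profiles[0]["oocyte_profile_diameter"])
    assert all(a > b for a, b in zip(ds[:-1], ds[1:]))
    assert all(d <= 30.0 for d in ds)


def test_nucleolus_halfopen_boundary_single_frame():
    """A nucleolus spanning z in [97, 100) belongs to frame [95,100) only."""
    model = _point_model([_follicle(z=98.5, d_oo=30, d_no=3.0)])
    lo = observe_section(model, SectionFrame(0, 19, 95.0, 100.0))
    hi = observe_section(model, SectionFrame(0, 20, 100.0, 105.0))
    assert lo.profiles[0]["nucleolus_visible"]
    assert lo.profiles[0]["nucleolus_chord"] == pytest.approx(3.0)
    assert hi.profiles and not hi.profiles[0]["nucleolus_visible"]
    assert hi.profiles[0]["nucleolus_chord"] == 0.0


def test_visibility_zero_sees_any_intersection():
    # nucleolus z-extent [98, 101): crosses the boundary at 100
    model = _point_model([_follicle(z=99.5, d_oo=30, d_no=3.0)])
    lo = observe_section(model, SectionFrame(0, 19, 95.0, 100.0),
                         nucleolus_visibility=0.0)
    hi = observe_section(model, SectionFrame(0, 20, 100.0, 105.0),
                         nucleolus_visibility=0.0)
    assert lo.profiles[0]["nucleolus_visible"] and hi.profiles[0]["nucleolus_visible"]
    # under the default in-focus rule only the center section sees it
    lo1 = observe_section(model, SectionFrame(0, 19, 95.0, 100.0))
    hi1 = observe_section(model, SectionFrame(0, 20, 100.0, 105.0))
    assert lo1.profiles[0]["nucleolus_visible"]
    assert not hi1.profiles[0]["nucleolus_visible"]


def test_every_nucleolus_lands_in_exactly_one_center_section():
    """Under the in-focus rule, frames tiling a slab see each nucleolus once."""
    model = generate_ovary(small_config(stages=mixed_stages(200, 0, 0, 0)), seed=2)
    plan = SamplingPlan.exhaustive()
    res = section_ovary(model, plan, seed=0)
    vis = res.observations[res.observations["nucleolus_visible"]]
    counts = vis.groupby("follicle_id").size()
    assert (counts == 1).all()
    assert len(counts) == 200


def test_expected_sections_hit_matches_d_plus_t_over_t():
    """E[#frames intersected by a sphere of diameter d] = (d + t)/t."""
    rng = np.random.default_rng(99)
    d, t = 32.0, 5.0  # not a multiple of t, so the hit count is random (7 or 8)
    n = 4000
    specs = [_follicle(fid=i, z=z, d_oo=d)
             for i, z in enumerate(rng.uniform(500, 9500, n))]
    model = _point_model(specs)
    frames, _ = select_serial_runs((0.0, 10_000.0), SamplingPlan(
        slab_thickness=10_000.0, run_length=50, run_start=1))
    obs = observe_frames(model, frames)
    hits = obs.groupby("follicle_id").size()
    expect = (d + t) / t
    se = hits.std(ddof=1) / math.sqrt(n)
    assert abs(hits.mean() - expect) < 3 * se


def test_section_ovary_realized_fractions_default_design(small_mixed_model):
    res = section_ovary(small_mixed_model, SamplingPlan(slab_start=1, run_start=1),
                        seed=0)
    assert res.n_slabs_total == 10
    assert res.selected_slabs == [0, 3, 6, 9]
    assert res.realized_f2 == pytest.approx(0.4)
    assert res.realized_f3 == pytest.approx(0.1)
    assert res.realized_f1 == 1.0


def test_f1_thinning_reduces_follicles_and_records_realized_fraction():
    cfg = small_config(stages=mixed_stages(400, 0, 0, 0), f1=0.7)
    model = generate_ovary(cfg, seed=8)
    res = section_ovary(model, SamplingPlan.exhaustive(), seed=5)
    seen = res.observations["follicle_id"].nunique()
    assert seen < 400
    assert res.realized_f1 == pytest.approx(seen / 400)


def test_invalid_plans_rejected():
    with pytest.raises(ValueError):
        SamplingPlan(run_length=60, group_size=50)
    with pytest.raises(ValueError):
        SamplingPlan(slab_start=4, slab_interval=3)
    with pytest.raises(ValueError):
        SamplingPlan(section_thickness=0)
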