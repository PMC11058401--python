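"""Quotient-scoring tests: smoothing, ICV normalization, reference fields,
voxelwise quotients and atlas aggregation, checked against brute-force
loops and closed-form kernel values on small grids."""

import math

import numpy as np
import pytest

from bhq.grids import AtlasVolume, VolumeGrid
from bhq.quotient import (
    compute_icv,
    fwhm_to_sigma,
    gaussian_smooth,
    proportional_map,
    quotient_map,
    reference_field,
    regional_quotients,
    score_cohort,
    scores_to_frame,
    whole_brain_bhq,
)
from bhq.simulate import generate_atlas


def vol(values, vox=2.0, modality="fa"):
    return VolumeGrid(np.asarray(values, dtype=float), (vox,) * 3, modality)


# ---------------------------------------------------------------------------
# smoothing


def test_smoothing_preserves_constants_and_identity_at_zero():
    c = vol(np.full((8, 8, 8), 0.4))
    assert np.allclose(gaussian_smooth(c, 8.0).values, 0.4)
    x = vol(np.random.default_rng(0).uniform(0, 1, (8, 8, 8)))
    assert np.array_equal(gaussian_smooth(x, 0.0).values, x.values)
    with pytest.raises(ValueError):
        gaussian_smooth(x, -1.0)


def test_smoothing_impulse_matches_discrete_gaussian_kernel():
    """Center-to-neighbor ratio of the impulse response equals exp(1/(2 sigma^2))."""
    shape = (17, 17, 17)
    impulse = np.zeros(shape)
    impulse[8, 8, 8] = 1.0
    out = gaussian_smooth(vol(impulse, vox=2.0), 8.0).values
    sigma_vox = fwhm_to_sigma(8.0) / 2.0
    assert out[8, 8, 8] / out[9, 8, 8] == pytest.approx(math.exp(1 / (2 * sigma_vox**2)), rel=1e-6)
    # reflect boundary conserves total intensity
    assert out.sum() == pytest.approx(1.0, rel=1e-12)


def test_smoothing_sigma_conversion():
    assert fwhm_to_sigma(8.0) == pytest.approx(8.0 / math.sqrt(8 * math.log(2)))


# ---------------------------------------------------------------------------
# ICV and proportional GM


def test_icv_trivials_and_bruteforce(rng):
    zero = vol(np.zeros((4, 4, 4)), modality="gm")
    assert compute_icv(zero, zero.with_values(zero.values, "wm"), zero.with_values(zero.values, "csf")) == 0.0
    gm = vol(rng.uniform(0, 1, (5, 5, 5)), modality="gm")
    wm = vol(rng.uniform(0, 1, (5, 5, 5)), modality="wm")
    csf = vol(rng.uniform(0, 1, (5, 5, 5)), modality="csf")
    expected = sum(
        gm.values[i, j, k] + wm.values[i, j, k] + csf.values[i, j, k]
        for i in range(5)
        for j in range(5)
        for k in range(5)
    )
    assert compute_icv(gm, wm, csf) == pytest.approx(expected, rel=1e-12)
    with pytest.raises(ValueError):
        compute_icv(gm, vol(np.zeros((4, 4, 4)), modality="wm"), csf)


def test_proportional_map_scale_invariance(rng):
    gm = vol(rng.uniform(0, 1, (6, 6, 6)), modality="gm")
    assert np.array_equal(proportional_map(gm, 1.0).values, gm.values)
    p1 = proportional_map(gm, 37.0)
    p2 = proportional_map(gm.with_values(2 * gm.values), 74.0)
    assert np.allclose(p1.values, p2.values)
    icv = float(gm.values.sum())
    assert proportional_map(gm, icv).values.sum() == pytest.approx(1.0, rel=1e-12)
    with pytest.raises(ValueError):
        proportional_map(gm, 0.0)


# ---------------------------------------------------------------------------
# reference field and quotient


def test_reference_field_two_map_example():
    a = vol(np.zeros((4, 4, 4)))
    b = vol(np.full((4, 4, 4), 2.0))
    ref_sample = reference_field([a, b], ddof=1)
    assert np.allclose(ref_sample.mean.values, 1.0)
    assert np.allclose(ref_sample.sd.values, math.sqrt(2.0))
    ref_pop = reference_field([a, b], ddof=0)
    assert np.allclose(ref_pop.sd.values, 1.0)
    assert ref_pop.mask.all()


def test_reference_field_identical_maps_all_masked_out():
    a = vol(np.full((4, 4, 4), 0.3))
    ref = reference_field([a, a, a])
    assert ref.n_masked == 0
    with pytest.raises(ValueError):
        reference_field([a])


def test_reference_field_matches_two_pass_oracle(rng):
    maps = [vol(rng.uniform(0, 1, (5, 5, 5))) for _ in range(7)]
    ref = reference_field(maps, ddof=0)
    stack = np.stack([m.values for m in maps])
    mean = np.zeros((5, 5, 5))
    for m in maps:
        mean += m.values / len(maps)
    var = np.zeros((5, 5, 5))
    for m in maps:
        var += (m.values - mean) ** 2 / len(maps)
    assert np.allclose(ref.mean.values, mean)
    assert np.allclose(ref.sd.values, np.sqrt(var))
    assert np.allclose(ref.mean.values, stack.mean(axis=0))


def test_quotient_map_anchor_points(rng):
    maps = [vol(rng.uniform(0.2, 0.8, (6, 6, 6))) for _ in range(5)]
    ref = reference_field(maps)
    at_mean = quotient_map(ref.mean.with_values(ref.mean.values, "fa"), ref)
    assert np.allclose(at_mean.values[ref.mask], 100.0)
    plus_one_sd = ref.mean.values + ref.sd.values
    q = quotient_map(vol(plus_one_sd), ref)
    assert np.allclose(q.values[ref.mask], 115.0)
    assert np.isnan(q.values[~ref.mask]).all() or ref.mask.all()


def test_cohort_self_scoring_mean_100_sd_15(small_cohort):
    """Population-SD convention: the defining cohort scores exactly 100/15."""
    maps = list(small_cohort.fa_maps.values())
    ref = reference_field(maps, ddof=0)
    qs = np.stack([quotient_map(m, ref).values[ref.mask] for m in maps])
    assert np.allclose(qs.mean(axis=0), 100.0, atol=1e-8)
    assert np.allclose(qs.std(axis=0, ddof=0), 15.0, atol=1e-8)


# ---------------------------------------------------------------------------
# regional aggregation


def test_regional_quotients_constant_and_single_region():
    atlas = generate_atlas((12, 12, 12), 1, seed=2)
    const = np.where(atlas.labels > 0, 100.0, np.nan)
    q = VolumeGrid(const, (2.0,) * 3, "quotient")
    regions = regional_quotients(q, atlas)
    assert regions == {1: pytest.approx(100.0)}
    assert whole_brain_bhq(regions) == pytest.approx(100.0)


def test_regional_quotients_match_bruteforce(rng):
    atlas = generate_atlas((12, 12, 12), 8, seed=3)
    vals = np.where(atlas.labels > 0, rng.normal(100, 15, (12, 12, 12)), np.nan)
    q = VolumeGrid(vals, (2.0,) * 3, "quotient")
    regions = regional_quotients(q, atlas)
    for lab in atlas.region_labels:
        acc, count = 0.0, 0
        for i in range(12):
            for j in range(12):
                for k in range(12):
                    if atlas.labels[i, j, k] == lab and np.isfinite(vals[i, j, k]):
                        acc += vals[i, j, k]
                        count += 1
        assert regions[lab] == pytest.approx(acc / count, rel=1e-12)


def test_whole_brain_mean_and_missing_handling():
    assert whole_brain_bhq({1: 100.0, 2: 100.0}) == 100.0
    assert whole_brain_bhq({1: 85.0, 2: 115.0}) == 100.0
    vals = {i: v for i, v in enumerate([97.0, 103.0, float("nan"), 110.0])}
    assert whole_brain_bhq(vals) == pytest.approx((97 + 103 + 110) / 3)
    with pytest.raises(ValueError):
        whole_brain_bhq({1: float("nan")})


# ---------------------------------------------------------------------------
# cohort scoring composition


def test_score_cohort_identical_maps_fails_informatively(small_cohort):
    one = next(iter(small_cohort.fa_maps.values()))
    maps = {("a", "pre"): one, ("b", "pre"): one, ("c", "pre"): one}
    with pytest.raises(ValueError, match="identical|empty"):
        score_cohort(maps, small_cohort.atlas, "fa")


def test_score_cohort_affine_invariance(small_cohort):
    """Quotients are invariant to a common affine rescaling of all raw maps."""
    base = score_cohort(small_cohort.fa_maps, small_cohort.atlas, "fa")
    rescaled = {
        k: VolumeGrid(0.5 * v.values + 0.2, v.voxel_size_mm, "fa")
        for k, v in small_cohort.fa_maps.items()
    }
    moved = score_cohort(rescaled, small_cohort.atlas, "fa")
    for a, b in zip(base, moved):
        assert b.whole_brain == pytest.approx(a.whole_brain, abs=1e-9)
        for lab in a.per_region:
            assert b.per_region[lab] == pytest.approx(a.per_region[lab], abs=1e-9)


def test_score_cohort_whole_brain_is_region_mean(small_cohort):
    for s in score_cohort(small_cohort.fa_maps, small_cohort.atlas, "fa"):
        finite = [v for v in s.per_region.values() if np.isfinite(v)]
        assert s.whole_brain == pytest.approx(np.mean(finite), rel=1e-12)


def test_score_cohort_gm_path_icv_invariance(small_cohort):
    """Scaling all three tissue maps of everyone equally leaves GM quotients fixed."""
    base = score_cohort(small_cohort.tissue_maps, small_cohort.atlas, "gm")
    scaled = {
        k: {m: VolumeGrid(3.0 * v.values, v.voxel_size_mm, m) for m, v in t.items()}
        for k, t in small_cohort.tissue_maps.items()
    }
    moved = score_cohort(scaled, small_cohort.atlas, "gm")
    for a, b in zip(base, moved):
        assert b.whole_brain == pytest.approx(a.whole_brain, abs=1e-8)


def test_cohort_bhq_spread_covers_95_percent_band():
    """~95% of a large Gaussian cohort lands between quotient 70 and 130."""
    rng = np.random.default_rng(42)
    shape = (8, 8, 8)
    atlas = generate_atlas(shape, 1, seed=1)
    mask = atlas.labels > 0
    n = 10_000
    traits = rng.normal(0, 1, n)
    maps = [
        VolumeGrid(
            np.clip(np.where(mask, 0.45 + 0.02 * traits[i] + rng.normal(0, 0.002, shape), 0.0), 0, 1),
            (2.0,) * 3,
            "fa",
        )
        for i in range(n)
    ]
    ref = reference_field(maps)
    vals = np.array(
        [whole_brain_bhq(regional_quotients(quotient_map(m, ref), atlas)) for m in maps]
    )
    frac = ((vals >= 70) & (vals <= 130)).mean()
    assert frac == pytest.approx(0.95, abs=0.02)


def test_scores_to_frame_layout(small_cohort):
    scores = score_cohort(small_cohort.fa_maps, small_cohort.atlas, "fa")
    frame = scores_to_frame(scores)
    assert set(frame.columns) == {"participant", "time", "measure", "value"}
    measures = set(frame["measure"])
    assert "fa_bhq" in measures
    assert sum(m.startswith("fa_bhq:") for m in measures) == small_cohort.config.n_regions
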