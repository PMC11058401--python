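"""Brain Healthcare Quotient (BHQ) scoring.

The quotient is an IQ-style standardization of a scalar brain map against a
reference population: every in-mask voxel gets ``100 + 15 * (x - mean) / sd``
where mean and SD are voxelwise images computed over the reference scan pool.
Regional quotients are unweighted voxel means within atlas labels, and the
whole-brain score is the unweighted mean across regions.

Two scoring paths are provided:

* FA: (optional Gaussian smoothing) -> reference -> quotient -> regions.
* GM: smoothing -> intracranial-volume (ICV) normalization into proportional
  gray matter -> reference -> quotient -> regions.  ICV is the total of the
  GM + WM + CSF maps, so dividing by it removes head-size differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import AtlasVolume, ReferenceField, VolumeGrid

__all__ = [
    "QuotientScores",
    "fwhm_to_sigma",
    "gaussian_smooth",
    "compute_icv",
    "proportional_map",
    "reference_field",
    "quotient_map",
    "regional_quotients",
    "whole_brain_bhq",
    "score_cohort",
    "scores_to_frame",
]

#: BHQ centering and scale: population mean maps to 100, one SD to 15 points.
BHQ_CENTER = 100.0
BHQ_SCALE = 15.0

FWHM_PER_SIGMA = math.sqrt(8.0 * math.log(2.0))


@dataclass
class QuotientScores:
    """Per participant/timepoint BHQ: whole-brain value plus per-region values.

    ``per_region`` maps atlas label -> mean quotient (NaN when a region had no
    in-mask voxels); ``whole_brain`` is the unweighted mean over non-missing
    regions.
    """

    participant: str
    time: str
    modality: str  # "fa_bhq" | "gm_bhq"
    whole_brain: float
    per_region: dict[int, float] = field(default_factory=dict)
    region_names: dict[int, str] = field(default_factory=dict)


def fwhm_to_sigma(fwhm: float) -> float:
    """Gaussian sigma for a given full width at half maximum."""
    return fwhm / FWHM_PER_SIGMA


def gaussian_smooth(volume: VolumeGrid, fwhm_mm: float, mode: str = "reflect") -> VolumeGrid:
    """Separable Gaussian smoothing with FWHM given in millimetres.

    Sigma per axis is ``fwhm / sqrt(8 ln 2)`` converted from mm to voxels.
    The reflect boundary rule conserves total intensity, which matters on the
    small grids used for synthetic cohorts.
    """
    if fwhm_mm < 0:
        raise ValueError(f"fwhm must be nonnegative, got {fwhm_mm}")
    if fwhm_mm == 0:
        return volume.with_values(volume.values.copy())
    sigma_vox = [fwhm_to_sigma(fwhm_mm) / s for s in volume.voxel_size_mm]
    smoothed = ndimage.gaussian_filter(volume.values, sigma=sigma_vox, mode=mode)
    return volume.with_values(smoothed)


def compute_icv(gm: VolumeGrid, wm: VolumeGrid, csf: VolumeGrid) -> float:
    """Intracranial volume proxy: total sum of the GM + WM + CSF maps."""
    for name, v in (("wm", wm), ("csf", csf)):
        if not gm.same_grid(v):
            raise ValueError(f"{name} map is not on the GM grid")
    for name, v in (("gm", gm), ("wm", wm), ("csf", csf)):
        if np.any(v.values < 0):
            raise ValueError(f"{name} map has negative values")
    return float(gm.values.sum() + wm.values.sum() + csf.values.sum())


def proportional_map(gm_smoothed: VolumeGrid, icv: float) -> VolumeGrid:
    """Head-size-normalized gray matter: the smoothed GM map divided by ICV."""
    if icv <= 0:
        raise ValueError(f"ICV must be positive, got {icv}")
    return gm_smoothed.with_values(gm_smoothed.values / icv)


def reference_field(
    maps: Sequence[VolumeGrid],
    *,
    sd_floor: float = 1e-6,
    mean_min: float = 0.0,
    ddof: int = 0,
) -> ReferenceField:
    """Voxelwise mean/SD images over a reference scan pool, with a validity mask.

    ``ddof=0`` (population SD) makes the defining cohort score exactly
    mean 100 / SD 15 at every masked voxel; ``ddof=1`` gives the sample-SD
    convention.  Voxels with SD <= ``sd_floor`` or mean <= ``mean_min`` are
    excluded from the mask instead of producing unbounded quotients.
    """
    if len(maps) < 2:
        raise ValueError(f"need at least 2 maps to build a reference, got {len(maps)}")
    first = maps[0]
    for m in maps[1:]:
        if not first.same_grid(m):
            raise ValueError("reference maps are not on a common grid")
    stack = np.stack([m.values for m in maps])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=ddof)
    mask = (sd > sd_floor) & (mean > mean_min)
    return ReferenceField(
        mean=first.with_values(mean, "mean"),
        sd=first.with_values(sd, "sd"),
        mask=mask,
        n_source_maps=len(maps),
    )


def quotient_map(volume: VolumeGrid, ref: ReferenceField) -> VolumeGrid:
    """Voxelwise quotient image: 100 + 15 * (x - mean) / sd inside the mask.

    Out-of-mask voxels are NaN (missing) rather than clamped or extrapolated.
    """
    if not volume.same_grid(ref.mean):
        raise ValueError("volume is not on the reference grid")
    q = np.full(volume.shape, np.nan)
    m = ref.mask
    q[m] = BHQ_CENTER + BHQ_SCALE * (volume.values[m] - ref.mean.values[m]) / ref.sd.values[m]
    return volume.with_values(q, "quotient")


def regional_quotients(
    q: VolumeGrid, atlas: AtlasVolume, *, volume_weighted: bool = False
) -> dict[int, float]:
    """Mean quotient per atlas label over non-missing voxels.

    Labels whose voxels are all out of the reference mask come back as NaN.
    ``volume_weighted`` is accepted for symmetry with :func:`whole_brain_bhq`
    but within a single label every voxel has the same volume, so it is a
    no-op here.
    """
    del volume_weighted
    if not q.same_grid(atlas):
        raise ValueError("atlas is not on the quotient grid")
    labels = atlas.region_labels
    if not labels:
        raise ValueError("atlas has no labeled voxels")
    out: dict[int, float] = {}
    for lab in labels:
        vals = q.values[atlas.labels == lab]
        vals = vals[np.isfinite(vals)]
        out[lab] = float(vals.mean()) if vals.size else float("nan")
    return out


def whole_brain_bhq(
    per_region: Mapping[int, float], weights: Mapping[int, float] | None = None
) -> float:
    """Unweighted (default) mean of non-missing regional quotients."""
    items = [(k, v) for k, v in per_region.items() if np.isfinite(v)]
    if not items:
        raise ValueError("all regions are missing; cannot form a whole-brain score")
    if weights is None:
        return float(np.mean([v for _, v in items]))
    w = np.array([weights[k] for k, _ in items], dtype=float)
    v = np.array([v for _, v in items], dtype=float)
    return float((w * v).sum() / w.sum())


# ---------------------------------------------------------------------------
# cohort-level composition


def _region_voxel_counts(atlas: AtlasVolume) -> dict[int, float]:
    return {lab: float((atlas.labels == lab).sum()) for lab in atlas.region_labels}


def score_cohort(
    maps: Mapping[tuple[str, str], VolumeGrid | Mapping[str, VolumeGrid]],
    atlas: AtlasVolume,
    modality: str,
    *,
    fwhm_mm: float = 8.0,
    smooth_fa: bool = True,
    ddof: int = 0,
    sd_floor: float = 1e-6,
    mean_min: float = 0.0,
    reference_keys: Iterable[tuple[str, str]] | None = None,
    volume_weighted: bool = False,
) -> list[QuotientScores]:
    """Score a cohort of maps into per-participant BHQ values.

    Parameters
    ----------
    maps
        ``{(participant, time): VolumeGrid}`` of FA maps when ``modality="fa"``;
        ``{(participant, time): {"gm": ..., "wm": ..., "csf": ...}}`` of tissue
        maps when ``modality="gm"``.
    modality
        ``"fa"`` or ``"gm"``.
    reference_keys
        Which scans define the population mean/SD images. Default: every scan
        in ``maps`` (all participants, both timepoints).
    volume_weighted
        Weight the across-region mean by region voxel volume instead of the
        default unweighted region mean.
    """
    if modality not in ("fa", "gm"):
        raise ValueError(f"modality must be 'fa' or 'gm', got {modality!r}")
    if not maps:
        raise ValueError("empty cohort")

    keys = list(maps.keys())
    if modality == "fa":
        prepared: dict[tuple[str, str], VolumeGrid] = {}
        for k, v in maps.items():
            if not isinstance(v, VolumeGrid):
                raise TypeError("FA scoring expects VolumeGrid values")
            if np.nanmin(v.values) < 0 or np.nanmax(v.values) > 1:
                raise ValueError(f"FA map {k} outside [0, 1]")
            prepared[k] = gaussian_smooth(v, fwhm_mm) if (smooth_fa and fwhm_mm > 0) else v
        out_modality = "fa_bhq"
    else:
        prepared = {}
        for k, tissues in maps.items():
            gm, wm, csf = tissues["gm"], tissues["wm"], tissues["csf"]  # type: ignore[index]
            icv = compute_icv(gm, wm, csf)
            if icv <= 0:
                raise ValueError(f"scan {k} has zero ICV")
            gm_s = gaussian_smooth(gm, fwhm_mm) if fwhm_mm > 0 else gm
            prepared[k] = proportional_map(gm_s, icv)
        out_modality = "gm_bhq"

    ref_keys = list(reference_keys) if reference_keys is not None else keys
    ref = reference_field(
        [prepared[k] for k in ref_keys], sd_floor=sd_floor, mean_min=mean_min, ddof=ddof
    )
    if ref.n_masked == 0:
        raise ValueError(
            "reference mask is empty (all voxels have zero SD or sub-threshold "
            "mean); a cohort of identical maps cannot be quotient-scored"
        )

    weights = _region_voxel_counts(atlas) if volume_weighted else None
    scores: list[QuotientScores] = []
    for (pid, time) in keys:
        q = quotient_map(prepared[(pid, time)], ref)
        regions = regional_quotients(q, atlas)
        scores.append(
            QuotientScores(
                participant=pid,
                time=time,
                modality=out_modality,
                whole_brain=whole_brain_bhq(regions, weights),
                per_region=regions,
                region_names=dict(atlas.names),
            )
        )
    return scores


def scores_to_frame(scores: Iterable[QuotientScores]) -> pd.DataFrame:
    """Tidy long table: participant, time, measure, value.

    The whole-brain score is the bare modality name ("fa_bhq"); regional
    values are "<modality>:<region name>".
    """
    rows = []
    for s in scores:
        rows.append((s.participant, s.time, s.modality, s.whole_brain))
        for lab, val in s.per_region.items():
            name = s.region_names.get(lab, f"region_{lab:02d}")
            rows.append((s.participant, s.time, f"{s.modality}:{name}", val))
    return pd.DataFrame(rows, columns=["participant", "time", "measure", "value"])
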