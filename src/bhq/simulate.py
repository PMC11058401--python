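"""Synthetic longitudinal neuroimaging cohorts.

Generates everything the scoring and analysis stages consume: spatially
normalized FA and tissue maps on a common grid, a labeled atlas of connected
regions, and a behavioral table (POMS mood subscales, trail-making times,
CES-D screening), for a two-group pre/post intervention design.

Generative model
----------------
All brain quantities are first drawn on a "BHQ-like points" scale and then
painted into raw FA units, so that the quotient scoring recovers the intended
statistical structure:

* participant baseline (FA, region r):
  ``off_g + shared_i + eta_ir`` with a group offset (control minus
  intervention = ``baseline_group_offset``), a shared between-subject
  component and an independent per-region component;
* pre-to-post change: ``delta_g + a * u_i + e_i`` where ``u_i ~ N(0,1)`` is a
  single latent responsiveness factor per participant and ``delta_g`` is
  ``intervention_effect`` or ``control_drift``;
* behavioral change of measure m (intervention group):
  ``mu_m + b_m * u_i + f_im``, with loadings chosen so that the population
  change-score correlation equals the configured ``latent_coupling_r[m]`` via
  ``r = a b / sqrt((a^2 + sigma_e^2)(b^2 + sigma_f^2))``; control-group
  behavioral change has the same marginal SD but no coupling.

The derived loadings (a, b_m, sigma_e, sigma_f) are recorded in the manifest.

Two output granularities share these latent draws: :func:`generate_cohort`
renders full voxel volumes, while :func:`generate_cohort_frame` emits only
the score-level long table (identical latent model, no voxel noise) for
cheap Monte-Carlo work.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .grids import AtlasVolume, VolumeGrid

__all__ = [
    "ConfigurationError",
    "SimConfig",
    "Participant",
    "BehavioralScores",
    "Cohort",
    "generate_atlas",
    "generate_cohort",
    "generate_cohort_frame",
    "apply_exclusions",
    "behavior_to_frame",
]


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


POMS_SUBSCALES = ("poms_ah", "poms_cb", "poms_dd", "poms_fi", "poms_ta", "poms_va", "poms_f")
POMS_MAX = 20  # 5 items per subscale, 0-4 each
BEHAVIORAL_MEASURES = POMS_SUBSCALES + ("tmt_a", "tmt_b")

#: default names for an 8-region white-matter atlas, mirroring the tracts a
#: JHU-style parcellation would provide
TRACT_NAMES_8 = (
    "corpus_callosum",
    "internal_capsule",
    "corona_radiata",
    "posterior_thalamic_radiation",
    "external_capsule",
    "cingulum",
    "superior_longitudinal_fasciculus",
    "uncinate_fasciculus",
)

# baseline (mean, sd) of the behavioral instruments, pooled across groups
BEHAVIOR_BASELINES: dict[str, tuple[float, float]] = {
    "poms_ah": (2.8, 2.4),
    "poms_cb": (2.0, 2.0),
    "poms_dd": (1.5, 2.1),
    "poms_fi": (3.0, 2.7),
    "poms_ta": (3.3, 2.7),
    "poms_va": (11.6, 4.4),
    "poms_f": (12.2, 3.6),
    "tmt_a": (22.4, 5.4),
    "tmt_b_minus_a": (27.8, 14.0),
}

DEFAULT_CHANGE_SD: dict[str, float] = {
    "poms_ah": 2.4,
    "poms_cb": 2.0,
    "poms_dd": 2.0,
    "poms_fi": 2.6,
    "poms_ta": 2.5,
    "poms_va": 3.3,
    "poms_f": 2.8,
    "tmt_a": 4.7,
    "tmt_b": 10.0,
}

# practice effects on the timed test, identical in both groups
DEFAULT_CHANGE_MEAN: dict[str, float] = {"tmt_a": -2.6, "tmt_b": -1.1}

DEFAULT_COUPLING: dict[str, float] = {"poms_va": 0.35, "tmt_b": -0.35}


@dataclass
class SimConfig:
    """Study-design parameters of the simulated trial.

    BHQ-scale quantities (offsets, effects, change SDs) are in quotient
    points; voxel-level quantities are in raw FA units.
    """

    n_per_group: int = 35
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: float = 2.0
    n_regions: int = 8
    #: baseline whole-brain FA-BHQ offset, control minus intervention (points)
    baseline_group_offset: float = 2.0
    #: mean pre-to-post change of the intervention group (points)
    intervention_effect: float = 0.525
    #: mean pre-to-post change of the control group (points)
    control_drift: float = -0.402
    #: SD of individual whole-brain change within a group (points)
    brain_change_sd: float = 1.7
    #: between-subject baseline SD shared across regions (points)
    baseline_shared_sd: float = 3.5
    #: between-subject baseline SD independent per region (points)
    baseline_region_sd: float = 6.0
    gm_baseline_sd: float = 7.4
    gm_change_sd: float = 1.6
    #: additive voxel noise on rendered maps, raw FA units
    voxel_noise_sd: float = 0.01
    #: raw FA units spanned by one between-subject SD of baseline points
    fa_subject_sd: float = 0.03
    #: target change-score correlation with the brain change, per measure
    latent_coupling_r: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COUPLING)
    )
    #: marginal SD of the behavioral change score, per measure
    behavioral_noise_sd: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CHANGE_SD)
    )
    cesd_exclusion_rate: float = 0.2
    imaging_failure_rate: float = 1.0 / 70.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ConfigurationError("n_per_group must be >= 2")
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        if len(self.grid_shape) != 3 or any(s < 4 for s in self.grid_shape):
            raise ConfigurationError(f"degenerate grid {self.grid_shape}")
        if self.voxel_size_mm <= 0:
            raise ConfigurationError("voxel_size_mm must be positive")
        if self.n_regions < 1:
            raise ConfigurationError("n_regions must be >= 1")
        if self.voxel_noise_sd < 0 or self.fa_subject_sd <= 0:
            raise ConfigurationError("noise/scale SDs must be positive")
        if not 0 <= self.cesd_exclusion_rate < 1:
            raise ConfigurationError("cesd_exclusion_rate must be in [0, 1)")
        self.latent_coupling_r = dict(self.latent_coupling_r)
        self.behavioral_noise_sd = dict(self.behavioral_noise_sd)
        for m, r in self.latent_coupling_r.items():
            if m not in BEHAVIORAL_MEASURES:
                raise ConfigurationError(f"unknown coupled measure {m!r}")
            if not abs(r) < 1:
                raise ConfigurationError(f"|latent_coupling_r| must be < 1, got {r} for {m}")
        for m in BEHAVIORAL_MEASURES:
            self.behavioral_noise_sd.setdefault(m, DEFAULT_CHANGE_SD[m])
            if self.behavioral_noise_sd[m] <= 0:
                raise ConfigurationError(f"behavioral_noise_sd[{m}] must be positive")

    def latent_params(self) -> dict:
        """Loadings of the shared latent factor, from the coupling identity.

        With brain change = delta + a*u + e and behavioral change =
        b_m*u + f_m, the change correlation is
        r_m = a*b_m / sqrt((a^2 + sigma_e^2)(b_m^2 + sigma_f_m^2)).
        We fix lambda = a / brain_change_sd (at least 1/sqrt(2), raised to the
        largest |r_m| if needed) and solve b_m, sigma_f_m per measure.
        """
        r_abs_max = max((abs(r) for r in self.latent_coupling_r.values()), default=0.0)
        lam = max(math.sqrt(0.5), r_abs_max)
        if lam >= 1.0:
            raise ConfigurationError("couplings too strong for a single latent factor")
        a = lam * self.brain_change_sd
        sigma_e = self.brain_change_sd * math.sqrt(1.0 - lam * lam)
        loadings = {}
        for m in BEHAVIORAL_MEASURES:
            r = self.latent_coupling_r.get(m, 0.0)
            sig = self.behavioral_noise_sd[m]
            b = r * sig / lam
            loadings[m] = {"b": b, "sigma_f": math.sqrt(max(sig * sig - b * b, 0.0))}
        return {"lambda": lam, "a": a, "sigma_e": sigma_e, "loadings": loadings}


@dataclass
class Participant:
    id: str
    group: str  # "intervention" | "control"
    age: int
    sex: str  # "male" | "female"
    cesd: int | None
    imaging_ok: bool = True


@dataclass
class BehavioralScores:
    """One participant/timepoint row of the behavioral battery.

    POMS subscales are integer sums of five 0-4 Likert items (range 0-20);
    trail-making times are seconds.
    """

    participant: str
    time: str  # "pre" | "post"
    poms_ah: int
    poms_cb: int
    poms_dd: int
    poms_fi: int
    poms_ta: int
    poms_va: int
    poms_f: int
    tmt_a_sec: float
    tmt_b_sec: float


@dataclass
class Cohort:
    """Everything one simulated trial produced."""

    config: SimConfig
    participants: list[Participant]
    atlas: AtlasVolume
    fa_maps: dict[tuple[str, str], VolumeGrid]
    tissue_maps: dict[tuple[str, str], dict[str, VolumeGrid]]
    behavior: list[BehavioralScores]
    frame: pd.DataFrame
    manifest: dict

    @property
    def retained(self) -> list[Participant]:
        kept, _ = apply_exclusions(self.participants)
        return kept


# ---------------------------------------------------------------------------
# atlas


def ellipsoid_mask(grid_shape: Sequence[int]) -> np.ndarray:
    """Brain-like in-mask region: the ellipsoid inscribed in the grid."""
    axes = [np.arange(s) - (s - 1) / 2.0 for s in grid_shape]
    radii = [max((s - 1) / 2.0, 1.0) for s in grid_shape]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    rho2 = (zz / radii[0]) ** 2 + (yy / radii[1]) ** 2 + (xx / radii[2]) ** 2
    return rho2 <= 1.0


def generate_atlas(
    grid_shape: Sequence[int],
    n_regions: int,
    seed: int,
    *,
    voxel_size_mm: float | tuple[float, float, float] = 2.0,
    names: Mapping[int, str] | None = None,
) -> AtlasVolume:
    """Random parcellation of the in-mask ellipsoid into connected regions.

    Seeds ``n_regions`` voxels and grows them by multi-source breadth-first
    flood fill, which guarantees every region is a single connected blob and
    that labels 1..n_regions partition the mask exactly.
    """
    grid_shape = tuple(int(s) for s in grid_shape)
    mask = ellipsoid_mask(grid_shape)
    n_in = int(mask.sum())
    if n_regions < 1:
        raise ConfigurationError("n_regions must be >= 1")
    if n_regions > n_in:
        raise ConfigurationError(f"n_regions={n_regions} exceeds {n_in} in-mask voxels")
    rng = np.random.default_rng(seed)
    coords = np.argwhere(mask)
    seeds = coords[rng.choice(n_in, size=n_regions, replace=False)]

    labels = np.zeros(grid_shape, dtype=np.int32)
    queue: deque[tuple[int, int, int]] = deque()
    for lab, (i, j, k) in enumerate(seeds, start=1):
        labels[i, j, k] = lab
        queue.append((i, j, k))
    neighbors = ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1))
    while queue:
        i, j, k = queue.popleft()
        lab = labels[i, j, k]
        for di, dj, dk in neighbors:
            ni, nj, nk = i + di, j + dj, k + dk
            if 0 <= ni < grid_shape[0] and 0 <= nj < grid_shape[1] and 0 <= nk < grid_shape[2]:
                if mask[ni, nj, nk] and labels[ni, nj, nk] == 0:
                    labels[ni, nj, nk] = lab
                    queue.append((ni, nj, nk))

    if names is None and n_regions == len(TRACT_NAMES_8):
        names = {i + 1: t for i, t in enumerate(TRACT_NAMES_8)}
    return AtlasVolume(labels, names or {}, voxel_size_mm)


# ---------------------------------------------------------------------------
# latent draws shared by the frame and volume paths


def _draw_participants(config: SimConfig, rng: np.random.Generator) -> list[Participant]:
    n = config.n_per_group
    n_retained = 2 * n
    n_cesd = round(n_retained * config.cesd_exclusion_rate / (1.0 - config.cesd_exclusion_rate))
    n_imaging = round(n_retained * config.imaging_failure_rate)

    groups = ["intervention"] * n + ["control"] * n
    rng.shuffle(groups)
    people: list[Participant] = []
    for i, g in enumerate(groups):
        cesd = int(np.clip(round(rng.normal(7.0, 4.0)), 0, 15))
        people.append(
            Participant(
                id=f"P{i + 1:03d}",
                group=g,
                age=int(rng.integers(40, 69)),
                sex="female" if rng.random() < 0.55 else "male",
                cesd=cesd,
                imaging_ok=True,
            )
        )
    # screened-out recruits: group was assigned before exclusion
    for j in range(n_cesd + n_imaging):
        failed_imaging = j >= n_cesd
        cesd = int(rng.integers(0, 16)) if failed_imaging else int(16 + rng.poisson(4.0))
        people.append(
            Participant(
                id=f"P{n_retained + j + 1:03d}",
                group=str(rng.choice(["intervention", "control"])),
                age=int(rng.integers(40, 69)),
                sex="female" if rng.random() < 0.55 else "male",
                cesd=cesd,
                imaging_ok=not failed_imaging,
            )
        )
    return people


def _draw_latents(config: SimConfig, rng: np.random.Generator) -> dict:
    """All score-level random structure for the retained cohort."""
    lat = config.latent_params()
    people = _draw_participants(config, rng)
    retained = [p for p in people if p.imaging_ok and (p.cesd or 0) < 16]
    n = len(retained)
    R = config.n_regions
    is_int = np.array([p.group == "intervention" for p in retained])

    off = np.where(is_int, -config.baseline_group_offset / 2.0, config.baseline_group_offset / 2.0)
    shared = rng.normal(0.0, config.baseline_shared_sd, size=n)
    eta = rng.normal(0.0, config.baseline_region_sd, size=(n, R))
    fa_region_pre = 100.0 + off[:, None] + shared[:, None] + eta

    u = rng.normal(0.0, 1.0, size=n)
    e = rng.normal(0.0, lat["sigma_e"], size=n)
    delta_g = np.where(is_int, config.intervention_effect, config.control_drift)
    fa_change = delta_g + lat["a"] * u + e

    gm_pre = 100.0 + rng.normal(0.0, config.gm_baseline_sd, size=n)
    gm_change = rng.normal(0.0, config.gm_change_sd, size=n)

    behav_change: dict[str, np.ndarray] = {}
    for m in BEHAVIORAL_MEASURES:
        mu = DEFAULT_CHANGE_MEAN.get(m, 0.0)
        b, sf = lat["loadings"][m]["b"], lat["loadings"][m]["sigma_f"]
        sig = config.behavioral_noise_sd[m]
        coupled = mu + b * u + rng.normal(0.0, sf, size=n)
        uncoupled = mu + rng.normal(0.0, sig, size=n)
        behav_change[m] = np.where(is_int, coupled, uncoupled)

    behav_pre: dict[str, np.ndarray] = {}
    for m in POMS_SUBSCALES:
        mean, sd = BEHAVIOR_BASELINES[m]
        behav_pre[m] = rng.normal(mean, sd, size=n)
    tmt_a_pre = np.maximum(rng.normal(*BEHAVIOR_BASELINES["tmt_a"], size=n), 5.0)
    tmt_ba_pre = np.maximum(rng.normal(*BEHAVIOR_BASELINES["tmt_b_minus_a"], size=n), 3.0)
    behav_pre["tmt_a"] = tmt_a_pre
    behav_pre["tmt_b"] = tmt_a_pre + tmt_ba_pre

    return {
        "people": people,
        "retained": retained,
        "is_intervention": is_int,
        "fa_region_pre": fa_region_pre,
        "fa_change": fa_change,
        "gm_pre": gm_pre,
        "gm_change": gm_change,
        "behav_pre": behav_pre,
        "behav_change": behav_change,
        "latent": lat,
        "u": u,
    }


def _behavior_tables(latents: dict) -> list[BehavioralScores]:
    """Integer-rounded, range-clipped behavioral battery, pre and post."""
    rows: list[BehavioralScores] = []
    pre, change = latents["behav_pre"], latents["behav_change"]

    def poms_int(x: np.ndarray) -> np.ndarray:
        return np.clip(np.round(x), 0, POMS_MAX).astype(int)

    for t in ("pre", "post"):
        vals = {}
        for m in POMS_SUBSCALES:
            cont = pre[m] if t == "pre" else pre[m] + change[m]
            vals[m] = poms_int(cont)
        a = pre["tmt_a"] if t == "pre" else np.maximum(pre["tmt_a"] + change["tmt_a"], 5.0)
        b = pre["tmt_b"] if t == "pre" else np.maximum(pre["tmt_b"] + change["tmt_b"], 5.0)
        for i, p in enumerate(latents["retained"]):
            rows.append(
                BehavioralScores(
                    participant=p.id,
                    time=t,
                    **{m: int(vals[m][i]) for m in POMS_SUBSCALES},
                    tmt_a_sec=float(a[i]),
                    tmt_b_sec=float(b[i]),
                )
            )
    return rows


def behavior_to_frame(behavior: Sequence[BehavioralScores], participants: Sequence[Participant]) -> pd.DataFrame:
    """Long table of behavioral measures, with the derived TMT B-A score."""
    group_of = {p.id: p.group for p in participants}
    rows = []
    for b in behavior:
        g = group_of[b.participant]
        for m in POMS_SUBSCALES:
            rows.append((b.participant, g, b.time, m, float(getattr(b, m))))
        rows.append((b.participant, g, b.time, "tmt_a", b.tmt_a_sec))
        rows.append((b.participant, g, b.time, "tmt_b", b.tmt_b_sec))
        rows.append((b.participant, g, b.time, "tmt_b_a", b.tmt_b_sec - b.tmt_a_sec))
    return pd.DataFrame(rows, columns=["participant", "group", "time", "measure", "value"])


def _region_names(config: SimConfig) -> list[str]:
    if config.n_regions == len(TRACT_NAMES_8):
        return list(TRACT_NAMES_8)
    return [f"region_{i:02d}" for i in range(1, config.n_regions + 1)]


def _latent_frame(config: SimConfig, latents: dict) -> pd.DataFrame:
    """Score-level long table built directly from the latent draws."""
    names = _region_names(config)
    rows = []
    region_pre = latents["fa_region_pre"]
    change = latents["fa_change"]
    for i, p in enumerate(latents["retained"]):
        for t, shift in (("pre", 0.0), ("post", change[i])):
            vals = region_pre[i] + shift
            rows.append((p.id, p.group, t, "fa_bhq", float(vals.mean())))
            for r, name in enumerate(names):
                rows.append((p.id, p.group, t, f"fa_bhq:{name}", float(vals[r])))
            gm = latents["gm_pre"][i] + (latents["gm_change"][i] if t == "post" else 0.0)
            rows.append((p.id, p.group, t, "gm_bhq", float(gm)))
    brain = pd.DataFrame(rows, columns=["participant", "group", "time", "measure", "value"])
    behavior = behavior_to_frame(_behavior_tables(latents), latents["retained"])
    return pd.concat([brain, behavior], ignore_index=True)


def _manifest(config: SimConfig, latents: dict) -> dict:
    cfg = asdict(config)
    cfg["grid_shape"] = list(config.grid_shape)
    return {
        "seed": config.seed,
        "config": cfg,
        "latent": latents["latent"],
        "region_names": _region_names(config),
        "n_recruited": len(latents["people"]),
        "n_retained": len(latents["retained"]),
        "points_to_raw_fa": config.fa_subject_sd
        / math.hypot(config.baseline_shared_sd, config.baseline_region_sd),
    }


def generate_cohort_frame(config: SimConfig) -> tuple[pd.DataFrame, dict]:
    """Score-level cohort table without voxel rendering.

    Same latent model and draw sequence as :func:`generate_cohort`, so the two
    paths agree participant by participant up to voxel noise; use this for
    replicate-heavy calibration work.
    """
    rng = np.random.default_rng(config.seed)
    latents = _draw_latents(config, rng)
    return _latent_frame(config, latents), _manifest(config, latents)


# ---------------------------------------------------------------------------
# voxel rendering


def _tissue_profiles(grid_shape: Sequence[int]) -> dict[str, np.ndarray]:
    """Smooth radial tissue templates: WM core, GM shell, thin CSF rim."""
    axes = [np.arange(s) - (s - 1) / 2.0 for s in grid_shape]
    radii = [max((s - 1) / 2.0, 1.0) for s in grid_shape]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    rho = np.sqrt((zz / radii[0]) ** 2 + (yy / radii[1]) ** 2 + (xx / radii[2]) ** 2)
    mask = rho <= 1.0
    wm = 0.85 * np.exp(-((rho / 0.45) ** 2))
    gm = 0.75 * np.exp(-(((rho - 0.72) / 0.22) ** 2))
    csf = 0.08 + 0.3 * np.exp(-(((rho - 0.97) / 0.1) ** 2))
    return {k: np.where(mask, v, 0.0) for k, v in {"gm": gm, "wm": wm, "csf": csf}.items()}


def generate_cohort(config: SimConfig) -> Cohort:
    """Simulate a full trial: participants, atlas, volumes, behavior.

    Identical config (including seed) gives bit-identical output.  FA maps
    are clipped to [0, 1] after noise; tissue maps are nonnegative.  Volumes
    are rendered for the retained (analysis-set) participants, matching a
    design in which screening precedes scanning.
    """
    rng = np.random.default_rng(config.seed)
    latents = _draw_latents(config, rng)
    atlas = generate_atlas(
        config.grid_shape, config.n_regions, config.seed, voxel_size_mm=config.voxel_size_mm
    )
    vox = (config.voxel_size_mm,) * 3

    k = config.fa_subject_sd / math.hypot(config.baseline_shared_sd, config.baseline_region_sd)
    fa_base = np.linspace(0.32, 0.58, config.n_regions)
    base_map = np.zeros(config.grid_shape)
    for r in range(config.n_regions):
        base_map[atlas.labels == r + 1] = fa_base[r]
    in_mask = atlas.labels > 0

    profiles = _tissue_profiles(config.grid_shape)
    gm_scale = 0.06 / max(config.gm_baseline_sd, 1e-9)  # relative GM per point

    fa_maps: dict[tuple[str, str], VolumeGrid] = {}
    tissue_maps: dict[tuple[str, str], dict[str, VolumeGrid]] = {}
    for i, p in enumerate(latents["retained"]):
        region_pts_pre = latents["fa_region_pre"][i] - 100.0
        icv_factor = 1.0 + rng.normal(0.0, 0.04)
        for t in ("pre", "post"):
            pts = region_pts_pre + (latents["fa_change"][i] if t == "post" else 0.0)
            shift = np.zeros(config.grid_shape)
            for r in range(config.n_regions):
                shift[atlas.labels == r + 1] = pts[r] * k
            fa = base_map + shift
            if config.voxel_noise_sd > 0:
                fa = fa + np.where(in_mask, rng.normal(0.0, config.voxel_noise_sd, config.grid_shape), 0.0)
            fa = np.clip(np.where(in_mask, fa, 0.0), 0.0, 1.0)
            fa_maps[(p.id, t)] = VolumeGrid(fa, vox, "fa")

            gm_pts = latents["gm_pre"][i] - 100.0 + (latents["gm_change"][i] if t == "post" else 0.0)
            tis = {}
            for mod in ("gm", "wm", "csf"):
                v = profiles[mod] * icv_factor
                if mod == "gm":
                    v = v * (1.0 + gm_pts * gm_scale)
                if config.voxel_noise_sd > 0:
                    v = v + np.where(
                        in_mask, rng.normal(0.0, config.voxel_noise_sd, config.grid_shape), 0.0
                    )
                tis[mod] = VolumeGrid(np.maximum(np.where(in_mask, v, 0.0), 0.0), vox, mod)
            tissue_maps[(p.id, t)] = tis

    return Cohort(
        config=config,
        participants=latents["people"],
        atlas=atlas,
        fa_maps=fa_maps,
        tissue_maps=tissue_maps,
        behavior=_behavior_tables(latents),
        frame=_latent_frame(config, latents),
        manifest=_manifest(config, latents),
    )


# ---------------------------------------------------------------------------
# screening


def apply_exclusions(
    participants: Sequence[Participant], cesd_threshold: int = 16
) -> tuple[list[Participant], list[dict]]:
    """Screen the recruited pool: depression scale cut-off, then imaging QC.

    Retains participants with CES-D strictly below the threshold and usable
    imaging; returns the retained list plus a per-exclusion log.
    """
    retained: list[Participant] = []
    log: list[dict] = []
    for p in participants:
        if p.cesd is None:
            raise ValueError(f"participant {p.id} has no CES-D score")
        if p.cesd >= cesd_threshold:
            log.append({"participant": p.id, "reason": "cesd_at_or_above_threshold"})
        elif not p.imaging_ok:
            log.append({"participant": p.id, "reason": "imaging_unavailable"})
        else:
            retained.append(p)
    return retained, log
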