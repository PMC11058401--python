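"""End-to-end orchestration: simulate -> score -> analyze -> report.

A run directory contains a manifest (config + seed + versions), the NIfTI
volumes and atlas, participant/behavior/score CSVs, the report tables, and an
index JSON listing every artifact.  A persisted config plus seed reproduces a
run bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig
from .grids import save_atlas, save_nifti
from .quotient import score_cohort, scores_to_frame
from .simulate import (
    SimConfig,
    apply_exclusions,
    behavior_to_frame,
    generate_cohort,
)
from .study import InterventionStudy

__all__ = ["run_end_to_end", "simulate_to_dir", "score_from_cohort"]

log = logging.getLogger("bhq")


def _write_participants(people, path: Path) -> None:
    pd.DataFrame(
        [dataclasses.asdict(p) for p in people]
    ).to_csv(path, index=False)


def simulate_to_dir(config: SimConfig, out_dir: str | Path, *, write_volumes: bool = True) -> dict:
    """Generate one cohort and persist it; returns the artifact index."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(config)
    index: dict[str, str] = {}

    if write_volumes:
        vol_dir = out / "volumes"
        vol_dir.mkdir(exist_ok=True)
        for (pid, t), v in cohort.fa_maps.items():
            save_nifti(v, vol_dir / f"sub-{pid}_time-{t}_mod-fa.nii.gz")
        for (pid, t), tissues in cohort.tissue_maps.items():
            for mod, v in tissues.items():
                save_nifti(v, vol_dir / f"sub-{pid}_time-{t}_mod-{mod}.nii.gz")
        index["volumes"] = str(vol_dir)
    save_atlas(cohort.atlas, out / "atlas.nii.gz")
    index["atlas"] = str(out / "atlas.nii.gz")

    _write_participants(cohort.participants, out / "participants.csv")
    index["participants"] = str(out / "participants.csv")
    pd.DataFrame([dataclasses.asdict(b) for b in cohort.behavior]).to_csv(
        out / "behavior.csv", index=False
    )
    index["behavior"] = str(out / "behavior.csv")
    behavior_to_frame(cohort.behavior, cohort.retained).to_csv(
        out / "behavior_long.csv", index=False
    )
    index["behavior_long"] = str(out / "behavior_long.csv")
    cohort.frame.to_csv(out / "latent_frame.csv", index=False)
    index["latent_frame"] = str(out / "latent_frame.csv")
    (out / "manifest.json").write_text(json.dumps(cohort.manifest, indent=1))
    index["manifest"] = str(out / "manifest.json")
    index["_cohort"] = ""  # placeholder so callers know simulation ran
    return index


def score_from_cohort(cohort, scoring) -> pd.DataFrame:
    """Score both modalities of an in-memory cohort into a tidy long table."""
    ref_keys = None
    if scoring.reference_pool == "pre":
        ref_keys = [k for k in cohort.fa_maps if k[1] == "pre"]
    common = dict(
        fwhm_mm=scoring.fwhm_mm,
        ddof=scoring.ddof,
        sd_floor=scoring.sd_floor,
        mean_min=scoring.mean_min,
        reference_keys=ref_keys,
        volume_weighted=scoring.volume_weighted,
    )
    fa_scores = score_cohort(
        cohort.fa_maps, cohort.atlas, "fa", smooth_fa=scoring.smooth_fa, **common
    )
    gm_scores = score_cohort(cohort.tissue_maps, cohort.atlas, "gm", **common)
    return pd.concat(
        [scores_to_frame(fa_scores), scores_to_frame(gm_scores)], ignore_index=True
    )


def run_end_to_end(config: RunConfig, out_dir: str | Path, seed: int | None = None) -> Path:
    """Full reproduction run; returns the run directory.

    ``seed`` overrides the simulation seed in ``config``.  The directory is
    validated writable before any compute.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    probe = out / ".write_probe"
    probe.write_text("")
    probe.unlink()

    if seed is not None:
        config = RunConfig.from_dict({**config.to_dict(), "sim": {**config.to_dict()["sim"], "seed": seed}})
    t0 = time.time()
    log.info("simulating cohort: n=%d/group, grid=%s", config.sim.n_per_group, config.sim.grid_shape)
    cohort = generate_cohort(config.sim)
    index: dict[str, str] = {}

    config.to_yaml(out / "config.yaml")
    index["config"] = str(out / "config.yaml")
    sim_index = simulate_to_dir(config.sim, out, write_volumes=config.write_volumes)
    sim_index.pop("_cohort", None)
    index.update(sim_index)

    retained, exclusion_log = apply_exclusions(cohort.participants)
    pd.DataFrame(exclusion_log or [{"participant": None, "reason": None}]).to_csv(
        out / "exclusions.csv", index=False
    )
    index["exclusions"] = str(out / "exclusions.csv")
    log.info("retained %d of %d recruited", len(retained), len(cohort.participants))

    scores = score_from_cohort(cohort, config.scoring)
    scores.to_csv(out / "scores.csv", index=False, float_format="%.10g")
    index["scores"] = str(out / "scores.csv")

    behavior = behavior_to_frame(cohort.behavior, retained)
    group_of = {p.id: p.group for p in retained}
    scores = scores[scores["participant"].isin(group_of)]
    scores = scores.assign(group=scores["participant"].map(group_of))

    participants_df = pd.DataFrame([dataclasses.asdict(p) for p in retained]).rename(
        columns={"id": "participant"}
    )
    study = InterventionStudy.from_frames(
        scores,
        behavior,
        participants=participants_df,
        bh_level=config.analysis.bh_level,
        welch=config.analysis.welch,
    )
    results = study.fit()
    report_index = results.save(out / "report")
    index.update({f"report/{k}": v for k, v in report_index.items()})

    manifest = json.loads((out / "manifest.json").read_text())
    manifest["bhq_version"] = __version__
    manifest["elapsed_seconds"] = round(time.time() - t0, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))

    (out / "index.json").write_text(
        json.dumps({k: str(Path(v).relative_to(out)) for k, v in index.items()}, indent=1)
    )
    return out
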