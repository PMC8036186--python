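"""End-to-end orchestration: simulate -> fuse -> reliability ->
build-atlas -> compare, with JSON sidecars for reproducibility.

Every output artifact gets a ``<name>.json`` sidecar recording the tool
version, a hash of the run configuration, and SHA-256 checksums of the
inputs, so a run can be reproduced bit-exactly from its sidecar.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .atlas import build_atlas, com_dispersion, threshold_volume_curve, volume
from .contrast import midbrain_contrast
from .image_io import write_volume
from .metrics import conjunction, segmentation_report
from .synthetic import CohortSpec, make_cohort

__all__ = ["RunConfig", "run_end_to_end", "write_sidecar", "write_cohort_bids"]

DEFAULT_THRESHOLDS = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Parameters of one end-to-end run; serialized into every sidecar."""

    out_dir: str
    n_subjects: int = 27
    seed: int = 42
    jitter_p: float = 0.5
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    connectivity: int = 6
    dd_variant: str = "cross"
    write_images: bool = True

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["thresholds"] = list(self.thresholds)
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_sidecar(
    artifact: Path, config: RunConfig | dict, inputs: list[Path] | None = None
) -> None:
    cfg = config.as_dict() if isinstance(config, RunConfig) else dict(config)
    meta = {
        "tool": "vta-atlas",
        "version": __version__,
        "config": cfg,
        "config_hash": (
            config.config_hash
            if isinstance(config, RunConfig)
            else hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]
        ),
        "input_checksums": {str(p): _sha256(Path(p)) for p in (inputs or [])},
    }
    artifact.with_suffix(artifact.suffix + ".json").write_text(
        json.dumps(meta, indent=2) + "\n"
    )


def write_cohort_bids(cohort, spec: CohortSpec, out_dir: Path) -> list[Path]:
    """Write a cohort as a BIDS-flavored tree of NIfTI files plus a JSON
    sidecar of the generating spec; returns the written mask paths."""
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "cohort_spec.json").write_text(json.dumps(spec.as_dict(), indent=2) + "\n")
    written: list[Path] = []
    for i, subj in enumerate(cohort, start=1):
        anat = out_dir / f"sub-{i:02d}" / "anat"
        anat.mkdir(parents=True, exist_ok=True)
        write_volume(subj.t1w, anat / f"sub-{i:02d}_T1w.nii.gz")
        write_volume(subj.echo3, anat / f"sub-{i:02d}_echo-3_T2starw.nii.gz")
        write_volume(subj.echo4, anat / f"sub-{i:02d}_echo-4_T2starw.nii.gz")
        write_volume(subj.truth_mask, anat / f"sub-{i:02d}_desc-truth_mask.nii.gz")
        for r, rm in enumerate(subj.rater_masks, start=1):
            p = anat / f"sub-{i:02d}_desc-rater{r}_mask.nii.gz"
            write_volume(rm, p)
            written.append(p)
    return written


def run_end_to_end(config: RunConfig) -> Path:
    """Run the full pipeline on a synthetic cohort and write all reports.

    Stages execute in order; a failing stage aborts with its name, and a
    ``FAILED`` marker file is left next to any partial outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        spec = CohortSpec(
            n_subjects=config.n_subjects,
            jitter_p=config.jitter_p,
            seed=config.seed,
        )
        cohort = make_cohort(spec)
        if config.write_images:
            write_cohort_bids(cohort, spec, out / "cohort")

        stage = "fuse"
        subj0 = cohort[0]
        fused = midbrain_contrast(
            subj0.t1w, subj0.echo3, subj0.echo4, subj0.midbrain_box
        )
        fused_path = out / "sub-01_midbraincontrast.nii.gz"
        write_volume(fused, fused_path)
        write_sidecar(fused_path, config)

        stage = "reliability"
        rows = []
        for i, subj in enumerate(cohort, start=1):
            rep = segmentation_report(
                subj.rater_masks[0],
                subj.rater_masks[1],
                connectivity=config.connectivity,
                dd_variant=config.dd_variant,
            )
            rows.append({"subject": f"sub-{i:02d}", **rep.as_dict()})
        rel = pd.DataFrame(rows)
        rel_path = out / "reliability.tsv"
        rel.to_csv(rel_path, sep="\t", index=False)
        write_sidecar(rel_path, config)

        stage = "build-atlas"
        conj = [
            conjunction(s.rater_masks[0], s.rater_masks[1]) for s in cohort
        ]
        atlas = build_atlas(
            conj, provenance=[f"sub-{i:02d}" for i in range(1, len(conj) + 1)]
        )
        atlas_path = out / "atlas_probseg.nii.gz"
        write_volume(atlas, atlas_path)
        write_sidecar(atlas_path, config)

        curve = threshold_volume_curve(atlas, list(config.thresholds))
        curve_path = out / "threshold_volume_curve.tsv"
        curve.to_csv(curve_path, sep="\t", index=False)
        write_sidecar(curve_path, config)

        stats = com_dispersion(conj)
        com_path = out / "com_stats.json"
        com_path.write_text(
            json.dumps(
                {
                    "mean_com_mm": stats.mean_com.tolist(),
                    "mean_signed_deviation_mm": stats.mean_signed_deviation.tolist(),
                    "sd_mm": stats.sd.tolist(),
                    "per_mask_com_mm": stats.per_mask_com.tolist(),
                    "unthresholded_volume_mm3": volume(atlas.support),
                    "weighted_volume_mm3": volume(atlas, weighted=True),
                },
                indent=2,
            )
            + "\n"
        )
        write_sidecar(com_path, config)
    except Exception as err:
        (out / "FAILED").write_text(f"stage {stage!r} failed: {err}\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed") from err
    return out
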