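"""NIfTI / CSV / JSON input-output.

Volumes and displacement fields travel as NIfTI (.nii.gz) with the voxel
spacing encoded in the affine; displacement fields store the 3 vector
components on the 4th axis.  Cohorts are a CSV manifest next to the per-
subject NIfTI files.  Traces, gene tables and qPCR plates are plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .atlas import DEFAULT_NAMES, DEFAULT_REGIONS, LabelAtlas
from .fields import DisplacementField
from .simulate import Cohort, Electropherogram, GroundTruth, Subject

__all__ = [
    "save_volume",
    "load_volume",
    "save_field",
    "load_field",
    "save_atlas",
    "load_atlas",
    "save_cohort",
    "load_cohort",
    "save_trace_csv",
    "load_trace_csv",
    "save_json",
    "load_json",
]


def _affine(spacing) -> np.ndarray:
    return np.diag(list(spacing) + [1.0])


def save_volume(path, values: np.ndarray, spacing) -> None:
    nib.save(nib.Nifti1Image(np.asarray(values), _affine(spacing)), str(path))


def load_volume(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj), spacing


def save_field(path, field: DisplacementField) -> None:
    save_volume(path, field.u, field.spacing)


def load_field(path) -> DisplacementField:
    u, spacing = load_volume(path)
    return DisplacementField(np.asarray(u, dtype=float), spacing)


def save_atlas(out_dir, atlas: LabelAtlas) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_volume(out / "atlas_labels.nii.gz", atlas.labels.astype(np.int16), atlas.spacing)
    meta = {
        "names": {str(k): v for k, v in atlas.names.items()},
        "regions": {k: list(v) for k, v in atlas.regions.items()},
        "mirror_axis": atlas.mirror_axis,
        "mirror_plane": atlas.mirror_plane,
        "meta": atlas.meta,
    }
    save_json(out / "atlas_meta.json", meta)


def load_atlas(out_dir) -> LabelAtlas:
    out = Path(out_dir)
    labels, spacing = load_volume(out / "atlas_labels.nii.gz")
    meta = load_json(out / "atlas_meta.json")
    return LabelAtlas(
        labels=np.asarray(labels).astype(np.int16),
        names={int(k): v for k, v in meta.get("names", DEFAULT_NAMES).items()},
        spacing=spacing,
        mirror_axis=int(meta.get("mirror_axis", 0)),
        mirror_plane=meta.get("mirror_plane"),
        regions={k: tuple(v) for k, v in meta.get("regions", DEFAULT_REGIONS).items()},
        meta=meta.get("meta", {}),
    )


def save_cohort(out_dir, cohort: Cohort, atlas: LabelAtlas | None = None) -> Path:
    """Write per-subject fields/channels plus a CSV manifest; returns manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if atlas is not None:
        save_atlas(out, atlas)
    rows = []
    for s in cohort:
        field_path = out / f"{s.subject_id}_field.nii.gz"
        save_field(field_path, s.field)
        row = {
            "subject_id": s.subject_id,
            "genotype": s.genotype,
            "batch": s.batch,
            "field_path": field_path.name,
            "contraction": s.truth.contraction,
            "seed_entropy": s.seed_entropy,
        }
        for ch, img in s.channels.items():
            ch_path = out / f"{s.subject_id}_{ch}.nii.gz"
            save_volume(ch_path, img, s.field.spacing)
            row[f"channel_{ch}"] = ch_path.name
        if s.truth.division_volumes:
            for name, v in s.truth.division_volumes.items():
                row[f"true_vol_{name}"] = v
            row["true_vol_total"] = s.truth.total_volume
        rows.append(row)
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_cohort(out_dir) -> Cohort:
    """Load a cohort saved by `save_cohort` (ground-truth effect masks are not
    round-tripped; truth volumes come back from the manifest)."""
    out = Path(out_dir)
    manifest = pd.read_csv(out / "manifest.csv")
    subjects = []
    for _, row in manifest.iterrows():
        field = load_field(out / row["field_path"])
        channels = {}
        for col in manifest.columns:
            if col.startswith("channel_") and isinstance(row[col], str):
                channels[col[len("channel_"):]], _ = load_volume(out / row[col])
        vols = {
            col[len("true_vol_"):]: float(row[col])
            for col in manifest.columns
            if col.startswith("true_vol_") and col != "true_vol_total" and pd.notna(row[col])
        }
        truth = GroundTruth(
            effect_region=np.zeros(field.shape, dtype=bool),
            contraction=float(row.get("contraction", 1.0)),
            division_volumes=vols or None,
            total_volume=float(row["true_vol_total"]) if "true_vol_total" in row and pd.notna(row.get("true_vol_total")) else None,
        )
        subjects.append(
            Subject(
                subject_id=row["subject_id"],
                genotype=row["genotype"],
                batch=row["batch"],
                field=field,
                channels=channels,
                truth=truth,
                seed_entropy=int(row.get("seed_entropy", 0)),
            )
        )
    return Cohort(subjects=subjects, design=None)


def save_trace_csv(path, trace: Electropherogram) -> None:
    pd.DataFrame({"size_bp": trace.size_bp, "rfu": trace.rfu}).to_csv(path, index=False)


def load_trace_csv(path, wt_size_bp: float | None = None, **meta) -> Electropherogram:
    df = pd.read_csv(path)
    return Electropherogram(
        size_bp=df["size_bp"].to_numpy(),
        rfu=df["rfu"].to_numpy(),
        wt_size_bp=wt_size_bp,
        **meta,
    )


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def save_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def load_json(path):
    return json.loads(Path(path).read_text())
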