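"""Plan JSON schema (versioned), volume export and config loading."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, Field, ValidationError, field_validator

from arcplan.phantom import VoxelGrid
from arcplan.plans import SCHEME_TAGS, Aperture, ControlPoint, Plan

PLAN_FORMAT = "arcplan-plan"
PLAN_VERSION = 1


class ApertureModel(BaseModel):
    left: list[float]
    right: list[float]
    mu: float = Field(ge=0)

    @field_validator("right")
    @classmethod
    def _same_length(cls, v, info):
        left = info.data.get("left")
        if left is not None and len(v) != len(left):
            raise ValueError("left and right leaf arrays differ in length")
        return v


class ControlPointModel(BaseModel):
    geometry_index: int = Field(ge=0)
    apertures: list[ApertureModel]


class PlanModel(BaseModel):
    format: str = PLAN_FORMAT
    version: int = PLAN_VERSION
    mode: Literal["dynamic_arc", "static"]
    scheme: str
    prescription_gy: float = Field(gt=0)
    seed: int = 0
    control_points: list[ControlPointModel]
    meta: dict = Field(default_factory=dict)

    @field_validator("scheme")
    @classmethod
    def _known_scheme(cls, v):
        if v not in SCHEME_TAGS:
            raise ValueError(f"unknown scheme tag {v!r}")
        return v

    @field_validator("format")
    @classmethod
    def _known_format(cls, v):
        if v != PLAN_FORMAT:
            raise ValueError(f"not an {PLAN_FORMAT} file")
        return v


class PlanSchemaError(ValueError):
    """Schema violation naming the offending field."""


def _meta_to_json(meta: dict) -> dict:
    out = {}
    for k, v in meta.items():
        if k == "geometries":
            out[k] = {str(i): list(g.direction) for i, g in v.items()}
        elif k == "directions":
            out[k] = [list(d) for d in v]
        else:
            try:
                json.dumps(v)
                out[k] = v
            except TypeError:
                continue  # drop non-serializable scratch entries
    return out


def _meta_from_json(meta: dict) -> dict:
    out = dict(meta)
    if "directions" in out:
        out["directions"] = [tuple(float(c) for c in d) for d in out["directions"]]
    if "geometries" in out:
        from arcplan.machine import ControlPointGeometry
        out["geometries"] = {
            int(i): ControlPointGeometry(int(i), tuple(float(c) for c in d))
            for i, d in out["geometries"].items()
        }
    return out


def write_plan(plan: Plan, path) -> None:
    model = PlanModel(
        mode=plan.mode,
        scheme=plan.scheme,
        prescription_gy=plan.prescription_gy,
        seed=plan.seed,
        control_points=[
            ControlPointModel(
                geometry_index=cp.geometry_index,
                apertures=[
                    ApertureModel(left=list(a.left), right=list(a.right), mu=a.mu)
                    for a in cp.apertures
                ],
            )
            for cp in plan.control_points
        ],
        meta=_meta_to_json(plan.meta),
    )
    Path(path).write_text(model.model_dump_json(indent=1))


def read_plan(path) -> Plan:
    raw = json.loads(Path(path).read_text())
    try:
        model = PlanModel.model_validate(raw)
    except ValidationError as e:
        first = e.errors()[0]
        loc = ".".join(str(p) for p in first["loc"])
        raise PlanSchemaError(f"invalid plan file: {loc}: {first['msg']}") from e
    cps = [
        ControlPoint(
            cp.geometry_index,
            [Aperture(np.array(a.left), np.array(a.right), a.mu) for a in cp.apertures],
        )
        for cp in model.control_points
    ]
    return Plan(model.mode, cps, prescription_gy=model.prescription_gy,
                scheme=model.scheme, seed=model.seed,
                meta=_meta_from_json(model.meta))


def write_volume(grid: VoxelGrid, path) -> None:
    """Write a voxel grid as NIfTI (mm affine from origin/spacing)."""
    import nibabel as nib

    affine = np.eye(4)
    affine[:3, :3] = np.diag(grid.spacing)
    affine[:3, 3] = grid.origin
    nib.save(nib.Nifti1Image(np.asarray(grid.values, dtype=np.float32), affine), str(path))


def read_volume(path) -> VoxelGrid:
    import nibabel as nib

    img = nib.load(str(path))
    aff = img.affine
    return VoxelGrid(aff[:3, 3].copy(), np.diag(aff[:3, :3]).copy(),
                     np.asarray(img.get_fdata()))


def write_dvh_csv(curves: dict, path) -> None:
    """DVH export: one dose column plus one cumulative-fraction column
    per structure, resampled onto a common dose axis."""
    top = max(float(c.bin_edges[-1]) for c in curves.values())
    axis = np.linspace(0.0, top, 401)
    cols = [axis]
    names = sorted(curves)
    for n in names:
        c = curves[n]
        cols.append(np.interp(axis, c.bin_edges, c.volume_fraction))
    header = "dose_gy," + ",".join(names)
    np.savetxt(path, np.column_stack(cols), delimiter=",", header=header,
               comments="", fmt="%.6f")


def write_fluence_csv(fmap: np.ndarray, path) -> None:
    np.savetxt(path, fmap, delimiter=",", fmt="%.8g")


def load_config(path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f)
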