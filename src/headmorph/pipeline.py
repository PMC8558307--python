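"""Config-driven personalization pipelines.

A pipeline is an ordered list of registration steps — a rigid pre-alignment,
a cranial-mask Demons step (the anchor of every pipeline), optional Demons
feature steps, and optional externally produced fields (e.g. from an
intensity registration tool) — followed by field summation, mesh morphing,
WM regrouping, element-quality gating and, when subject segmentations are
available, DICE/HD95 scoring of the baseline warped through the nested
inverse chain of the steps.

Three pipeline archetypes cover increasing anatomical difficulty: the basic
two-step cranial + intensity pipeline; the same with extra feature steps for
grossly changed anatomy (enlarged ventricles, lesions); and the same with
extra multimodality intensity steps. All are expressible as configs, not
code.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import yaml

from .demons_reg import DemonsParams, RigidTransform, demons_register, rigid_align
from .dispfield import (
    DisplacementField,
    field_jacobian_map,
    load_external_field,
    resample_field,
    sum_fields,
    warp_by_inverse_chain,
)
from .evalmetrics import OverlapScores, region_scores
from .grouping import regroup_elements
from .hexmesh import ElementQualityReport, HexMesh, morph_mesh, quality_report
from .imagevol import LabelMask, VolumeImage

log = logging.getLogger(__name__)

STEP_KINDS = ("rigid", "demons_mask", "demons_feature", "external_field")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineStep:
    kind: str
    moving: str = ""  # input name of the subject-side mask
    fixed: str = ""  # input name of the baseline-side mask
    tag: str = ""
    params: DemonsParams | None = None
    path: str = ""  # external_field only
    dialect: str = "mm"  # external_field only

    def __post_init__(self) -> None:
        if self.kind not in STEP_KINDS:
            raise PipelineError(f"unknown step kind {self.kind!r}")


@dataclass
class PipelineSpec:
    """Declarative description of one personalization run."""

    steps: list[PipelineStep]
    baseline_image: str = "baseline_image"
    baseline_mesh: str = "baseline_mesh"
    regroup_mask: str = ""  # input name of the subject's WM/tissue mask
    regroup_parts: tuple[str, ...] = ("GM", "WM")
    evaluate_regions: tuple[str, ...] = ()
    hd95_units: str = "voxel"
    seed: int = 0

    def __post_init__(self) -> None:
        tags = [s.tag for s in self.steps if s.kind != "rigid"]
        if len(tags) != len(set(tags)):
            raise PipelineError("step tags must be unique")
        non_rigid = [s for s in self.steps if s.kind != "rigid"]
        if non_rigid and non_rigid[0].kind != "demons_mask":
            raise PipelineError(
                "the first non-rigid step must be the cranial-mask demons step"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineSpec":
        cfg = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(cfg)

    @classmethod
    def from_dict(cls, cfg: dict) -> "PipelineSpec":
        steps = []
        for raw in cfg.get("steps", []):
            params = None
            if "params" in raw:
                p = dict(raw["params"])
                if "iterations" in p:
                    p["iterations"] = tuple(p["iterations"])
                params = DemonsParams(**p)
            steps.append(
                PipelineStep(
                    kind=raw["kind"],
                    moving=raw.get("moving", ""),
                    fixed=raw.get("fixed", ""),
                    tag=raw.get("tag", ""),
                    params=params,
                    path=raw.get("path", ""),
                    dialect=raw.get("dialect", "mm"),
                )
            )
        re_cfg = cfg.get("regroup", {})
        ev_cfg = cfg.get("evaluate", {})
        return cls(
            steps=steps,
            baseline_image=cfg.get("baseline_image", "baseline_image"),
            baseline_mesh=cfg.get("baseline_mesh", "baseline_mesh"),
            regroup_mask=re_cfg.get("mask", ""),
            regroup_parts=tuple(re_cfg.get("parts", ("GM", "WM"))),
            evaluate_regions=tuple(ev_cfg.get("regions", ())),
            hd95_units=ev_cfg.get("units", "voxel"),
            seed=int(cfg.get("seed", 0)),
        )


@dataclass
class PersonalizationResult:
    """Everything one pipeline run produces."""

    fields: list[DisplacementField]
    g_subj: DisplacementField
    mesh: HexMesh
    quality: ElementQualityReport
    quality_ok: bool
    rigid: RigidTransform | None = None
    scores: OverlapScores | None = None
    warped_image: VolumeImage | None = None
    run_log: list[dict] = dc_field(default_factory=list)

    def save_log(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.run_log, indent=2))


def _resolve(inputs: dict, name: str, step_tag: str):
    try:
        return inputs[name]
    except KeyError:
        raise PipelineError(
            f"step {step_tag!r}: input {name!r} not provided"
        ) from None


def run_pipeline(spec: PipelineSpec, inputs: dict) -> PersonalizationResult:
    """Execute a personalization pipeline end to end.

    ``inputs`` maps names to loaded objects: the baseline mesh and image,
    the per-step masks (subject side = moving, baseline side = fixed), and
    optionally ``baseline_labels`` / ``subject_labels`` dicts of region
    masks for scoring. Before every registration the baseline-side mask is
    warped by the inverse chain of the fields accumulated so far, so each
    step sees the progressively personalized baseline.
    """
    mesh: HexMesh = _resolve(inputs, spec.baseline_mesh, "baseline")
    baseline_img: VolumeImage | None = inputs.get(spec.baseline_image)
    grid_ref: VolumeImage | None = baseline_img

    rigid: RigidTransform | None = None
    fields: list[DisplacementField] = []
    run_log: list[dict] = []

    for i, step in enumerate(spec.steps):
        t0 = time.time()
        tag = step.tag or f"step{i}"
        try:
            if step.kind == "rigid":
                moving = _resolve(inputs, step.moving, tag)
                fixed = _resolve(inputs, step.fixed, tag)
                rigid = rigid_align(moving, fixed)
                run_log.append(
                    {"step": tag, "kind": step.kind,
                     "translation_mm": rigid.translation.tolist(),
                     "seconds": round(time.time() - t0, 2)}
                )
                continue
            if step.kind == "external_field":
                if grid_ref is None:
                    raise PipelineError(
                        "external_field steps need the baseline image grid"
                    )
                f = load_external_field(
                    step.path, grid_ref, dialect=step.dialect, tag=tag
                )
            else:  # demons_mask / demons_feature
                moving = _resolve(inputs, step.moving, tag)
                fixed = _resolve(inputs, step.fixed, tag)
                if grid_ref is None:
                    grid_ref = fixed
                if rigid is not None:
                    moving = rigid.resample_mask(moving, fixed)
                fixed_w = (
                    warp_by_inverse_chain(fixed, fields, interp="nearest")
                    if fields
                    else fixed
                )
                f = demons_register(moving, fixed_w, step.params)
                f.tag = tag
            fields.append(f)
            jmin = float(
                field_jacobian_map(f).data[1:-1, 1:-1, 1:-1].min()
            )
            run_log.append(
                {"step": tag, "kind": step.kind,
                 "mean_disp_mm": float(np.linalg.norm(f.vectors, axis=-1).mean()),
                 "max_disp_mm": float(np.linalg.norm(f.vectors, axis=-1).max()),
                 "jacobian_min": jmin,
                 "seconds": round(time.time() - t0, 2)}
            )
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"step {tag!r} failed: {exc}") from exc

    if not fields:
        raise PipelineError("pipeline produced no displacement fields")
    g_subj = sum_fields(fields)
    g_subj.tag = "g_subj"

    morphed = morph_mesh(mesh, g_subj)
    if spec.regroup_mask:
        mask: LabelMask = _resolve(inputs, spec.regroup_mask, "regroup")
        if rigid is not None:
            mask = rigid.resample_mask(mask, mask)
        morphed = regroup_elements(
            morphed, mask, parts_in_play=set(spec.regroup_parts)
        )
    quality = quality_report(morphed)
    quality_ok = quality.satisfactory
    if not quality_ok:
        log.warning(
            "element quality below the satisfaction bound: %.1f%% of elements "
            "with scaled Jacobian >= 0.5 (need >= 95%%)",
            quality.percentages["scaled_jacobian"],
        )

    warped_image = None
    if baseline_img is not None:
        warped_image = warp_by_inverse_chain(baseline_img, fields)

    scores = None
    if spec.evaluate_regions:
        base_labels: dict[str, LabelMask] = inputs.get("baseline_labels", {})
        subj_labels: dict[str, LabelMask] = inputs.get("subject_labels", {})
        warped_labels = {
            name: warp_by_inverse_chain(m, fields, interp="nearest")
            for name, m in base_labels.items()
        }
        if rigid is not None:
            subj_labels = {
                name: rigid.resample_mask(m, m) for name, m in subj_labels.items()
            }
        scores = region_scores(
            warped_labels,
            subj_labels,
            list(spec.evaluate_regions),
            subject_id=inputs.get("subject_id", ""),
            units=spec.hd95_units,
        )

    return PersonalizationResult(
        fields=fields,
        g_subj=g_subj,
        mesh=morphed,
        quality=quality,
        quality_ok=quality_ok,
        rigid=rigid,
        scores=scores,
        warped_image=warped_image,
        run_log=run_log,
    )


def chain_via_intermediate(
    g_base: DisplacementField, bridge: DisplacementField
) -> DisplacementField:
    """Personalize through an intermediate subject: g = g_base + g_bridge.

    ``g_base`` personalizes the baseline to the intermediate subject;
    ``bridge`` carries the intermediate to the final subject. The bridge is
    resampled to the baseline grid before summation.
    """
    bridge = resample_field(bridge, g_base.grid())
    out = sum_fields([g_base, bridge])
    out.tag = f"{g_base.tag}+{bridge.tag}"
    return out
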