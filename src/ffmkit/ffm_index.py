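"""The fossa-foveolar mismatch index and the per-case pipeline.

FFM index = (tracking-pattern area outside the fossa) / (total tracking
pattern area), measured in the standardized medial view.  ``run_case``
chains the full method: frame standardization -> the 17 motion protocols ->
per-branch impingement truncation -> footprint tracking -> one index per
protocol, with the total-ROM index computed on the union of every
admissible pose's footprint across all protocols.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .anatomy_frame import HipFrame, build_hip_frame
from .collision import DEFAULT_EXCLUDED_PAIRS, truncate_at_impingement
from .errors import DataError, FFMError, NumericalError
from .kinematics import (
    MotionProtocol,
    Pose,
    RomLimits,
    compose_rotation,
    default_protocols,
)
from .mesh_model import LabeledMesh
from .tracking import (
    TrackingPattern,
    characterize_fovea,
    fossa_region_2d,
    fovea_footprint,
    tracking_pattern,
)

logger = logging.getLogger("ffmkit")


@dataclass
class FFMResult:
    motion: str
    display_name: str
    index: float
    area_total: float
    area_inside: float
    area_outside: float
    n_poses: int
    n_poses_excluded: int

    def to_dict(self) -> dict:
        return {
            "motion": self.motion,
            "display_name": self.display_name,
            "ffm_index": self.index,
            "area_total_mm2": self.area_total,
            "area_inside_mm2": self.area_inside,
            "area_outside_mm2": self.area_outside,
            "n_poses": self.n_poses,
            "n_poses_excluded": self.n_poses_excluded,
        }


def compute_index(pattern: TrackingPattern) -> float:
    """area_outside / area_total; a zero denominator is an error, never a
    silent zero."""
    if pattern.area_total <= 0:
        raise NumericalError("tracking pattern area is zero: FFM index undefined")
    value = float(pattern.area_outside / pattern.area_total)
    if not -1e-9 <= value <= 1 + 1e-9:
        raise NumericalError(f"FFM index {value} outside [0, 1]: inconsistent areas")
    return min(max(value, 0.0), 1.0)  # clamp float round-off at the boundaries


@dataclass
class CaseReport:
    results: list[FFMResult]
    frame: HipFrame
    collision_summary: dict
    config: dict
    patterns: dict[str, TrackingPattern] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if len(self.results) != 17:
            raise DataError(f"case report must have exactly 17 rows, got {len(self.results)}")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_dict() for r in self.results])

    def index_by_motion(self) -> dict[str, float]:
        return {r.motion: r.index for r in self.results}

    def config_hash(self) -> str:
        blob = json.dumps(self.config, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def to_json_dict(self) -> dict:
        return {
            "results": [r.to_dict() for r in self.results],
            "frame": self.frame.to_dict(),
            "collision_summary": self.collision_summary,
            "config": self.config,
            "config_hash": self.config_hash(),
        }


def _neutral_pose() -> Pose:
    return Pose("neutral", 0, 0, (0.0, 0.0, 0.0), compose_rotation(0.0, 0.0, 0.0))


def run_case(
    pelvis: LabeledMesh,
    femur: LabeledMesh,
    rom: RomLimits | None = None,
    collision_tolerance: float = 0.0,
    backend: str = "polygon",
    raster_resolution: float = 0.1,
    max_sphere_rms: float = 1.5,
    n_circle_segments: int = 90,
    excluded_label_pairs=DEFAULT_EXCLUDED_PAIRS,
    protocols: list[MotionProtocol] | None = None,
) -> CaseReport:
    """Full FFM analysis of one labeled mesh pair; deterministic.

    Impingement truncation is per branch, neutral-outward.  A protocol whose
    branches are all truncated to nothing (possible only for impingement
    tests whose fixed starting pose already collides) falls back to the
    anatomical-neutral footprint so its pattern is never empty.
    """
    rom = rom or RomLimits()
    try:
        frame, pelvis_c, femur_c = build_hip_frame(pelvis, femur, max_sphere_rms)
    except FFMError as e:
        raise type(e)(f"[frame] {e}") from e
    try:
        fovea = characterize_fovea(femur_c, frame)
        fossa2d = fossa_region_2d(pelvis_c, frame)
    except FFMError as e:
        raise type(e)(f"[tracking] {e}") from e

    if protocols is None:
        protocols = default_protocols(rom)
    by_name = {p.name: p for p in protocols}
    if "total_rom" not in by_name or len(protocols) != 17:
        raise DataError("expected the 17 standard protocols including total_rom")

    admissible_cache: dict[tuple, Pose] = {}
    results: list[FFMResult] = []
    patterns: dict[str, TrackingPattern] = {}
    collision_info: dict[str, dict] = {}
    branch_cache: dict[tuple, tuple] = {}

    def truncated_branch(protocol: MotionProtocol, b_idx: int):
        br = protocol.branches[b_idx]
        key = (br.motion, br.direction, br.range_deg, br.fixed_flexion,
               br.fixed_abduction, br.fixed_rotation, br.step)
        if key not in branch_cache:
            from .kinematics import protocol_poses as _pp
            single = MotionProtocol(protocol.name, protocol.display_name, (br,))
            poses = _pp(single)
            try:
                kept, rep = truncate_at_impingement(
                    poses, pelvis_c, femur_c, collision_tolerance, excluded_label_pairs
                )
            except FFMError as e:
                raise type(e)(f"[collision] {e}") from e
            branch_cache[key] = (kept, rep)
        return branch_cache[key]

    for protocol in protocols:
        if protocol.is_union:
            continue
        kept_poses: list[Pose] = []
        n_total = 0
        n_excluded = 0
        seen: set[tuple] = set()
        for b_idx in range(len(protocol.branches)):
            kept, rep = truncated_branch(protocol, b_idx)
            branch_n = protocol.branches[b_idx].n_poses()
            n_total += branch_n
            n_excluded += branch_n - len(kept)
            for pose in kept:
                if pose.key() in seen:
                    n_total -= 1  # shared neutral counted once
                    n_excluded -= 0
                    continue
                seen.add(pose.key())
                kept_poses.append(pose)
        if not kept_poses:
            logger.warning(
                "protocol %s truncated to nothing; falling back to anatomical neutral",
                protocol.name,
            )
            kept_poses = [_neutral_pose()]
        for pose in kept_poses:
            admissible_cache.setdefault(pose.key(), pose)
        footprints = [
            fovea_footprint(femur_c, pose, frame, fovea, n_circle_segments)
            for pose in kept_poses
        ]
        try:
            pattern = tracking_pattern(
                footprints, fossa2d, raster_resolution, backend, protocol.name
            )
        except FFMError as e:
            raise type(e)(f"[tracking:{protocol.name}] {e}") from e
        idx = compute_index(pattern)
        results.append(
            FFMResult(
                motion=protocol.name,
                display_name=protocol.display_name,
                index=idx,
                area_total=pattern.area_total,
                area_inside=pattern.area_inside,
                area_outside=pattern.area_outside,
                n_poses=len(kept_poses),
                n_poses_excluded=n_excluded,
            )
        )
        patterns[protocol.name] = pattern
        collision_info[protocol.name] = {
            "n_poses_evaluated": len(kept_poses),
            "n_poses_excluded": n_excluded,
        }
        logger.info(
            "protocol %-40s poses=%2d excluded=%2d FFM=%.4f",
            protocol.name, len(kept_poses), n_excluded, idx,
        )

    # total ROM: union over every admissible pose of all other protocols
    total_protocol = by_name["total_rom"]
    union_poses = list(admissible_cache.values())
    footprints = [
        fovea_footprint(femur_c, pose, frame, fovea, n_circle_segments)
        for pose in union_poses
    ]
    pattern = tracking_pattern(footprints, fossa2d, raster_resolution, backend, "total_rom")
    idx = compute_index(pattern)
    total_result = FFMResult(
        motion="total_rom",
        display_name=total_protocol.display_name,
        index=idx,
        area_total=pattern.area_total,
        area_inside=pattern.area_inside,
        area_outside=pattern.area_outside,
        n_poses=len(union_poses),
        n_poses_excluded=0,
    )
    patterns["total_rom"] = pattern

    ordered: list[FFMResult] = []
    by_motion = {r.motion: r for r in results}
    by_motion["total_rom"] = total_result
    for p in protocols:
        ordered.append(by_motion[p.name])

    config = {
        "rom": rom.to_dict(),
        "collision_tolerance_mm": collision_tolerance,
        "backend": backend,
        "raster_resolution_mm": raster_resolution,
        "max_sphere_rms_mm": max_sphere_rms,
        "n_circle_segments": n_circle_segments,
    }
    return CaseReport(
        results=ordered,
        frame=frame,
        collision_summary=collision_info,
        config=config,
        patterns=patterns,
    )
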