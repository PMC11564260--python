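"""Hip motion protocols and their discrete 10-degree pose grids.

Canonical right-hip frame: +x anterior, +y medial, +z cranial; the hip
center is the rotation center.  Angle sign conventions (right hip):

* flexion  = rotation about -y (femur distal end moves anteriorly);
  extension is negative flexion,
* abduction = rotation about -x (distal end moves laterally);
  adduction is negative abduction,
* internal rotation = rotation about +z; external rotation is negative.

A pose's rotation is the intrinsic sequence flexion -> abduction -> axial
rotation, i.e. the matrix product Ry(-flex) Rx(-abd) Rz(rot).  The paper's
simulation software convention is unknown; this is a stated package
convention, and every downstream quantity uses it consistently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import ConfigError

STEP_DEG = 10.0


def compose_rotation(flexion: float, abduction: float, rotation: float) -> np.ndarray:
    """3x3 rotation matrix for the intrinsic flexion/abduction/axial sequence."""
    if not np.all(np.isfinite([flexion, abduction, rotation])):
        raise ConfigError("non-finite joint angle")
    return Rotation.from_euler(
        "YXZ", [-flexion, -abduction, rotation], degrees=True
    ).as_matrix()


@dataclass(frozen=True)
class RomLimits:
    """Physiological range-of-motion limits (degrees, all >= 0).

    Defaults are calibrated so the standard protocols reproduce the expected
    pose counts (15 poses for combined flexion/extension, 4 for the anterior
    impingement test); they are configuration, not measured population values.
    """

    flexion: float = 120.0
    extension: float = 20.0
    abduction: float = 50.0
    adduction: float = 30.0
    internal_rotation: float = 30.0
    external_rotation: float = 40.0
    internal_rotation_flexed: float = 30.0  # at 90 deg flexion
    external_rotation_flexed: float = 40.0

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ConfigError(f"ROM limit {name} must be a finite value >= 0, got {v}")

    @classmethod
    def from_dict(cls, d: dict) -> "RomLimits":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown ROM limit name(s): {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})

    def to_dict(self) -> dict:
        return {k: float(getattr(self, k)) for k in self.__dataclass_fields__}


@dataclass(frozen=True)
class Branch:
    """One elementary sweep: a fixed pre-rotation plus a swept motion.

    ``motion`` selects which angle slot is swept ('flexion', 'abduction' or
    'rotation'), ``direction`` its sign, ``range_deg`` the amplitude from the
    branch's step 0 outward.
    """

    motion: str  # 'flexion' | 'abduction' | 'rotation'
    direction: float  # +1 or -1
    range_deg: float
    fixed_flexion: float = 0.0
    fixed_abduction: float = 0.0
    fixed_rotation: float = 0.0
    step: float = STEP_DEG

    def __post_init__(self) -> None:
        if self.motion not in ("flexion", "abduction", "rotation"):
            raise ConfigError(f"unknown elementary motion {self.motion!r}")
        if self.step <= 0:
            raise ConfigError("step must be > 0")
        if self.range_deg < 0:
            raise ConfigError("branch range must be >= 0")

    def n_poses(self) -> int:
        return int(np.floor(self.range_deg / self.step + 1e-9)) + 1

    def angles(self, k: int) -> tuple[float, float, float]:
        """(flexion, abduction, rotation) angle triple at step ``k``."""
        sweep = self.direction * self.step * k
        f, a, r = self.fixed_flexion, self.fixed_abduction, self.fixed_rotation
        if self.motion == "flexion":
            f += sweep
        elif self.motion == "abduction":
            a += sweep
        else:
            r += sweep
        return (f, a, r)


@dataclass(frozen=True)
class MotionProtocol:
    """A named motion and its branch decomposition.

    Combined protocols (e.g. flexion/extension) hold both branches; the
    total-ROM protocol is flagged ``is_union`` and carries every branch of
    every other protocol — it is not a new sweep.
    """

    name: str
    display_name: str
    branches: tuple[Branch, ...]
    is_union: bool = False


@dataclass(frozen=True)
class Pose:
    protocol: str
    branch: int
    step_index: int
    angles: tuple[float, float, float]  # (flexion, abduction, rotation) deg
    rotation: np.ndarray = field(repr=False, compare=False, default=None)

    def key(self) -> tuple:
        """Deduplication key: the angle triple rounded to micro-degrees."""
        return tuple(round(a, 6) for a in self.angles)


def protocol_poses(protocol: MotionProtocol) -> list[Pose]:
    """Ordered pose grid, neutral-outward per branch; branches sharing the
    same step-0 pose contribute it once."""
    poses: list[Pose] = []
    seen_step0: set[tuple] = set()
    for b_idx, br in enumerate(protocol.branches):
        for k in range(br.n_poses()):
            ang = br.angles(k)
            pose = Pose(protocol.name, b_idx, k, ang, compose_rotation(*ang))
            if k == 0:
                if pose.key() in seen_step0:
                    continue
                seen_step0.add(pose.key())
            poses.append(pose)
    if protocol.is_union:
        unique: dict[tuple, Pose] = {}
        for p in poses:
            unique.setdefault(p.key(), p)
        poses = list(unique.values())
    return poses


PROTOCOL_ORDER = [
    ("flexion_extension", "Flex-/extension index"),
    ("flexion", "Flexion index"),
    ("extension", "Extension index"),
    ("abduction_adduction", "Ab-/adduction index"),
    ("abduction", "Abduction index"),
    ("adduction", "Adduction index"),
    ("internal_external_rotation", "Int-/external rotation index"),
    ("internal_rotation", "Internal rotation index"),
    ("external_rotation", "External rotation index"),
    ("flexed_90_internal_external_rotation", "90° flexion + int-/external rotation index"),
    ("flexed_90_internal_rotation", "90° flexion + internal rotation index"),
    ("flexed_90_external_rotation", "90° flexion + external rotation index"),
    ("anterior_impingement_test", "Anterior impingement test index"),
    ("posterior_impingement_test", "Posterior impingement test index"),
    ("static_30_internal_rotation", "30° internal rotation index"),
    ("static_30_external_rotation", "30° external rotation index"),
    ("total_rom", "Total ROM index"),
]


def default_protocols(rom: RomLimits | None = None, step: float = STEP_DEG) -> list[MotionProtocol]:
    """The 17 standard motion protocols within ``rom``.

    Six elementary sweeps, three combined pairs, IR/ER at 90 deg flexion
    (single and combined), the anterior (90 flexion + 10 adduction + IR
    sweep) and posterior (10 extension + ER sweep) impingement tests, two
    static 30-degree rotation positions, and the total-ROM union.
    """
    rom = rom or RomLimits()
    flex = Branch("flexion", +1, rom.flexion, step=step)
    ext = Branch("flexion", -1, rom.extension, step=step)
    abd = Branch("abduction", +1, rom.abduction, step=step)
    add = Branch("abduction", -1, rom.adduction, step=step)
    ir = Branch("rotation", +1, rom.internal_rotation, step=step)
    er = Branch("rotation", -1, rom.external_rotation, step=step)
    ir90 = Branch("rotation", +1, rom.internal_rotation_flexed, fixed_flexion=90.0, step=step)
    er90 = Branch("rotation", -1, rom.external_rotation_flexed, fixed_flexion=90.0, step=step)
    ant = Branch(
        "rotation", +1, rom.internal_rotation_flexed,
        fixed_flexion=90.0, fixed_abduction=-10.0, step=step,
    )
    post = Branch("rotation", -1, rom.external_rotation, fixed_flexion=-10.0, step=step)
    ir30 = Branch("rotation", +1, 0.0, fixed_rotation=30.0, step=step)
    er30 = Branch("rotation", -1, 0.0, fixed_rotation=-30.0, step=step)

    named = {
        "flexion_extension": (flex, ext),
        "flexion": (flex,),
        "extension": (ext,),
        "abduction_adduction": (abd, add),
        "abduction": (abd,),
        "adduction": (add,),
        "internal_external_rotation": (ir, er),
        "internal_rotation": (ir,),
        "external_rotation": (er,),
        "flexed_90_internal_external_rotation": (ir90, er90),
        "flexed_90_internal_rotation": (ir90,),
        "flexed_90_external_rotation": (er90,),
        "anterior_impingement_test": (ant,),
        "posterior_impingement_test": (post,),
        "static_30_internal_rotation": (ir30,),
        "static_30_external_rotation": (er30,),
    }
    protocols = []
    all_branches: list[Branch] = []
    for name, display in PROTOCOL_ORDER:
        if name == "total_rom":
            protocols.append(
                MotionProtocol(name, display, tuple(all_branches), is_union=True)
            )
            continue
        branches = named[name]
        for b in branches:
            if b not in all_branches:
                all_branches.append(b)
        protocols.append(MotionProtocol(name, display, branches))
    return protocols


def protocols_by_name(rom: RomLimits | None = None) -> dict[str, MotionProtocol]:
    return {p.name: p for p in default_protocols(rom)}
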