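"""Deterministic synthetic two-class images with exact ground truth.

The generator rasterizes bright foreground primitives (disks, axis-aligned
boxes) on a darker background, then adds i.i.d. Gaussian gray-level noise
and quantizes back to integer levels. The noiseless class assignment is the
ground-truth mask, so misclassification error can be measured exactly. The
scenes emulate the structure the thresholding model assumes — two
populations with distinct mean gray levels plus noise — and are the test
bed standing in for benchmark photographs that cannot be redistributed.

Default study conditions: a 120-level contrast (background 60, foreground
180) with noise sigma 10, i.e. well-separated classes; the "low-contrast"
and "small-objects" presets probe harder regimes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Union

import numpy as np

from ._util import DEFAULT_LEVELS, quantize
from .exceptions import ParameterError

__all__ = ["Disk", "Box", "SceneSpec", "generate_scene", "generate_suite", "random_layout", "PRESETS"]


@dataclass(frozen=True)
class Disk:
    """Filled disk; a pixel belongs to it when its centre lies within radius."""

    row: float
    col: float
    radius: float


@dataclass(frozen=True)
class Box:
    """Filled axis-aligned rectangle covering rows [top, top+height) and
    columns [left, left+width)."""

    top: int
    left: int
    height: int
    width: int


Primitive = Union[Disk, Box]


@dataclass(frozen=True)
class SceneSpec:
    """Full description of one synthetic scene; the seed fixes the noise."""

    shape: tuple[int, int] = (64, 64)
    bg_level: int = 60
    fg_level: int = 180
    noise_sigma: float = 10.0
    objects: tuple[Primitive, ...] = field(default_factory=tuple)
    seed: int = 0
    levels: int = DEFAULT_LEVELS

    def __post_init__(self) -> None:
        L = self.levels
        for name, v in (("bg_level", self.bg_level), ("fg_level", self.fg_level)):
            if not (0 <= v <= L - 1):
                raise ParameterError(f"{name} must lie in [0, {L - 1}], got {v}")
        if self.bg_level == self.fg_level:
            raise ParameterError("bg_level and fg_level must differ")
        if self.noise_sigma < 0:
            raise ParameterError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if min(self.shape) < 1:
            raise ParameterError(f"shape must be at least 1x1, got {self.shape}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["objects"] = [
            {"kind": type(o).__name__.lower(), **dataclasses.asdict(o)}
            for o in self.objects
        ]
        return d


def _rasterize(spec: SceneSpec) -> np.ndarray:
    mask = np.zeros(spec.shape, dtype=bool)
    rr, cc = np.mgrid[0 : spec.shape[0], 0 : spec.shape[1]]
    for obj in spec.objects:
        if isinstance(obj, Disk):
            mask |= (rr - obj.row) ** 2 + (cc - obj.col) ** 2 <= obj.radius**2
        elif isinstance(obj, Box):
            mask[obj.top : obj.top + obj.height, obj.left : obj.left + obj.width] = True
        else:
            raise ParameterError(f"unknown primitive {obj!r}")
    return mask


def generate_scene(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render a scene: returns (gray image, ground-truth foreground mask).

    The image is the per-class mean gray level plus N(0, noise_sigma^2)
    noise, rounded half-up and clipped to [0, levels-1]. Identical specs
    (including seed) produce bit-identical images.
    """
    mask = _rasterize(spec)
    clean = np.where(mask, float(spec.fg_level), float(spec.bg_level))
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        clean = clean + rng.normal(0.0, spec.noise_sigma, size=spec.shape)
    return quantize(clean, spec.levels), mask


def random_layout(seed: int, shape: tuple[int, int], small: bool = False) -> tuple[Primitive, ...]:
    """Seed-dependent object layout: a few disks and one box, kept inside
    the frame so every scene contains both classes."""
    rng = np.random.default_rng(seed + 7919)  # layout stream separate from noise
    M, N = shape
    objects: list[Primitive] = []
    n_disks = int(rng.integers(2, 4))
    lo, hi = (2.5, 4.5) if small else (M / 10, M / 5)
    for _ in range(n_disks):
        radius = float(rng.uniform(lo, hi))
        row = float(rng.uniform(radius + 1, M - radius - 2))
        col = float(rng.uniform(radius + 1, N - radius - 2))
        objects.append(Disk(row=row, col=col, radius=radius))
    if not small:
        h = int(rng.integers(M // 8, M // 4))
        w = int(rng.integers(N // 8, N // 4))
        objects.append(
            Box(
                top=int(rng.integers(1, M - h - 1)),
                left=int(rng.integers(1, N - w - 1)),
                height=h,
                width=w,
            )
        )
    return tuple(objects)


def _preset_specs(name: str) -> list[SceneSpec]:
    shape = (64, 64)
    if name == "clean":
        return [
            SceneSpec(shape=shape, bg_level=60, fg_level=180, noise_sigma=0.0,
                      objects=random_layout(k, shape), seed=k)
            for k in range(5)
        ]
    if name == "noisy":
        return [
            SceneSpec(shape=shape, bg_level=60, fg_level=180, noise_sigma=10.0,
                      objects=random_layout(k, shape), seed=k)
            for k in range(10)
        ]
    if name == "small-objects":
        return [
            SceneSpec(shape=shape, bg_level=60, fg_level=180, noise_sigma=5.0,
                      objects=random_layout(k, shape, small=True), seed=k)
            for k in range(5)
        ]
    if name == "low-contrast":
        return [
            SceneSpec(shape=shape, bg_level=100, fg_level=140, noise_sigma=5.0,
                      objects=random_layout(k, shape), seed=k)
            for k in range(5)
        ]
    raise ParameterError(
        f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
    )


PRESETS = ("clean", "noisy", "small-objects", "low-contrast")


def generate_suite(preset: str) -> list[tuple[np.ndarray, np.ndarray, SceneSpec]]:
    """Fixed seeded collection of (image, mask, spec) triples for a preset."""
    out = []
    for spec in _preset_specs(preset):
        image, mask = generate_scene(spec)
        out.append((image, mask, spec))
    return out
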