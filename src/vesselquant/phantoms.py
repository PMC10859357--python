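"""Synthetic phantoms with analytically known tumor-vessel wrap angles.

A phantom is a 3D label volume containing cylindrical "vessels" and, per
vessel, a tumor shell rasterised as an annular sector subtending exactly
theta degrees around the vessel axis and abutting the vessel surface.
Because the wrap angle is known by construction, phantoms validate the
involvement quantifier and the staging rules end to end without any
clinical data.

Geometry choices
----------------
Vessels run the full length of the volume along their grid axis while the
tumor wrap covers a limited band of slices (default 20).  The long vessel
matters: on longitudinal (near-tangent) planes a short vessel co-extensive
with its wrap would present thin sliver cross-sections whose boundary is
tumor-adjacent along an entire long edge, reading close to 180 degrees
regardless of the true wrap; a full-length vessel dilutes those planes so
the transverse planes, which measure the true angle, dominate the maximum.

The default geometry (96^3 voxels at 0.5 mm isotropic, vessel radius 5 mm,
shell 3 mm, 20-slice wrap) is comparable to the superior mesenteric artery
caliber at CT-like resolution and quantifies in seconds.

Optional boundary jitter emulates segmentation noise: each boundary voxel
of each structure toggles membership (structure <-> background) with a
fixed probability, driven by a seeded generator so identical specs and
seeds yield voxel-identical volumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .involvement import bin_degree, report_from_degrees
from .staging import RuleSet, Stage, classify_stage, default_ruleset
from .volume_io import VESSELS, LabelMap, LabelVolume, save_label_volume

__all__ = [
    "DEFAULT_LABELS",
    "VesselSpec",
    "WrapSpec",
    "PhantomSpec",
    "PhantomTruth",
    "PhantomSpecError",
    "make_wrap_phantom",
    "make_multi_vessel_phantom",
    "make_curved_vessel_phantom",
    "write_phantom",
]

#: Default label assignment for phantoms.
DEFAULT_LABELS = {"tumor": 1, "CeTr": 2, "HA": 3, "SMA": 4, "SMV": 5, "PV": 6}


class PhantomSpecError(ValueError):
    """The phantom specification is geometrically invalid."""


@dataclass(frozen=True)
class VesselSpec:
    """One tubular vessel.

    ``center`` gives the in-plane position (voxel units) on the two axes
    orthogonal to ``axis``, in ascending axis order.  A helical vessel
    winds around that center with ``helix_amplitude_mm`` radius, advancing
    ``helix_turn_deg_per_mm`` degrees per mm along the axis, except over
    the straight wrap band where the centerline is frozen so the wrap
    angle stays analytic.
    """

    name: str
    radius_mm: float
    center: tuple[float, float]
    axis: int = 2
    kind: str = "straight"  # "straight" | "helical"
    helix_amplitude_mm: float = 0.0
    helix_turn_deg_per_mm: float = 0.0
    helix_phase_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise PhantomSpecError("vessel radius must be positive")
        if self.kind not in ("straight", "helical"):
            raise PhantomSpecError(f"unknown vessel kind: {self.kind!r}")
        if self.axis not in (0, 1, 2):
            raise PhantomSpecError("axis must be 0, 1 or 2")


@dataclass(frozen=True)
class WrapSpec:
    """Tumor wrap around one vessel: an annular sector shell.

    ``start_deg`` is measured from the first in-plane axis toward the
    second.  The default (``None``) centers the sector on the in-plane
    225-degree diagonal, i.e. general position with respect to the grid:
    a sector edge exactly tangent-aligned with a grid axis is a degenerate
    configuration in which a longitudinal tangent plane reads
    ``extent/(2L)*360`` degrees regardless of the true wrap.
    """

    theta_deg: float
    start_deg: float | None = None
    shell_mm: float = 3.0
    extent_slices: int = 20
    center_slice: int | None = None  # defaults to the volume middle

    def __post_init__(self) -> None:
        if not 0 <= self.theta_deg <= 360:
            raise PhantomSpecError("wrap angle must lie in [0, 360]")
        if self.shell_mm <= 0:
            raise PhantomSpecError("shell thickness must be positive")
        if self.extent_slices <= 0:
            raise PhantomSpecError("wrap extent must be positive")

    @property
    def resolved_start_deg(self) -> float:
        if self.start_deg is not None:
            return float(self.start_deg)
        return (225.0 - self.theta_deg / 2.0) % 360.0


@dataclass(frozen=True)
class PhantomSpec:
    """Full phantom description."""

    shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    vessels: tuple[VesselSpec, ...] = ()
    wraps: Mapping[str, WrapSpec] = field(default_factory=dict)
    labels: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_LABELS))
    jitter_prob: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.jitter_prob < 1:
            raise PhantomSpecError("jitter_prob must lie in [0, 1)")
        names = [v.name for v in self.vessels]
        if len(set(names)) != len(names):
            raise PhantomSpecError("duplicate vessel names")
        for name in self.wraps:
            if name not in names:
                raise PhantomSpecError(f"wrap refers to unknown vessel {name!r}")


@dataclass(frozen=True)
class PhantomTruth:
    """Analytic ground truth of a phantom.

    Categories and the expected case stage are recomputed from the exact
    wrap angles through the public binning and staging operations, never
    stored independently.
    """

    wrap_angles: Mapping[str, float]  # all five staging vessels; 0 if absent
    categories: Mapping[str, str]
    expected_stage: Stage

    @classmethod
    def from_angles(
        cls, angles: Mapping[str, float], rules: RuleSet | None = None
    ) -> "PhantomTruth":
        full = {v: float(angles.get(v, 0.0)) for v in VESSELS}
        cats = {v: bin_degree(full[v]) for v in VESSELS}
        stage = classify_stage(report_from_degrees(full), rules or default_ruleset()).stage
        return cls(wrap_angles=full, categories=cats, expected_stage=stage)


def _inplane_grids(shape, spacing, axis):
    """Physical (mm) coordinate grids of the two in-plane axes."""
    others = [a for a in range(3) if a != axis]
    n0, n1 = shape[others[0]], shape[others[1]]
    s0, s1 = spacing[others[0]], spacing[others[1]]
    g0, g1 = np.mgrid[0:n0, 0:n1]
    return g0 * s0, g1 * s1, others


def _centerline_mm(vessel: VesselSpec, spec: PhantomSpec, wrap: WrapSpec | None):
    """Per-slice in-plane centerline (mm) along the vessel axis."""
    n_axis = spec.shape[vessel.axis]
    s_axis = spec.spacing[vessel.axis]
    others = [a for a in range(3) if a != vessel.axis]
    c0 = vessel.center[0] * spec.spacing[others[0]]
    c1 = vessel.center[1] * spec.spacing[others[1]]
    if vessel.kind == "straight":
        return np.full(n_axis, c0), np.full(n_axis, c1)
    lo, hi = _band(spec, wrap, vessel.axis) if wrap is not None else (n_axis // 2, n_axis // 2)
    z = np.arange(n_axis, dtype=float)
    # phase advances with distance outside the straight band, frozen inside
    dist = np.where(z < lo, z - lo, np.where(z >= hi, z - (hi - 1), 0.0)) * s_axis
    phi = np.radians(vessel.helix_phase_deg + vessel.helix_turn_deg_per_mm * dist)
    a = vessel.helix_amplitude_mm
    return c0 + a * np.cos(phi), c1 + a * np.sin(phi)


def _band(spec: PhantomSpec, wrap: WrapSpec, axis: int) -> tuple[int, int]:
    n_axis = spec.shape[axis]
    center = wrap.center_slice if wrap.center_slice is not None else n_axis // 2
    lo = max(0, center - wrap.extent_slices // 2)
    return lo, min(n_axis, lo + wrap.extent_slices)


def make_wrap_phantom(spec: PhantomSpec) -> tuple[LabelVolume, PhantomTruth]:
    """Rasterise a phantom and return it with its analytic truth.

    Each vessel is a tube of its radius; each tumor wrap is an annular
    sector shell from the vessel surface outward, subtending exactly
    ``theta_deg`` starting at ``start_deg`` (measured from the first
    in-plane axis toward the second).  Tumor abuts the vessel surface with
    no overlap and no gap beyond rasterisation.  Raises
    :class:`PhantomSpecError` if structures intersect or a vessel exits
    the lateral bounds.
    """
    vox = np.zeros(spec.shape, dtype=np.int16)
    tumor_label = spec.labels["tumor"]
    for vessel in spec.vessels:
        label = spec.labels[vessel.name]
        wrap = spec.wraps.get(vessel.name)
        g0, g1, others = _inplane_grids(spec.shape, spec.spacing, vessel.axis)
        c0s, c1s = _centerline_mm(vessel, spec, wrap)
        n_axis = spec.shape[vessel.axis]
        band = _band(spec, wrap, vessel.axis) if wrap is not None else None
        for k in range(n_axis):
            d = np.hypot(g0 - c0s[k], g1 - c1s[k])
            vmask = d <= vessel.radius_mm
            if (
                vmask[0, :].any()
                or vmask[-1, :].any()
                or vmask[:, 0].any()
                or vmask[:, -1].any()
            ):
                raise PhantomSpecError(f"vessel {vessel.name!r} exits the lateral bounds")
            sl = [slice(None)] * 3
            sl[vessel.axis] = k
            plane = vox[tuple(sl)]
            if (plane[vmask] != 0).any():
                raise PhantomSpecError(f"vessel {vessel.name!r} intersects another structure")
            plane[vmask] = label
            if wrap is not None and wrap.theta_deg > 0 and band[0] <= k < band[1]:
                ang = np.degrees(np.arctan2(g1 - c1s[k], g0 - c0s[k])) % 360.0
                off = (ang - wrap.resolved_start_deg) % 360.0
                tmask = (
                    (d > vessel.radius_mm)
                    & (d <= vessel.radius_mm + wrap.shell_mm)
                    & (off <= wrap.theta_deg)
                )
                clash = tmask & (plane != 0) & (plane != tumor_label)
                if clash.any():
                    raise PhantomSpecError(
                        f"tumor wrap of {vessel.name!r} intersects another structure"
                    )
                plane[tmask] = tumor_label
    if spec.jitter_prob > 0:
        vox = _apply_jitter(vox, spec.jitter_prob, spec.seed)
    volume = LabelVolume(voxels=vox, spacing=spec.spacing, label_map=LabelMap(spec.labels))
    angles = {v.name: spec.wraps[v.name].theta_deg for v in spec.vessels if v.name in spec.wraps}
    return volume, PhantomTruth.from_angles(angles)


def _apply_jitter(vox: np.ndarray, prob: float, seed: int | None) -> np.ndarray:
    """Seeded single-voxel boundary jitter, structure <-> background only."""
    rng = np.random.default_rng(0 if seed is None else seed)
    struct = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    out = vox.copy()
    labels = sorted(int(v) for v in np.unique(vox) if v != 0)
    original_bg = vox == 0
    for label in labels:
        mask = vox == label
        boundary = mask & ~ndimage.binary_erosion(mask, structure=struct)
        drop = boundary & (rng.random(vox.shape) < prob)
        grow = (
            ndimage.binary_dilation(mask, structure=struct)
            & original_bg
            & (out == 0)
            & (rng.random(vox.shape) < prob)
        )
        out[drop] = 0
        out[grow] = label
    return out


#: Standard in-plane centers (voxel units on a 96x96 cross-section) for the
#: five vessels in a multi-vessel phantom; pairwise distances keep each
#: tumor shell clear of every other vessel.
_MULTI_CENTERS = {
    "CeTr": (24.0, 24.0),
    "HA": (24.0, 72.0),
    "SMA": (72.0, 24.0),
    "SMV": (72.0, 72.0),
    "PV": (48.0, 48.0),
}


def make_multi_vessel_phantom(
    wraps: Mapping[str, float],
    *,
    shape: tuple[int, int, int] = (96, 96, 96),
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5),
    radius_mm: float = 5.0,
    shell_mm: float = 3.0,
    extent_slices: int = 20,
    start_deg: Mapping[str, float] | None = None,
    jitter_prob: float = 0.0,
    seed: int | None = None,
) -> tuple[LabelVolume, PhantomTruth]:
    """One volume with all five staging vessels at disjoint locations.

    ``wraps`` maps vessel names to wrap angles in degrees (vessels left
    out get no tumor).  The truth includes the expected case stage under
    the default rule table.
    """
    scale = np.array(shape[:2]) / 96.0
    vessels = tuple(
        VesselSpec(
            name=name,
            radius_mm=radius_mm,
            center=(c[0] * scale[0], c[1] * scale[1]),
        )
        for name, c in _MULTI_CENTERS.items()
    )
    wrap_specs = {
        name: WrapSpec(
            theta_deg=float(theta),
            start_deg=(start_deg or {}).get(name),
            shell_mm=shell_mm,
            extent_slices=extent_slices,
        )
        for name, theta in wraps.items()
        if theta > 0
    }
    spec = PhantomSpec(
        shape=shape,
        spacing=spacing,
        vessels=vessels,
        wraps=wrap_specs,
        jitter_prob=jitter_prob,
        seed=seed,
    )
    volume, _ = make_wrap_phantom(spec)
    truth = PhantomTruth.from_angles({k: float(v) for k, v in wraps.items()})
    return volume, truth


def make_curved_vessel_phantom(
    theta_deg: float,
    *,
    vessel_name: str = "SMA",
    shape: tuple[int, int, int] = (96, 96, 96),
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5),
    radius_mm: float = 5.0,
    shell_mm: float = 3.0,
    extent_slices: int = 20,
    helix_amplitude_mm: float = 4.0,
    helix_turn_deg_per_mm: float = 8.0,
    start_deg: float | None = None,
    jitter_prob: float = 0.0,
    seed: int | None = None,
) -> tuple[LabelVolume, PhantomTruth]:
    """A helically curved vessel with the wrap on its straight mid-band.

    The centerline winds around the volume center except over the wrap
    band, where it is frozen so the wrap angle remains analytic; truth
    applies to that straight sub-segment.
    """
    vessel = VesselSpec(
        name=vessel_name,
        radius_mm=radius_mm,
        center=(shape[0] / 2.0, shape[1] / 2.0),
        kind="helical",
        helix_amplitude_mm=helix_amplitude_mm,
        helix_turn_deg_per_mm=helix_turn_deg_per_mm,
    )
    wraps = (
        {vessel_name: WrapSpec(theta_deg=theta_deg, start_deg=start_deg,
                               shell_mm=shell_mm, extent_slices=extent_slices)}
        if theta_deg > 0
        else {}
    )
    spec = PhantomSpec(
        shape=shape,
        spacing=spacing,
        vessels=(vessel,),
        wraps=wraps,
        jitter_prob=jitter_prob,
        seed=seed,
    )
    volume, _ = make_wrap_phantom(spec)
    return volume, PhantomTruth.from_angles({vessel_name: theta_deg})


def write_phantom(
    volume: LabelVolume, truth: PhantomTruth, outdir: str | Path, stem: str = "phantom"
) -> dict[str, Path]:
    """Write volume (NIfTI), truth sidecar (JSON) and label map (YAML)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "volume": outdir / f"{stem}.nii.gz",
        "truth": outdir / f"{stem}_truth.json",
        "labels": outdir / f"{stem}_labels.yaml",
    }
    save_label_volume(volume, paths["volume"])
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "wrap_angles_deg": dict(truth.wrap_angles),
                "categories": dict(truth.categories),
                "expected_stage": truth.expected_stage.label,
            },
            fh,
            indent=2,
            ensure_ascii=False,
        )
    volume.label_map.to_yaml(paths["labels"])
    return paths
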