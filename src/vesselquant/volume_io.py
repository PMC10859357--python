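"""Reading, validating and slicing 3D multi-label segmentation volumes.

A segmentation of a pancreatic-cancer CT is stored as a NIfTI label volume:
each voxel carries an integer code identifying the structure occupying it
(0 = background).  The label map names at least the primary tumor and the
five vessels that determine resectability: celiac trunk (CeTr), hepatic
artery (HA), superior mesenteric artery (SMA), superior mesenteric vein
(SMV) and portal vein (PV).

The voxel grid is used exactly as stored; no reorientation to anatomical
axes is performed.  Slice indices are 0-based throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import nibabel as nib
import numpy as np
import yaml

__all__ = [
    "REQUIRED_STRUCTURES",
    "VESSELS",
    "LabelMap",
    "LabelVolume",
    "LabelPlane",
    "VolumeFormatError",
    "LabelConsistencyError",
    "load_label_volume",
    "save_label_volume",
    "extract_plane",
    "planes_containing",
]

#: Structure names every label map must declare.
REQUIRED_STRUCTURES = ("tumor", "CeTr", "HA", "SMA", "SMV", "PV")

#: The five staging-relevant vessels, in reporting order.
VESSELS = ("CeTr", "HA", "SMA", "SMV", "PV")


class VolumeFormatError(ValueError):
    """The file on disk is not an integer-valued label volume."""


class LabelConsistencyError(ValueError):
    """A voxel value in the volume is not declared in the label map."""


@dataclass(frozen=True)
class LabelMap:
    """Mapping from structure name to positive integer label value.

    Parameters
    ----------
    entries
        Name -> label value.  Must contain all of
        :data:`REQUIRED_STRUCTURES`; values must be unique positive
        integers.  Additional structures (pancreas, aorta, ...) are
        allowed and ignored by the quantifier.
    """

    entries: Mapping[str, int]

    def __post_init__(self) -> None:
        vals = list(self.entries.values())
        if any((not isinstance(v, (int, np.integer))) or v <= 0 for v in vals):
            raise ValueError("label values must be positive integers")
        if len(set(vals)) != len(vals):
            raise ValueError("label values must be unique")
        missing = [n for n in REQUIRED_STRUCTURES if n not in self.entries]
        if missing:
            raise ValueError(f"label map is missing required structures: {missing}")
        object.__setattr__(self, "entries", dict(self.entries))

    def __getitem__(self, name: str) -> int:
        try:
            return self.entries[name]
        except KeyError:
            raise LabelConsistencyError(f"unknown structure name: {name!r}") from None

    def values(self) -> Sequence[int]:
        return list(self.entries.values())

    @classmethod
    def from_yaml(cls, path: str | Path) -> "LabelMap":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected a mapping of name -> label value")
        return cls(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dict(self.entries), fh, sort_keys=False)


@dataclass
class LabelVolume:
    """A 3D integer label grid with physical voxel spacing.

    Attributes
    ----------
    voxels
        3D array of non-negative integers; 0 is background.
    spacing
        Millimetres per voxel along each of the three grid axes.
    label_map
        Names for the nonzero values in ``voxels``.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    label_map: LabelMap

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise VolumeFormatError("voxels must have an integer dtype")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive values (mm)")
        present = np.unique(self.voxels)
        declared = set(self.label_map.values()) | {0}
        undeclared = [int(v) for v in present if int(v) not in declared]
        if undeclared:
            raise LabelConsistencyError(
                f"voxel values not declared in the label map: {undeclared}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def mask(self, name: str) -> np.ndarray:
        """Boolean mask of the named structure."""
        return self.voxels == self.label_map[name]


@dataclass(frozen=True)
class LabelPlane:
    """One 2D slice of a label volume.

    ``axis`` is the grid axis the slice is orthogonal to and ``index`` its
    0-based position along that axis.  ``in_plane_spacing`` holds the mm
    spacings of the two remaining axes in ascending axis order (axis 0 ->
    (s1, s2), axis 1 -> (s0, s2), axis 2 -> (s0, s1)).
    """

    pixels: np.ndarray
    in_plane_spacing: tuple[float, float]
    axis: int
    index: int


def load_label_volume(path: str | Path, label_map: LabelMap) -> LabelVolume:
    """Load a NIfTI label volume and validate it against a label map.

    The voxel grid is kept in the file's native axis order and the spacing
    is taken from the header (absolute per-axis zooms).  Values must be
    exactly representable as integers.

    Raises
    ------
    VolumeFormatError
        If the on-disk data is not integer-valued.
    LabelConsistencyError
        If a nonzero voxel value is absent from ``label_map``.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise VolumeFormatError(f"{path}: expected a 3D volume, got shape {data.shape}")
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.array_equal(rounded, data):
            raise VolumeFormatError(f"{path}: voxel values are not integers")
        data = rounded.astype(np.int32)
    spacing = tuple(abs(float(z)) for z in img.header.get_zooms()[:3])
    return LabelVolume(voxels=data, spacing=spacing, label_map=label_map)


def save_label_volume(volume: LabelVolume, path: str | Path) -> None:
    """Write a label volume as NIfTI with spacing encoded in the affine."""
    affine = np.diag(list(volume.spacing) + [1.0])
    img = nib.Nifti1Image(volume.voxels.astype(np.int16), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def _in_plane_spacing(spacing: Sequence[float], axis: int) -> tuple[float, float]:
    others = [spacing[a] for a in range(3) if a != axis]
    return (others[0], others[1])


def extract_plane(volume: LabelVolume, axis: int, index: int) -> LabelPlane:
    """Extract the 2D slice orthogonal to ``axis`` at ``index``."""
    if axis not in (0, 1, 2):
        raise ValueError(f"axis must be 0, 1 or 2, got {axis}")
    extent = volume.shape[axis]
    if not 0 <= index < extent:
        raise IndexError(f"index {index} out of range for axis {axis} (extent {extent})")
    pixels = np.take(volume.voxels, index, axis=axis)
    return LabelPlane(
        pixels=pixels,
        in_plane_spacing=_in_plane_spacing(volume.spacing, axis),
        axis=axis,
        index=index,
    )


def planes_containing(
    volume: LabelVolume, label_a: int, label_b: int
) -> list[tuple[int, int]]:
    """All (axis, index) slices containing both labels.

    Sweeps all three grid axes and returns every slice that holds at least
    one voxel of ``label_a`` and one of ``label_b``, in (axis, index)
    lexicographic order.
    """
    declared = set(volume.label_map.values())
    for lab in (label_a, label_b):
        if lab not in declared:
            raise LabelConsistencyError(f"label {lab} not declared in the label map")
    out: list[tuple[int, int]] = []
    a_mask = volume.voxels == label_a
    b_mask = volume.voxels == label_b
    for axis in range(3):
        other = tuple(a for a in range(3) if a != axis)
        has_a = a_mask.any(axis=other)
        has_b = b_mask.any(axis=other)
        out.extend((axis, int(i)) for i in np.nonzero(has_a & has_b)[0])
    return out


def iter_planes(volume: LabelVolume, pairs: Sequence[tuple[int, int]]) -> Iterator[LabelPlane]:
    """Yield the planes for a sequence of (axis, index) pairs."""
    for axis, index in pairs:
        yield extract_plane(volume, axis, index)
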