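"""Loading, validation and intensity normalization of tumour images.

A tumour is represented as an ordered stack of 2D grey-scale slices with a
binary region-of-interest (ROI) mask delineating the pathological
T2-hyperintense region on each slice, and an optional binary reference mask
of contralateral normal-appearing white matter used to normalize
signal-intensity statistics.

Supported on-disk formats are NIfTI (``.nii``/``.nii.gz``) volumes and
directories of plain-text 2D numeric matrices (one file per slice, sorted
lexicographically, with an optional ``spacing.json`` sidecar).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np


class DimensionError(ValueError):
    """Image and mask shapes disagree."""


class EmptyMaskError(ValueError):
    """A required mask contains no pixels."""


class DataError(ValueError):
    """Non-finite intensities or non-binary mask values."""


class ConfigurationError(ValueError):
    """A required input (e.g. reference mask or scalar) was not supplied."""


@dataclass(frozen=True)
class Spacing:
    """Pixel geometry in millimetres: in-plane size and slice pitch.

    ``slice_pitch`` is slice thickness plus inter-slice gap, i.e. the
    centre-to-centre distance of adjacent slices.
    """

    pixel_mm: float = 1.0
    slice_pitch_mm: float = 1.0


@dataclass
class TumourImage:
    """A multi-slice grey-scale tumour image with ROI (and reference) masks.

    Parameters
    ----------
    slices : list of 2D float arrays
        Grey-scale slices in acquisition order, arbitrary intensity units.
    roi : list of 2D bool arrays
        Per-slice mask of the pathological region; same shape as the slice.
    reference : list of 2D bool arrays, optional
        Mask of contralateral normal white matter (may be empty on most
        slices); used only for signal-intensity normalization.
    spacing : Spacing, optional
        Pixel geometry; affects only optional mm-unit conversions.
    tumour_id : str
        Opaque label for the tumour.
    label : str or None
        Optional outcome label (``"progression"`` / ``"pseudoprogression"``).
    """

    slices: list[np.ndarray]
    roi: list[np.ndarray]
    reference: list[np.ndarray] | None = None
    spacing: Spacing | None = None
    tumour_id: str = "tumour"
    label: str | None = None

    def __post_init__(self) -> None:
        self.slices = [np.asarray(s, dtype=float) for s in self.slices]
        self.roi = [np.asarray(m).astype(bool) for m in self.roi]
        if self.reference is not None:
            self.reference = [np.asarray(m).astype(bool) for m in self.reference]
        self._validate()

    def _validate(self) -> None:
        if len(self.slices) == 0:
            raise DataError("image has no slices")
        if len(self.roi) != len(self.slices):
            raise DimensionError(
                f"{len(self.slices)} slices but {len(self.roi)} ROI masks"
            )
        for j, (s, m) in enumerate(zip(self.slices, self.roi)):
            if s.ndim != 2:
                raise DimensionError(f"slice {j} is not 2D (shape {s.shape})")
            if s.shape != m.shape:
                raise DimensionError(
                    f"slice {j} shape {s.shape} != ROI mask shape {m.shape}"
                )
            if not np.all(np.isfinite(s)):
                raise DataError(f"slice {j} contains non-finite intensities")
            if np.any(s < 0):
                raise DataError(f"slice {j} contains negative intensities")
        if self.reference is not None:
            if len(self.reference) != len(self.slices):
                raise DimensionError("reference mask count != slice count")
            for j, (s, m) in enumerate(zip(self.slices, self.reference)):
                if s.shape != m.shape:
                    raise DimensionError(
                        f"slice {j} shape {s.shape} != reference mask {m.shape}"
                    )
        if self.n_roi_pixels == 0:
            raise EmptyMaskError("ROI mask is empty on every slice")

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    @property
    def n_roi_pixels(self) -> int:
        return int(sum(int(m.sum()) for m in self.roi))

    def roi_values(self) -> np.ndarray:
        """Raw intensities of all ROI pixels, pooled over slices."""
        return np.concatenate([s[m] for s, m in zip(self.slices, self.roi)])


@dataclass
class NormalizedROI:
    """ROI intensities after tumour-wide linear mapping onto [0, 1].

    The bounds ``lo``/``hi`` are the minimum and maximum raw intensity over
    all ROI pixels of all slices, so the grey-scale thresholds partition one
    tumour-wide intensity scale and per-slice counts are comparable.
    """

    values: list[np.ndarray]  # per-slice normalized intensities of ROI pixels
    masks: list[np.ndarray]  # per-slice ROI masks (bool)
    shapes: list[tuple[int, int]]
    lo: float
    hi: float
    n_pixels_per_slice: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.n_pixels_per_slice:
            self.n_pixels_per_slice = [int(m.sum()) for m in self.masks]

    @property
    def n_pixels_total(self) -> int:
        return int(sum(self.n_pixels_per_slice))

    def slice_grid(self, j: int) -> np.ndarray:
        """Normalized values embedded on the slice grid (NaN outside ROI)."""
        grid = np.full(self.shapes[j], np.nan)
        grid[self.masks[j]] = self.values[j]
        return grid


def normalize_roi(img: TumourImage) -> NormalizedROI:
    """Map ROI intensities linearly onto [0, 1] with one tumour-wide scale.

    ``lo`` and ``hi`` are the min and max over every ROI pixel of every
    slice.  A constant-intensity ROI maps to all ones, so the all-white
    convention at the lowest threshold still holds.
    """
    pooled = img.roi_values()
    if pooled.size == 0:
        raise EmptyMaskError("ROI mask is empty")
    lo, hi = float(pooled.min()), float(pooled.max())
    values = []
    for s, m in zip(img.slices, img.roi):
        raw = s[m]
        if hi == lo:
            values.append(np.ones_like(raw))
        else:
            values.append((raw - lo) / (hi - lo))
    return NormalizedROI(
        values=values,
        masks=[m.copy() for m in img.roi],
        shapes=[s.shape for s in img.slices],
        lo=lo,
        hi=hi,
    )


def reference_mean(img: TumourImage, scalar: float | None = None) -> float:
    """Mean raw intensity under the white-matter reference mask.

    An explicit ``scalar`` bypasses the mask (for images shipped without a
    contralateral reference region).
    """
    if scalar is not None:
        if scalar <= 0:
            raise ConfigurationError("explicit reference mean must be positive")
        return float(scalar)
    if img.reference is None:
        raise ConfigurationError(
            "no reference mask present; supply reference_path or an explicit "
            "reference scalar"
        )
    vals = np.concatenate([s[m] for s, m in zip(img.slices, img.reference)])
    if vals.size == 0:
        raise EmptyMaskError("reference mask is empty")
    return float(vals.mean())


def _require_binary(arr: np.ndarray, what: str) -> np.ndarray:
    uniq = np.unique(arr)
    if not np.all(np.isin(uniq, (0, 1))):
        raise DataError(f"{what} contains non-binary values {uniq[:8]}")
    return arr.astype(bool)


def _load_volume(path: Path) -> tuple[list[np.ndarray], Spacing | None]:
    """Read a NIfTI volume or a directory of text matrices as a slice list."""
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir()
            if p.suffix in {".txt", ".csv", ".tsv", ".dat"}
        )
        if not files:
            raise FileNotFoundError(f"no matrix files in {path}")
        slices = [np.loadtxt(f, delimiter="," if f.suffix == ".csv" else None)
                  for f in files]
        spacing = None
        sidecar = path / "spacing.json"
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            spacing = Spacing(
                pixel_mm=float(meta.get("pixel_mm", 1.0)),
                slice_pitch_mm=float(meta.get("slice_pitch_mm", 1.0)),
            )
        return [np.atleast_2d(s) for s in slices], spacing
    import nibabel as nib

    vol = nib.load(str(path))
    data = np.asanyarray(vol.dataobj)
    if data.ndim == 2:
        data = data[..., None]
    if data.ndim != 3:
        raise DimensionError(f"expected 2D/3D volume, got shape {data.shape}")
    zooms = vol.header.get_zooms()
    spacing = Spacing(pixel_mm=float(zooms[0]),
                      slice_pitch_mm=float(zooms[2]) if len(zooms) > 2 else 1.0)
    return [data[:, :, k] for k in range(data.shape[2])], spacing


def load_image(
    volume_path: str | Path,
    roi_path: str | Path,
    reference_path: str | Path | None = None,
    tumour_id: str | None = None,
    label: str | None = None,
) -> TumourImage:
    """Load a tumour volume plus masks and return a validated TumourImage.

    Raises
    ------
    DimensionError
        If mask and volume shapes disagree.
    DataError
        If a mask contains values other than {0, 1} or the volume has
        non-finite voxels.
    EmptyMaskError
        If the ROI is empty on every slice.
    """
    slices, spacing = _load_volume(Path(volume_path))
    roi_slices, _ = _load_volume(Path(roi_path))
    if len(roi_slices) != len(slices):
        raise DimensionError(
            f"volume has {len(slices)} slices, ROI has {len(roi_slices)}"
        )
    roi = [_require_binary(m, f"ROI slice {j}") for j, m in enumerate(roi_slices)]
    reference = None
    if reference_path is not None:
        ref_slices, _ = _load_volume(Path(reference_path))
        if len(ref_slices) != len(slices):
            raise DimensionError("reference mask slice count != volume")
        reference = [
            _require_binary(m, f"reference slice {j}")
            for j, m in enumerate(ref_slices)
        ]
    return TumourImage(
        slices=slices,
        roi=roi,
        reference=reference,
        spacing=spacing,
        tumour_id=tumour_id or Path(volume_path).stem.replace(".nii", ""),
        label=label,
    )


def save_image(img: TumourImage, out_dir: str | Path) -> dict[str, str]:
    """Write a TumourImage as text matrices (volume/, roi/, reference/).

    Returns the paths written, keyed by role.  The inverse of
    :func:`load_image` for the text-matrix format.
    """
    out_dir = Path(out_dir)
    paths: dict[str, str] = {}
    roles: list[tuple[str, Sequence[np.ndarray] | None, str]] = [
        ("volume", img.slices, "%.6g"),
        ("roi", img.roi, "%d"),
        ("reference", img.reference, "%d"),
    ]
    for role, arrs, fmt in roles:
        if arrs is None:
            continue
        d = out_dir / role
        d.mkdir(parents=True, exist_ok=True)
        for j, a in enumerate(arrs):
            np.savetxt(d / f"slice_{j:03d}.txt", np.asarray(a, dtype=float), fmt=fmt)
        if img.spacing is not None:
            (d / "spacing.json").write_text(json.dumps({
                "pixel_mm": img.spacing.pixel_mm,
                "slice_pitch_mm": img.spacing.slice_pitch_mm,
            }))
        paths[role] = str(d)
    return paths
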