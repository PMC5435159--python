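"""2D Minkowski functionals of thresholded tumour images.

Each grey-scale slice is binarized at a ladder of thresholds covering the
normalized intensity range.  A thresholded ("white") pixel set is treated as
a union of closed unit squares on the pixel lattice; counting its distinct
faces ``p``, edges ``e`` and vertices ``v`` gives the three 2D Minkowski
functionals:

* area        ``A = p``
* perimeter   ``U = -4p + 2e``  (black/white boundary length, edge units)
* genus       ``chi = p - e + v``  (Euler characteristic: number of
  connected white regions, counting diagonal contact, minus the number of
  completely enclosed black regions)

The threshold spectrum of these functionals, normalized by the total ROI
pixel count, parameterizes intra-tumour texture heterogeneity: the more
heterogeneous the region, the higher the normalized perimeter at
intermediate thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import NormalizedROI, TumourImage, normalize_roi, reference_mean

#: Canonical ordered names of the 38 per-tumour features.
FEATURE_NAMES: tuple[str, ...] = (
    tuple(f"nArea_{i}" for i in range(2, 12))
    + tuple(f"nPeri_{i}" for i in range(1, 12))
    + tuple(f"nGenus_{i}" for i in range(1, 12))
    + ("TotalArea", "TotalPerimeter", "SImean", "SIsd", "SImax", "SImin")
)

MF_FEATURES = FEATURE_NAMES[:32]
SIZE_FEATURES = ("TotalArea", "TotalPerimeter")
SI_FEATURES = ("SImean", "SIsd", "SImax", "SImin")


def threshold_sequence(n_levels: int = 11) -> np.ndarray:
    """Evenly spaced grey-scale thresholds ``t_i = (i-1)/n_levels``.

    The first threshold is 0, so every ROI pixel is white there; the last is
    ``(n_levels-1)/n_levels`` so the final binary image is generically
    non-empty.  The default of 11 gives ten equal steps through the
    normalized grey scale.
    """
    if n_levels < 2:
        raise ValueError(f"n_levels must be >= 2, got {n_levels}")
    return np.arange(n_levels) / n_levels


def binarize(norm: NormalizedROI, slice_index: int, t: float) -> np.ndarray:
    """Binary slice at threshold ``t``: white where normalized value >= t.

    Pixels outside the ROI are excluded entirely (neither black nor white);
    the returned array is True only on ROI pixels at or above threshold.
    A slice with no ROI pixels yields an all-False array, not an error.
    """
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {t}")
    grid = np.zeros(norm.shapes[slice_index], dtype=bool)
    mask = norm.masks[slice_index]
    grid[mask] = norm.values[slice_index] >= t
    return grid


def count_cells(white: np.ndarray) -> tuple[int, int, int]:
    """Count distinct faces, edges and vertices of a white pixel set.

    The white pixels' closed unit squares form a cell complex on the
    lattice; shared edges and vertices are counted once.  An empty image
    returns ``(0, 0, 0)``.
    """
    white = np.asarray(white).astype(bool)
    if white.ndim != 2:
        raise ValueError("expected a 2D binary array")
    p = int(white.sum())
    if p == 0:
        return 0, 0, 0
    h, w = white.shape
    # Lattice points (h+1, w+1): a vertex is present iff any of the up-to-4
    # incident pixels is white; edges likewise from their 1-2 incident pixels.
    vert = np.zeros((h + 1, w + 1), dtype=bool)
    vert[:-1, :-1] |= white
    vert[:-1, 1:] |= white
    vert[1:, :-1] |= white
    vert[1:, 1:] |= white
    # Horizontal edges: (h+1) rows of w edges.
    horiz = np.zeros((h + 1, w), dtype=bool)
    horiz[:-1, :] |= white  # top edge of each pixel
    horiz[1:, :] |= white   # bottom edge
    # Vertical edges: h rows of (w+1) edges.
    vertical = np.zeros((h, w + 1), dtype=bool)
    vertical[:, :-1] |= white  # left edge
    vertical[:, 1:] |= white   # right edge
    e = int(horiz.sum()) + int(vertical.sum())
    v = int(vert.sum())
    return p, e, v


def minkowski_2d(p: int, e: int, v: int) -> tuple[int, int, int]:
    """Area, perimeter and genus from face/edge/vertex counts.

    ``A = p``; ``U = -4p + 2e`` is the black/white boundary length in
    pixel-edge units; ``chi = p - e + v`` equals white components (with
    diagonal contact counted as connected) minus enclosed black regions.
    """
    return p, -4 * p + 2 * e, p - e + v


@dataclass
class MFSpectrum:
    """Per-threshold normalized Minkowski functionals for one tumour.

    ``narea`` holds thresholds 2..11 only: at threshold 1 all ROI pixels are
    white so the normalized area is identically 1 and carries no
    information.  All values are normalized by ``n_pixels_total``, the ROI
    pixel count of the whole tumour.
    """

    thresholds: np.ndarray
    n_pixels_total: int
    narea: np.ndarray   # thresholds 2..n
    nperi: np.ndarray   # thresholds 1..n
    ngenus: np.ndarray  # thresholds 1..n
    counts: list[tuple[int, int, int]] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for i, val in enumerate(self.narea, start=2):
            out[f"nArea_{i}"] = float(val)
        for i, val in enumerate(self.nperi, start=1):
            out[f"nPeri_{i}"] = float(val)
        for i, val in enumerate(self.ngenus, start=1):
            out[f"nGenus_{i}"] = float(val)
        return out


def mf_spectrum(norm: NormalizedROI, thresholds: np.ndarray | None = None) -> MFSpectrum:
    """Threshold spectrum of normalized MFs, pooled over slices.

    For each threshold the cell counts ``(p, e, v)`` are summed over all
    slices, the functionals computed from the summed counts, and each
    divided by the total ROI pixel count.  This yields one spectrum per
    tumour whose normalized area is exactly the above-threshold pixel
    fraction.
    """
    if thresholds is None:
        thresholds = threshold_sequence()
    thresholds = np.asarray(thresholds, dtype=float)
    n_tot = norm.n_pixels_total
    if n_tot == 0:
        raise ValueError("cannot compute a spectrum for an empty ROI")
    counts: list[tuple[int, int, int]] = []
    for t in thresholds:
        p = e = v = 0
        for j in range(len(norm.masks)):
            pj, ej, vj = count_cells(binarize(norm, j, float(t)))
            p, e, v = p + pj, e + ej, v + vj
        counts.append((p, e, v))
    areas, peris, genera = [], [], []
    for p, e, v in counts:
        a, u, chi = minkowski_2d(p, e, v)
        areas.append(a / n_tot)
        peris.append(u / n_tot)
        genera.append(chi / n_tot)
    return MFSpectrum(
        thresholds=thresholds,
        n_pixels_total=n_tot,
        narea=np.array(areas[1:]),
        nperi=np.array(peris),
        ngenus=np.array(genera),
        counts=counts,
    )


def size_features(img: TumourImage, in_mm: bool = False) -> tuple[float, float]:
    """Total area and total perimeter of the ROI summed over slices.

    Total area is the ROI pixel count (the area at the all-white threshold);
    total perimeter is the summed ROI contour length in pixel-edge units.
    With ``in_mm`` and spacing metadata, area is returned in mm^2 and
    perimeter in mm.
    """
    ta = 0
    tp = 0
    for m in img.roi:
        p, e, v = count_cells(m)
        a, u, _ = minkowski_2d(p, e, v)
        ta += a
        tp += u
    if in_mm:
        if img.spacing is None:
            raise ValueError("mm units requested but image has no spacing")
        ta *= img.spacing.pixel_mm ** 2
        tp *= img.spacing.pixel_mm
    return float(ta), float(tp)


def si_features(img: TumourImage, ref_mean: float) -> tuple[float, float, float, float]:
    """Mean, SD, max and min of raw ROI intensity, as ratios to ``ref_mean``.

    Statistics are computed on the raw (un-normalized) intensities pooled
    over all slices, then divided by the reference-region mean so they are
    expressed relative to contralateral normal white matter.  SD is the
    population standard deviation.
    """
    if ref_mean <= 0:
        raise ValueError(f"reference mean must be positive, got {ref_mean}")
    vals = img.roi_values()
    mu = float(vals.mean())
    sd = float(vals.std(ddof=0))
    return mu / ref_mean, sd / ref_mean, float(vals.max()) / ref_mean, float(vals.min()) / ref_mean


@dataclass
class FeatureVector:
    """The 38 features of one tumour: 32 MF + 2 size + 4 signal intensity."""

    tumour_id: str
    mf: MFSpectrum
    total_area: float
    total_perimeter: float
    si_mean: float
    si_sd: float
    si_max: float
    si_min: float
    label: str | None = None
    ref_mean: float | None = None

    def as_dict(self) -> dict[str, float]:
        out = self.mf.as_dict()
        out["TotalArea"] = self.total_area
        out["TotalPerimeter"] = self.total_perimeter
        out["SImean"] = self.si_mean
        out["SIsd"] = self.si_sd
        out["SImax"] = self.si_max
        out["SImin"] = self.si_min
        return out

    def as_array(self) -> np.ndarray:
        d = self.as_dict()
        return np.array([d[name] for name in FEATURE_NAMES])


def extract_features(
    img: TumourImage,
    ref: float | None = None,
    n_levels: int = 11,
) -> FeatureVector:
    """Compute the full 38-feature vector for one tumour.

    ``ref`` is an explicit reference-region mean intensity; when omitted the
    image's own reference mask is used.
    """
    rm = reference_mean(img, scalar=ref)
    norm = normalize_roi(img)
    spectrum = mf_spectrum(norm, threshold_sequence(n_levels))
    ta, tp = size_features(img)
    mu, sd, mx, mn = si_features(img, rm)
    return FeatureVector(
        tumour_id=img.tumour_id,
        mf=spectrum,
        total_area=ta,
        total_perimeter=tp,
        si_mean=mu,
        si_sd=sd,
        si_max=mx,
        si_min=mn,
        label=img.label,
        ref_mean=rm,
    )


def features_to_frame(vectors: list[FeatureVector]):
    """Stack FeatureVectors into a DataFrame (tumour_id index, label column)."""
    import pandas as pd

    rows = []
    for fv in vectors:
        row: dict[str, object] = {"tumour_id": fv.tumour_id}
        row.update(fv.as_dict())
        row["label"] = fv.label
        rows.append(row)
    return pd.DataFrame(rows).set_index("tumour_id")
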