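"""Synthetic multi-slice tumour phantoms for end-to-end testing.

No patient images accompany the method, so phantoms provide controllable
stand-ins that realize the morphological axes separating true progression
from pseudoprogression on T2-weighted images: lesion size, boundary
irregularity (contour length per unit area — "frond-like" margins), texture
heterogeneity of the interior, and the depth of dark intratumoural foci
(which lowers the minimum signal intensity).  Each knob is independent so a
test can probe one axis at a time.

The phantom is not an MR simulation: there is no k-space, coil or
relaxation modelling, and its textures are stationary Gaussian random
fields rather than tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy.ndimage import gaussian_filter

from .io import Spacing, TumourImage

Label = Literal["progression", "pseudoprogression"]


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters of one synthetic tumour.

    Parameters
    ----------
    label : str
        Outcome class the phantom emulates.
    n_slices : int
        Number of image slices through the lesion.
    base_radius : float
        Mid-slice lesion radius in pixels (per-slice radii follow a
        spherical-cap profile).
    frond_amplitude : float in [0, 1)
        Relative amplitude of the sinusoidal boundary perturbation
        ``r(theta) = R_j (1 + a * sum_m a_m cos(m theta + phi_m))``;
        0 gives a disc, larger values give frond-like margins with more
        contour length per unit area.
    frond_modes : int
        Highest angular mode of the boundary perturbation.
    texture_sigma : float
        Relative SD of the interior intensity texture (Gaussian random
        field), as a fraction of the tumour base intensity.
    texture_corr_len : float
        Correlation length of the texture in pixels; shorter = more
        fine-grained heterogeneity.
    dark_focus_rate : float
        Expected number of punched dark foci per 100 ROI pixels (Poisson).
    dark_focus_depth : float in [0, 1)
        Relative intensity drop at the centre of a dark focus; deeper foci
        lower the minimum signal intensity.
    wm_mean : float
        Mean intensity of the rectangular white-matter reference region
        (arbitrary units); the tumour base intensity is
        ``hyper_ratio * wm_mean`` (T2-hyperintense lesion).
    hyper_ratio : float
        Tumour-to-white-matter base intensity ratio.
    canvas : int
        Side length of the square slice grid in pixels.
    seed : int
        Seed for all randomness of this phantom.
    """

    label: Label = "progression"
    n_slices: int = 3
    base_radius: float = 14.0
    frond_amplitude: float = 0.35
    frond_modes: int = 8
    texture_sigma: float = 0.30
    texture_corr_len: float = 1.5
    dark_focus_rate: float = 1.2
    dark_focus_depth: float = 0.60
    wm_mean: float = 100.0
    hyper_ratio: float = 1.6
    canvas: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_radius < 3:
            raise ValueError("base_radius must be >= 3 pixels")
        if not 0 <= self.frond_amplitude < 1:
            raise ValueError("frond_amplitude must lie in [0, 1)")
        if not 0 <= self.dark_focus_depth < 1:
            raise ValueError("dark_focus_depth must lie in [0, 1)")
        for name in ("texture_sigma", "texture_corr_len", "dark_focus_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_slices < 1:
            raise ValueError("need at least one slice")
        if self.wm_mean <= 0 or self.hyper_ratio <= 0:
            raise ValueError("wm_mean and hyper_ratio must be positive")
        # the perturbed radius must stay inside the canvas, clear of the
        # reference strip along the top rows
        if self.base_radius * (1 + self.frond_amplitude) > self.canvas / 2 - 6:
            raise ValueError("lesion too large for the canvas")


#: Default class conditions: progression phantoms are larger, more
#: frond-like, more heterogeneous, with deeper/more frequent dark foci.
PROGRESSION_SPEC = PhantomSpec(label="progression")
PSEUDOPROGRESSION_SPEC = PhantomSpec(
    label="pseudoprogression",
    base_radius=10.0,
    frond_amplitude=0.10,
    texture_sigma=0.15,
    texture_corr_len=3.0,
    dark_focus_rate=0.3,
    dark_focus_depth=0.25,
)


def _boundary_radius(theta: np.ndarray, R: float, amp: float, modes: int,
                     coeffs: np.ndarray, phases: np.ndarray) -> np.ndarray:
    """r(theta) for a frond-like simple closed boundary."""
    if amp == 0 or modes < 2:
        return np.full_like(theta, R)
    pert = np.zeros_like(theta)
    for m, (a, phi) in enumerate(zip(coeffs, phases), start=2):
        pert += a * np.cos(m * theta + phi)
    return R * (1 + amp * pert)


def make_phantom(spec: PhantomSpec) -> TumourImage:
    """Render one phantom tumour as a validated :class:`TumourImage`.

    Deterministic for a fixed spec (the seed is part of the spec).  The
    returned image carries a rectangular white-matter reference mask on the
    first slice and the spec's label.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.canvas
    cy = cx = n / 2 + 2  # keep clear of the reference strip in the top rows
    yy, xx = np.mgrid[0:n, 0:n]
    dy, dx = yy + 0.5 - cy, xx + 0.5 - cx
    rr = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)

    # shared boundary shape across slices (one lesion, varying cap radius)
    n_modes = max(spec.frond_modes - 1, 0)
    coeffs = rng.uniform(-1, 1, size=n_modes)
    if n_modes and np.abs(coeffs).sum() > 0:
        coeffs = coeffs / np.abs(coeffs).sum()  # total perturbation < amp < 1
    phases = rng.uniform(0, 2 * np.pi, size=n_modes)

    # spherical-cap radius profile over slices, never vanishing
    z = (np.arange(spec.n_slices) - (spec.n_slices - 1) / 2)
    z = z / (spec.n_slices / 2 + 0.5)
    radii = spec.base_radius * np.sqrt(np.clip(1 - z ** 2, 0.2, None))

    base = spec.hyper_ratio * spec.wm_mean
    slices, rois, refs = [], [], []
    for j in range(spec.n_slices):
        rb = _boundary_radius(theta, float(radii[j]), spec.frond_amplitude,
                              spec.frond_modes, coeffs, phases)
        roi = rr <= rb

        img = np.full((n, n), 0.5 * spec.wm_mean)  # dim background tissue
        tumour = np.full((n, n), base)
        if spec.texture_sigma > 0:
            noise = rng.standard_normal((n, n))
            field = gaussian_filter(noise, sigma=max(spec.texture_corr_len, 1e-6))
            sd = field.std()
            if sd > 0:
                field = field / sd
            tumour = base * (1 + spec.texture_sigma * field)
        # punched dark foci (microhaemorrhage/necrosis-like depressions)
        n_roi = int(roi.sum())
        n_foci = rng.poisson(spec.dark_focus_rate * n_roi / 100.0)
        ys, xs = np.nonzero(roi)
        for _ in range(n_foci):
            if len(ys) == 0:
                break
            k = rng.integers(len(ys))
            fy, fx, frad = ys[k], xs[k], rng.uniform(1.0, 3.0)
            bump = np.exp(-(((yy - fy) ** 2 + (xx - fx) ** 2)
                            / (2 * frad ** 2)))
            tumour = tumour * (1 - spec.dark_focus_depth * bump)
        img[roi] = tumour[roi]

        # white-matter reference strip on the first slice, top-left corner
        ref = np.zeros((n, n), dtype=bool)
        if j == 0:
            ref[1:5, 1:13] = True
            img[ref] = spec.wm_mean * (1 + 0.03 * rng.standard_normal(ref.sum()))
        img = np.clip(img, 1e-3, None)
        slices.append(img)
        rois.append(roi)
        refs.append(ref)

    return TumourImage(
        slices=slices,
        roi=rois,
        reference=refs,
        spacing=Spacing(pixel_mm=1.0, slice_pitch_mm=7.0),
        tumour_id=f"{spec.label}_{spec.seed}",
        label=spec.label,
    )


@dataclass
class LabelledCohort:
    """A reproducible set of phantoms with outcome labels."""

    images: list[TumourImage]
    labels: list[str]
    specs: list[PhantomSpec]
    seed: int


def make_cohort(
    n_per_class: int,
    progression_spec: PhantomSpec = PROGRESSION_SPEC,
    pseudo_spec: PhantomSpec = PSEUDOPROGRESSION_SPEC,
    seed: int = 0,
) -> LabelledCohort:
    """Generate ``n_per_class`` phantoms of each class.

    Per-phantom seeds are drawn deterministically from the cohort seed, so
    the cohort is bit-exactly reproducible from ``(specs, seed)``.
    """
    if n_per_class < 2:
        raise ValueError("need at least 2 phantoms per class")
    rng = np.random.default_rng(seed)
    images, labels, specs = [], [], []
    for base_spec in (progression_spec, pseudo_spec):
        for i in range(n_per_class):
            child = int(rng.integers(2 ** 31))
            sp = replace(base_spec, seed=child)
            img = make_phantom(sp)
            img.tumour_id = f"{sp.label}_{i:03d}"
            images.append(img)
            labels.append(sp.label)
            specs.append(sp)
    return LabelledCohort(images=images, labels=labels, specs=specs, seed=seed)


def sphere_reference(total_area: float, slice_pitch: float = 1.0) -> float:
    """Expected total perimeter of a sphere with the given summed area.

    A sphere sliced at centre-to-centre pitch ``d`` produces discs whose
    summed cross-section approximates ``(4/3) pi R^3 / d`` and whose summed
    circumference approximates ``pi^2 R^2 / d``; eliminating ``R`` links
    total area (a volume surrogate) to total perimeter (a surface
    surrogate).  Tumours with more contour per unit area than this curve
    are more irregular than a sphere.
    """
    if total_area <= 0:
        raise ValueError("total_area must be positive")
    if slice_pitch <= 0:
        raise ValueError("slice_pitch must be positive")
    radius = (3.0 * total_area * slice_pitch / (4.0 * np.pi)) ** (1.0 / 3.0)
    return float(np.pi ** 2 * radius ** 2 / slice_pitch)
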