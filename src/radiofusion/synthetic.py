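"""Seeded synthetic cohorts of masked 3D tumor volumes.

Real pediatric low-grade glioma cohorts (masked FLAIR ROIs with molecular
labels) are not publicly deposited, so every downstream stage of this package
is exercised on synthetic cohorts that emulate the *structure* of such data:

* a binary tumor mask (perturbed ellipsoid) with everything outside zeroed,
* per-channel intensities z-scored within the mask,
* three imbalanced molecular classes (BRAF Fusion / BRAF Mutation / Other),
* optionally several MRI channels with non-primary channels randomly missing.

Class signal is injected through three orthogonal knobs so that the
complementarity of handcrafted features and a CNN can be studied by design:

``shape_effect``
    per-class ellipsoid axis ratios — visible to mesh/PCA shape features.
``texture_effect``
    per-class correlation length and variance of a Gaussian random field —
    visible to gray-level texture matrices (GLDM/GLRLM/GLSZM).
``spatial_effect``
    a linear intensity gradient whose *orientation* encodes the class —
    invisible to translation/rotation-insensitive handcrafted features but
    recoverable by a convolutional network.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

CLASS_NAMES: tuple[str, str, str] = ("Fusion", "Mutation", "Other")

#: Exact class fractions of the emulated 336-patient cohort (142/70/124).
DEFAULT_PROPORTIONS: tuple[float, float, float] = (142 / 336, 70 / 336, 124 / 336)

_CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)


class CohortConfigError(ValueError):
    """Invalid cohort configuration."""


class GenerationError(RuntimeError):
    """A subject could not be generated under the requested geometry."""


@dataclass(frozen=True)
class ShapeEffect:
    """Per-class ellipsoid geometry of the tumor mask.

    ``axis_ratios[k]`` multiplies ``base_radius`` to give the three semi-axes
    (in voxels) for class ``k``.  With the effect disabled all classes share a
    spherical geometry, removing shape as a discriminative cue.
    """

    enabled: bool = True
    axis_ratios: tuple[tuple[float, float, float], ...] = (
        (1.0, 1.0, 1.0),
        (1.55, 1.0, 0.65),
        (1.25, 1.15, 0.7),
    )
    base_radius: float = 6.0
    radius_jitter: float = 0.12
    perturb_amp: float = 0.12
    perturb_smooth: float = 2.0

    def ratios_for(self, class_idx: int) -> tuple[float, float, float]:
        if not self.enabled:
            return (1.0, 1.0, 1.0)
        return self.axis_ratios[class_idx]


@dataclass(frozen=True)
class TextureEffect:
    """Per-class Gaussian-random-field texture inside the mask.

    ``sigma[k]`` is the smoothing kernel width (voxels) controlling the
    correlation length of the field for class ``k``; ``variance[k]`` its
    variance before within-mask z-scoring.  Disabled means no texture field
    at all (a flat interior, up to noise and spatial gradient).
    """

    enabled: bool = True
    sigma: tuple[float, float, float] = (0.5, 1.8, 1.0)
    variance: tuple[float, float, float] = (1.0, 1.0, 1.0)


@dataclass(frozen=True)
class SpatialEffect:
    """Class-coded internal intensity gradient.

    Each class gets a unit gradient direction (default: the three volume
    axes).  The gradient magnitude is identical across classes, so intensity
    *statistics* within the mask do not separate the classes — only the
    spatial arrangement does, which is exactly the kind of cue a CNN can use
    and a translation-invariant handcrafted feature cannot.
    """

    enabled: bool = True
    gradient_axes: tuple[tuple[float, float, float], ...] = (
        (1.0, 0.0, 0.0),
        (0.0, 1.0, 0.0),
        (0.0, 0.0, 1.0),
    )
    magnitude: float = 1.0


@dataclass(frozen=True)
class CohortConfig:
    n_subjects: int = 150
    class_proportions: tuple[float, float, float] = DEFAULT_PROPORTIONS
    volume_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    shape_effect: ShapeEffect = field(default_factory=ShapeEffect)
    texture_effect: TextureEffect = field(default_factory=TextureEffect)
    spatial_effect: SpatialEffect = field(default_factory=SpatialEffect)
    n_channels: int = 1
    channel_missing_prob: tuple[float, ...] | None = None
    noise_sd: float = 0.3
    seed: int = 0

    def missing_probs(self) -> np.ndarray:
        """Per-channel missingness; channel 1 (index 0) is always present."""
        if self.channel_missing_prob is None:
            probs = np.full(self.n_channels, 0.2)
            probs[0] = 0.0
            return probs
        probs = np.asarray(self.channel_missing_prob, dtype=float)
        return probs

    def validate(self) -> None:
        p = np.asarray(self.class_proportions, dtype=float)
        if p.shape != (3,):
            raise CohortConfigError("class_proportions must have exactly 3 entries")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise CohortConfigError(
                f"class_proportions must be non-negative and sum to 1, got {p.tolist()}"
            )
        if self.n_subjects < 3:
            raise CohortConfigError("n_subjects must be at least 3")
        counts = largest_remainder_counts(self.n_subjects, p)
        if np.any(counts == 0):
            raise CohortConfigError(
                f"every class needs at least one subject; counts {counts.tolist()}"
            )
        if not (1 <= self.n_channels <= 4):
            raise CohortConfigError("n_channels must be between 1 and 4")
        probs = self.missing_probs()
        if probs.shape != (self.n_channels,):
            raise CohortConfigError(
                "channel_missing_prob must have one entry per channel"
            )
        if probs[0] != 0.0:
            raise CohortConfigError("channel 1 must never be missing (prob 0)")
        if np.any((probs < 0) | (probs > 1)):
            raise CohortConfigError("channel_missing_prob entries must lie in [0, 1]")
        if self.noise_sd < 0:
            raise CohortConfigError("noise_sd must be non-negative")
        if len(self.volume_shape) != 3 or any(s < 8 for s in self.volume_shape):
            raise CohortConfigError("volume_shape must be 3 axes of at least 8 voxels")


@dataclass
class SubjectVolume:
    """One synthetic subject: multi-channel masked image + label.

    ``images`` has shape (n_channels, D, H, W) and is exactly zero outside
    ``mask``; intensities of each present channel are z-scored within the
    mask.  ``spacing`` is in mm per axis.
    """

    subject_id: str
    images: np.ndarray
    present_channels: np.ndarray
    mask: np.ndarray
    spacing: tuple[float, float, float]
    label: str


def largest_remainder_counts(n: int, proportions: Sequence[float]) -> np.ndarray:
    """Apportion ``n`` into integer class counts by largest-remainder rounding."""
    p = np.asarray(proportions, dtype=float)
    exact = n * p
    counts = np.floor(exact).astype(int)
    remainder = exact - counts
    short = n - counts.sum()
    # ties broken by class order (stable argsort on negated remainder)
    for idx in np.argsort(-remainder, kind="stable")[:short]:
        counts[idx] += 1
    return counts


def z_score_in_mask(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Z-score intensities within the mask; outside stays exactly zero.

    A degenerate (constant) interior maps to zeros rather than NaN.
    """
    out = np.zeros_like(image, dtype=np.float32)
    vals = image[mask]
    sd = vals.std()
    if sd > 1e-12:
        out[mask] = (vals - vals.mean()) / sd
    return out


def _largest_cc(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=_CONNECTIVITY_26)
    if n == 0:
        return mask
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def generate_mask(
    semi_axes: Sequence[float],
    volume_shape: Sequence[int],
    rng: np.random.Generator,
    perturb_amp: float = 0.12,
    perturb_smooth: float = 2.0,
    center: Sequence[float] | None = None,
) -> np.ndarray:
    """Voxelize a boundary-perturbed ellipsoid as a 26-connected binary mask.

    The implicit surface is ``q(x) = 1 + perturb_amp * f(x)`` where ``q`` is
    the normalized ellipsoid radius and ``f`` a smoothed, unit-variance noise
    field; the largest 26-connected component is returned.
    """
    semi_axes = np.asarray(semi_axes, dtype=float)
    shape = tuple(int(s) for s in volume_shape)
    if center is None:
        center = (np.asarray(shape) - 1) / 2.0
    center = np.asarray(center, dtype=float)
    margin = 1.0 + 1.5 * perturb_amp
    if np.any(center - semi_axes * margin < -0.5) or np.any(
        center + semi_axes * margin > np.asarray(shape) - 0.5
    ):
        raise GenerationError(
            f"ellipsoid semi-axes {semi_axes.tolist()} do not fit in volume {shape}"
        )
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    q = np.sqrt(
        sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes))
    )
    if perturb_amp > 0:
        noise = ndimage.gaussian_filter(
            rng.standard_normal(shape), perturb_smooth
        )
        noise = noise / max(noise.std(), 1e-12)
        mask = q <= 1.0 + perturb_amp * noise
    else:
        mask = q <= 1.0
    mask = _largest_cc(mask)
    if mask.sum() < 27:
        raise GenerationError(
            f"mask has only {int(mask.sum())} voxels (< 27); enlarge semi_axes"
        )
    return mask


def fill_texture(
    mask: np.ndarray,
    sigma: float,
    variance: float,
    gradient_axis: Sequence[float] | None,
    gradient_magnitude: float,
    rng: np.random.Generator,
    noise_sd: float = 0.0,
    texture_enabled: bool = True,
) -> np.ndarray:
    """Masked intensity field: Gaussian random field + linear gradient + noise.

    The result is z-scored within the mask and exactly zero outside.  With
    texture disabled, zero gradient and zero noise, the (pre-z-score) interior
    is constant.
    """
    if not mask.any():
        raise GenerationError("fill_texture requires a non-empty mask")
    shape = mask.shape
    img = np.zeros(shape, dtype=np.float64)
    if texture_enabled:
        if np.isfinite(sigma):
            f = rng.standard_normal(shape)
            if sigma > 0:
                f = ndimage.gaussian_filter(f, sigma)
            sd = f[mask].std()
            if sd > 1e-12:
                f = f / sd
            img += np.sqrt(variance) * f
        # infinite correlation length: a uniform field adds nothing
    if gradient_axis is not None and gradient_magnitude != 0.0:
        d = np.asarray(gradient_axis, dtype=float)
        d = d / np.linalg.norm(d)
        coords = np.argwhere(mask).astype(float)
        centroid = coords.mean(axis=0)
        r0 = max(float(np.abs((coords - centroid) @ d).max()), 1.0)
        grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
        proj = sum(d_i * (g - c) for d_i, g, c in zip(d, grids, centroid))
        img += gradient_magnitude * proj / r0
    if noise_sd > 0:
        img += noise_sd * rng.standard_normal(shape)
    img[~mask] = 0.0
    return z_score_in_mask(img, mask)


def generate_cohort(config: CohortConfig) -> list[SubjectVolume]:
    """Generate a seeded cohort of :class:`SubjectVolume`.

    Class counts follow largest-remainder rounding of the configured
    proportions; the subject order is a seeded permutation.  The result is
    bitwise reproducible for a fixed config.
    """
    config.validate()
    counts = largest_remainder_counts(config.n_subjects, config.class_proportions)
    ss = np.random.SeedSequence(config.seed)
    order_seed, missing_seed, *subject_seeds = ss.spawn(2 + config.n_subjects)

    class_indices = np.repeat(np.arange(3), counts)
    order_rng = np.random.default_rng(order_seed)
    class_indices = class_indices[order_rng.permutation(config.n_subjects)]

    se, te, pe = config.shape_effect, config.texture_effect, config.spatial_effect
    width = len(str(config.n_subjects))
    cohort: list[SubjectVolume] = []
    for i, k in enumerate(class_indices):
        sid = f"S{i + 1:0{width}d}"
        rng = np.random.default_rng(subject_seeds[i])
        ratios = np.asarray(se.ratios_for(int(k)))
        # lognormal jitter truncated at two sigma so the largest class
        # geometry provably fits inside the default volume
        draw = float(np.clip(rng.normal(0.0, 1.0), -2.0, 2.0))
        jitter = float(np.exp(se.radius_jitter * draw))
        semi_axes = se.base_radius * ratios * jitter
        center = (np.asarray(config.volume_shape) - 1) / 2.0 + rng.uniform(-1.5, 1.5, 3)
        try:
            mask = generate_mask(
                semi_axes,
                config.volume_shape,
                rng,
                perturb_amp=se.perturb_amp,
                perturb_smooth=se.perturb_smooth,
                center=center,
            )
        except GenerationError as exc:
            raise GenerationError(f"subject {sid}: {exc}") from exc
        sigma = te.sigma[int(k)] if te.enabled else 0.0
        variance = te.variance[int(k)] if te.enabled else 0.0
        axis = pe.gradient_axes[int(k)] if pe.enabled else None
        images = np.empty((config.n_channels, *config.volume_shape), dtype=np.float32)
        for c in range(config.n_channels):
            images[c] = fill_texture(
                mask,
                sigma=sigma,
                variance=variance,
                gradient_axis=axis,
                gradient_magnitude=pe.magnitude if pe.enabled else 0.0,
                rng=rng,
                noise_sd=config.noise_sd,
                texture_enabled=te.enabled,
            )
        cohort.append(
            SubjectVolume(
                subject_id=sid,
                images=images,
                present_channels=np.ones(config.n_channels, dtype=bool),
                mask=mask,
                spacing=tuple(float(s) for s in config.voxel_spacing),
                label=CLASS_NAMES[int(k)],
            )
        )
    if config.n_channels > 1:
        cohort = apply_missing_channels(
            cohort, config, np.random.default_rng(missing_seed)
        )
    return cohort


def complementarity_config(n_subjects: int = 150, seed: int = 0) -> CohortConfig:
    """The designed condition under which handcrafted and CNN features are
    complementary.

    Shape and texture differences are kept subtle — axis ratios within the
    range of the per-subject radius jitter and boundary perturbation, texture
    correlation lengths close together — so handcrafted features separate the
    classes only partially.  The class-coded gradient orientation is invisible
    to the direction-averaged handcrafted set but learnable by the CNN.
    Neither feature family alone should reach the performance of their fusion
    here.
    """
    return CohortConfig(
        n_subjects=n_subjects,
        seed=seed,
        shape_effect=ShapeEffect(
            axis_ratios=(
                (1.0, 1.0, 1.0),
                (1.15, 1.0, 0.87),
                (1.08, 1.05, 0.9),
            )
        ),
        texture_effect=TextureEffect(sigma=(0.85, 1.45, 1.1)),
        spatial_effect=SpatialEffect(magnitude=1.2),
        noise_sd=0.4,
    )


def apply_missing_channels(
    cohort: list[SubjectVolume], config: CohortConfig, rng: np.random.Generator
) -> list[SubjectVolume]:
    """Zero out randomly absent non-primary channels, flagging them absent.

    Emulates incomplete MRI protocols where secondary sequences exist only
    for a subset of patients; the primary channel is never removed.
    """
    probs = config.missing_probs()
    for subject in cohort:
        draws = rng.random(len(probs))
        absent = draws < probs
        absent[0] = False
        for c in np.nonzero(absent)[0]:
            subject.images[c] = 0.0
            subject.present_channels[c] = False
    return cohort


def labels_of(cohort: Sequence[SubjectVolume]) -> np.ndarray:
    return np.array([s.label for s in cohort])
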