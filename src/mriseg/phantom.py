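"""Synthetic brain-like grayscale phantoms with known per-pixel tissue labels.

A phantom emulates the tissue classes visible on a brain MR slice — regional
background, soft tissue, fat and bone — as K intensity classes on [0, 1]
with chosen area fractions, optionally corrupted by additive Gaussian noise
and a smooth multiplicative bias field.  The ground-truth label map makes
every segmentation method verifiable without patient data.

Two layouts are provided: ``concentric`` nests the classes as slightly
elliptical rings around the image center (background outermost), and
``blobs`` carves classes out of a smoothed random field.  Both assign
classes by quantiles of a per-pixel scalar field, so the empirical area
fractions match the requested ones to within ties of that field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = ["PhantomSpec", "Phantom", "generate_phantom", "phantom_suite", "PRESETS"]

DEFAULT_CLASS_MEANS = (0.05, 0.35, 0.65, 0.95)
#: area fractions mirror a brain slice's composition: regional background
#: dominates, then soft tissue and fat, with bone the thinnest class
DEFAULT_CLASS_FRACTIONS = (0.4, 0.3, 0.2, 0.1)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic phantom.

    Intensities are normalized to [0, 1]; ``noise_sigma`` is the standard
    deviation of additive Gaussian noise in those units, and
    ``bias_amplitude`` the peak-to-peak amplitude of the multiplicative
    low-frequency bias field (0 disables it).
    """

    width: int = 256
    height: int = 256
    n_classes: int = 4
    class_means: tuple[float, ...] = DEFAULT_CLASS_MEANS
    class_fractions: tuple[float, ...] = DEFAULT_CLASS_FRACTIONS
    noise_sigma: float = 0.05
    bias_amplitude: float = 0.0
    layout: str = "concentric"
    seed: int = 0

    def validate(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("width and height must be positive")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if len(self.class_means) != self.n_classes:
            raise ValueError("class_means must have n_classes entries")
        if len(self.class_fractions) != self.n_classes:
            raise ValueError("class_fractions must have n_classes entries")
        means = np.asarray(self.class_means, dtype=float)
        if np.any(np.diff(means) <= 0):
            raise ValueError("class_means must be strictly increasing")
        fracs = np.asarray(self.class_fractions, dtype=float)
        if np.any(fracs <= 0):
            raise ValueError("class_fractions must all be > 0")
        if abs(fracs.sum() - 1.0) > 1e-9:
            raise ValueError("class_fractions must sum to 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.bias_amplitude < 0:
            raise ValueError("bias_amplitude must be >= 0")
        if self.layout not in ("concentric", "blobs"):
            raise ValueError(f"unknown layout {self.layout!r}")


@dataclass
class Phantom:
    """A synthetic image, its ground-truth label map and the generating spec."""

    image: np.ndarray
    truth: np.ndarray
    spec: PhantomSpec


def _quantile_labels(field_vals: np.ndarray, fractions: np.ndarray) -> np.ndarray:
    """Assign classes 0..K-1 by rank quantiles of a scalar field (exact
    fractions up to ties); the highest field values get the highest class."""
    flat = field_vals.ravel()
    order = np.argsort(flat, kind="stable")
    n = flat.size
    bounds = np.floor(np.cumsum(fractions) * n + 0.5).astype(int)
    bounds[-1] = n
    labels = np.empty(n, dtype=np.int32)
    start = 0
    for cls, stop in enumerate(bounds):
        labels[order[start:stop]] = cls
        start = stop
    return labels.reshape(field_vals.shape)


def _concentric_field(h: int, w: int) -> np.ndarray:
    """Slightly elliptical radial distance from the image center; *negated*
    so the innermost pixels carry the largest field values (highest class)."""
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r2 = ((rr - cy) / h) ** 2 * 1.15 + ((cc - cx) / w) ** 2
    return -r2


def _blob_field(h: int, w: int, rng: np.random.Generator) -> np.ndarray:
    sigma = max(2.0, min(h, w) / 16.0)
    return gaussian_filter(rng.standard_normal((h, w)), sigma=sigma, mode="reflect")


def _bias_field(h: int, w: int, amplitude: float) -> np.ndarray:
    if amplitude == 0:
        return np.ones((h, w))
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    surface = np.cos(2 * np.pi * rr / max(h, 1)) * np.cos(2 * np.pi * cc / max(w, 1))
    return 1.0 + 0.5 * amplitude * surface


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Generate image and truth for a spec; deterministic given ``spec.seed``.

    Pixel values are class_mean[truth] x bias + Gaussian noise, clipped to
    [0, 1].
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    fractions = np.asarray(spec.class_fractions, dtype=float)
    if spec.layout == "concentric":
        field_vals = _concentric_field(h, w)
    else:
        field_vals = _blob_field(h, w, rng)
    truth = _quantile_labels(field_vals, fractions)
    means = np.asarray(spec.class_means, dtype=float)
    image = means[truth] * _bias_field(h, w, spec.bias_amplitude)
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=(h, w))
    return Phantom(image=np.clip(image, 0.0, 1.0), truth=truth, spec=spec)


def _preset_benchmark() -> list[PhantomSpec]:
    """Two 256x256 and two 512x512 phantoms, the sizes of the runtime and
    error-rate comparison harness."""
    return [
        PhantomSpec(width=256, height=256, layout="concentric", seed=11),
        PhantomSpec(width=256, height=256, layout="blobs", seed=12),
        PhantomSpec(width=512, height=512, layout="concentric", seed=13),
        PhantomSpec(width=512, height=512, layout="blobs", seed=14),
    ]


def _preset_tiny() -> list[PhantomSpec]:
    return [
        PhantomSpec(width=32, height=32, noise_sigma=0.02, layout="concentric", seed=1),
        PhantomSpec(width=24, height=24, noise_sigma=0.02, layout="blobs", seed=2),
    ]


def _preset_separable() -> list[PhantomSpec]:
    """Zero-noise, zero-bias phantoms: exactly K-valued, so any correct
    K-cluster segmentation must reach error rate 0."""
    return [
        PhantomSpec(width=256, height=256, noise_sigma=0.0, layout="concentric", seed=21),
        PhantomSpec(width=256, height=256, noise_sigma=0.0, layout="blobs", seed=22),
    ]


def _preset_noisy_ordering() -> list[PhantomSpec]:
    """Twenty seeded 64x64 phantoms at noise_sigma 0.06, where adjacent
    class histograms overlap (class means 0.3 apart, +-3 sigma = 0.18 on
    each side); the stage for the three-method error-rate ordering.  The
    unbalanced default area fractions matter here: initialization
    sensitivity of k-means shows only when cluster masses are unequal."""
    return [
        PhantomSpec(
            width=64,
            height=64,
            noise_sigma=0.06,
            layout="concentric" if i % 2 == 0 else "blobs",
            seed=100 + i,
        )
        for i in range(20)
    ]


PRESETS = {
    "benchmark": _preset_benchmark,
    "tiny": _preset_tiny,
    "separable": _preset_separable,
    "noisy_ordering": _preset_noisy_ordering,
}


def phantom_suite(preset: str) -> list[Phantom]:
    """Generate the named preset's phantoms (fixed seeds, reproducible)."""
    try:
        specs = PRESETS[preset]()
    except KeyError:
        raise ValueError(
            f"unknown preset {preset!r}; registered: {sorted(PRESETS)}"
        ) from None
    return [generate_phantom(s) for s in specs]
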