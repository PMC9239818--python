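"""One-call segmentation of a grayscale image with any of the three methods."""

from __future__ import annotations

import numpy as np

from .config import RunConfig
from .density import density_init_centers
from .kmeans import Dataset, random_init, run_kmeans
from .meanshift import mean_shift_segment

__all__ = ["segment_image"]


def segment_image(pixels: np.ndarray, cfg: RunConfig) -> tuple[np.ndarray, dict]:
    """Segment a 2-D intensity raster in [0, 1].

    Returns the 2-D integer label image and an info dict (centers or modes,
    objective trace, iteration counts, config) suitable for JSON export.
    """
    cfg.validate()
    pixels = np.asarray(pixels, dtype=np.float64)
    if pixels.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    data = Dataset.from_image(pixels, spatial_weight=cfg.spatial_weight)

    if cfg.method == "meanshift":
        result = mean_shift_segment(data, bandwidth=cfg.bandwidth)
        info = {
            "method": cfg.method,
            "modes": result.modes.tolist(),
            "n_modes": result.n_modes,
            "bandwidth": result.bandwidth,
            "config": cfg.to_dict(),
        }
        return result.labels_as_image(pixels.shape), info

    if cfg.init == "density":
        centers = density_init_centers(data, cfg.k, radius=cfg.density_radius)
    else:
        centers = random_init(data, cfg.k, rng=cfg.seed)
    model = run_kmeans(data, centers, max_iter=cfg.max_iter, tol=cfg.tol)
    info = {
        "method": cfg.method,
        "init_centers": centers.tolist(),
        "centers": model.centers.tolist(),
        "objective_trace": [float(v) for v in model.objective_trace],
        "iterations": model.iterations,
        "converged": model.converged,
        "config": cfg.to_dict(),
    }
    return model.labels_as_image(pixels.shape), info
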