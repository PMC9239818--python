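"""Run configuration shared by the CLI and the comparison harness."""

from __future__ import annotations

from dataclasses import dataclass, asdict

METHODS = ("kmeans", "kmeans-density", "meanshift")
INITS = ("random", "density")


@dataclass
class RunConfig:
    """Validated parameters of one segmentation run.

    ``method`` "kmeans" uses random initialization, "kmeans-density" the
    density-peaks initialization, "meanshift" the mode-seeking baseline.
    ``seed`` affects only the random initialization; every other path is
    deterministic.
    """

    method: str = "kmeans-density"
    k: int = 4
    init: str | None = None  # derived from method when None
    density_radius: float | str = "auto"
    bandwidth: float | str = "auto"
    spatial_weight: float = 0.0
    tol: float = 1e-6
    max_iter: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.init is None:
            self.init = "density" if self.method == "kmeans-density" else "random"

    def validate(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.method != "meanshift" and self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.init not in INITS:
            raise ValueError(f"init must be one of {INITS}, got {self.init!r}")
        if self.density_radius != "auto" and float(self.density_radius) <= 0:
            raise ValueError("density_radius must be > 0 or 'auto'")
        if self.bandwidth != "auto" and float(self.bandwidth) <= 0:
            raise ValueError("bandwidth must be > 0 or 'auto'")
        if self.spatial_weight < 0:
            raise ValueError("spatial_weight must be >= 0")
        if self.tol < 0:
            raise ValueError("tol must be >= 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)
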