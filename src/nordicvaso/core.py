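"""Core in-memory containers shared across the package.

A :class:`ComplexSeries` is the canonical 4D fMRI object: a spatial grid
(x, y, z) by time array that is either complex-valued (magnitude + phase
acquisitions) or real-valued (magnitude-only).  Trailing RF-off noise
volumes, used to calibrate the thermal-noise threshold, are carried inside
the array and flagged by ``n_noise_volumes`` rather than dropped, so they
stay aligned with the data through g-factor normalization.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ComplexSeries", "GFactorMap", "wrap_phase"]


def wrap_phase(phase: np.ndarray) -> np.ndarray:
    """Wrap phase values (radians) into the interval (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(phase, dtype=float), 2.0 * np.pi)


@dataclass
class ComplexSeries:
    """A 4D voxel time series, complex-valued or magnitude-only.

    Parameters
    ----------
    values
        Array of shape ``(nx, ny, nz, nt)``.  Complex dtype when phase is
        available, real dtype for magnitude-only data.
    contrast
        Label of the contrast carried by the series.  Canonical values are
        ``"interleaved"`` (alternating nulled / not-nulled volumes, volume 0
        is nulled), ``"nulled"``, ``"notnulled"``, ``"vaso"`` (BOLD-corrected)
        and ``"bold"``.
    n_noise_volumes
        Number of trailing volumes acquired with the RF amplitude set to 0
        (pure thermal noise).  They are part of ``values`` but are excluded
        from :attr:`data`.
    voxel_size
        Voxel dimensions in mm.
    """

    values: np.ndarray
    contrast: str = "interleaved"
    n_noise_volumes: int = 0
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    validate: dataclasses.InitVar[bool] = True

    def __post_init__(self, validate: bool) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 4:
            raise ValueError(
                f"series must be 4D (x, y, z, t); got shape {self.values.shape}"
            )
        if self.n_noise_volumes < 0 or self.n_noise_volumes >= self.values.shape[-1]:
            raise ValueError("n_noise_volumes must be >= 0 and < total volumes")
        if validate:
            if self.n_data_volumes < 2:
                raise ValueError("need at least 2 data volumes (noise volumes excluded)")
            if not np.iscomplexobj(self.values) and np.any(self.values < 0):
                raise ValueError("magnitude-only series must be non-negative")

    # -- basic geometry -------------------------------------------------
    @property
    def grid_dims(self) -> tuple[int, int, int]:
        return self.values.shape[:3]

    @property
    def n_volumes(self) -> int:
        """Total number of volumes, noise volumes included."""
        return self.values.shape[-1]

    @property
    def n_data_volumes(self) -> int:
        return self.n_volumes - self.n_noise_volumes

    @property
    def data(self) -> np.ndarray:
        """View of the data volumes (noise volumes excluded)."""
        return self.values[..., : self.n_data_volumes]

    @property
    def noise_volumes(self) -> np.ndarray:
        """View of the trailing RF-off noise volumes (may be empty)."""
        return self.values[..., self.n_data_volumes :]

    # -- magnitude / phase ----------------------------------------------
    @property
    def has_phase(self) -> bool:
        return bool(np.iscomplexobj(self.values))

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.values) if self.has_phase else self.values

    @property
    def phase(self) -> np.ndarray:
        if not self.has_phase:
            raise ValueError("magnitude-only series carries no phase")
        return np.angle(self.values)

    def as_magnitude(self) -> "ComplexSeries":
        """Return a magnitude-only copy (drops phase information)."""
        return ComplexSeries(
            np.abs(self.values),
            contrast=self.contrast,
            n_noise_volumes=self.n_noise_volumes,
            voxel_size=self.voxel_size,
        )

    def copy_with(self, values: np.ndarray, *, contrast: str | None = None,
                  n_noise_volumes: int | None = None,
                  validate: bool = False) -> "ComplexSeries":
        """New series with the same metadata but different values."""
        return ComplexSeries(
            values,
            contrast=self.contrast if contrast is None else contrast,
            n_noise_volumes=(
                self.n_noise_volumes if n_noise_volumes is None else n_noise_volumes
            ),
            voxel_size=self.voxel_size,
            validate=validate,
        )


@dataclass
class GFactorMap:
    """Spatial map of parallel-imaging noise amplification.

    Dividing a series by the g-factor makes thermal noise spatially
    uniform, which is what the singular-value threshold assumes.  The map
    is used on a relative scale only; ``normalization`` records the scalar
    that set the reference level (in-mask median = 1 when estimated here).
    """

    values: np.ndarray
    normalization: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("g-factor map must be 3D")
        if not np.all(np.isfinite(self.values)) or np.any(self.values <= 0):
            raise ValueError("g-factor map must be strictly positive and finite")

    @property
    def grid_dims(self) -> tuple[int, int, int]:
        return self.values.shape
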