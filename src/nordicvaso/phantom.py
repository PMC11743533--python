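"""Synthetic VASO phantom with known ground truth.

The phantom emulates a submillimeter block-design VASO run: nulled
(CBV-weighted) and not-nulled (BOLD-weighted) volumes acquired in an
alternating fashion, a negative fractional response in the nulled contrast
and a positive one in the not-nulled contrast during task blocks, complex
Gaussian thermal noise scaled by a smooth g-factor field (so magnitude data
are Rician), CSF-like voxels with temporal 180-degree phase skips, and an
appended RF-off noise volume.

Geometry is a curved cortical ribbon (an annulus whose radius undulates
across slices) embedded in a slab, with an analytic cortical-depth map in
[0, 1] from the inner (deep) to the outer (superficial) boundary, and a
CSF band lining the inner boundary.  This provides the ROI and laminar
machinery downstream analyses need without any segmentation step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from .core import ComplexSeries, GFactorMap

__all__ = [
    "PhantomSpec",
    "DesignTable",
    "GroundTruth",
    "make_design",
    "generate_gfactor_field",
    "tissue_maps",
    "simulate_run",
    "default_profile_shape",
]

# tissue class codes
BACKGROUND, CORTEX, CSF = 0, 1, 2

# seed-stream tags so independent noise sources never share a stream
_STREAM_GFIELD = 11
_STREAM_PHASE = 12
_STREAM_SKIP = 13
_STREAM_RUN = 100  # + run_index


def default_profile_shape(depth: np.ndarray) -> np.ndarray:
    """Mid-depth-peaked laminar response profile.

    A smooth bump peaking at depth 0.5, emulating the middle-layer weighted
    CBV response that laminar VASO studies target.  Values are amplitude
    multipliers of order 1.
    """
    depth = np.asarray(depth, dtype=float)
    return 0.6 + 0.8 * np.exp(-((depth - 0.5) ** 2) / (2 * 0.15**2))


@dataclass
class DesignTable:
    """Block design in volume units (per contrast timeline).

    ``blocks`` is a list of ``(onset_volume, duration_volumes, condition)``
    tuples with condition in {"rest", "task"}; blocks tile the run without
    gaps or overlap, starting with rest.
    """

    blocks: list[tuple[int, int, str]]
    n_trials: int
    volumes_per_contrast: int

    def __post_init__(self) -> None:
        cursor = 0
        for onset, dur, cond in self.blocks:
            if onset != cursor:
                raise ValueError("blocks must tile the run without gaps or overlap")
            if cond not in ("rest", "task"):
                raise ValueError(f"unknown condition {cond!r}")
            cursor = onset + dur
        if cursor != self.volumes_per_contrast:
            raise ValueError("blocks do not cover volumes_per_contrast")
        if self.n_trials != sum(1 for b in self.blocks if b[2] == "task"):
            raise ValueError("n_trials must equal the number of task blocks")

    @property
    def task_blocks(self) -> list[tuple[int, int, str]]:
        return [b for b in self.blocks if b[2] == "task"]

    @property
    def rest_blocks(self) -> list[tuple[int, int, str]]:
        return [b for b in self.blocks if b[2] == "rest"]

    def task_indicator(self) -> np.ndarray:
        """Boolean per-volume task indicator of length volumes_per_contrast."""
        ind = np.zeros(self.volumes_per_contrast, dtype=bool)
        for onset, dur, cond in self.blocks:
            if cond == "task":
                ind[onset : onset + dur] = True
        return ind

    def trial_index(self) -> np.ndarray:
        """Per-volume trial index (-1 for rest volumes)."""
        idx = np.full(self.volumes_per_contrast, -1, dtype=int)
        trial = 0
        for onset, dur, cond in self.blocks:
            if cond == "task":
                idx[onset : onset + dur] = trial
                trial += 1
        return idx


def make_design(volumes_per_contrast: int, rest_len: int, task_len: int) -> DesignTable:
    """Alternating rest/task block design starting with rest.

    ``volumes_per_contrast`` must divide evenly into rest+task cycles and
    block lengths must be >= 3 so that discarding the first two transition
    volumes of each block leaves at least one usable volume.
    """
    if rest_len < 3 or task_len < 3:
        raise ValueError("rest_len and task_len must be >= 3")
    cycle = rest_len + task_len
    remainder = volumes_per_contrast % cycle
    if remainder:
        raise ValueError(
            f"volumes_per_contrast={volumes_per_contrast} does not divide into "
            f"rest+task cycles of {cycle} volumes (remainder {remainder})"
        )
    n_trials = volumes_per_contrast // cycle
    blocks: list[tuple[int, int, str]] = []
    onset = 0
    for _ in range(n_trials):
        blocks.append((onset, rest_len, "rest"))
        onset += rest_len
        blocks.append((onset, task_len, "task"))
        onset += task_len
    return DesignTable(blocks=blocks, n_trials=n_trials,
                       volumes_per_contrast=volumes_per_contrast)


@dataclass
class PhantomSpec:
    """Stated world of the phantom.

    Defaults emulate one 12-min 3T run of the block-design visuomotor
    paradigm: 144 volumes per contrast alternating 6-volume rest and task
    blocks (12 trials per run), six runs per session, thermal-noise-dominated
    voxels (single-voxel nulled tSNR ~ 10), a smooth g-factor field, ~10%
    trial-to-trial amplitude variability shared across voxels, a weak slow
    shared physiological fluctuation, and one trailing RF-off noise volume.
    """

    grid_dims: tuple[int, int, int] = (32, 32, 16)
    n_runs: int = 6
    volumes_per_contrast_per_run: int = 144
    rest_block_len: int = 6
    task_block_len: int = 6
    # per-tissue baselines in arbitrary scanner units
    baseline_nulled: dict[str, float] = field(
        default_factory=lambda: {"cortex": 300.0, "csf": 150.0, "background": 0.0}
    )
    baseline_notnulled: dict[str, float] = field(
        default_factory=lambda: {"cortex": 1000.0, "csf": 1400.0, "background": 0.0}
    )
    vaso_amplitude: float = 0.02  # fractional nulled-signal DECREASE during task
    bold_amplitude: float = 0.02  # fractional not-nulled INCREASE during task
    profile_shape: Callable[[np.ndarray], np.ndarray] = default_profile_shape
    sigma_thermal: float = 30.0  # complex-channel noise SD, signal units
    g_field_smoothness: float = 8.0  # voxels
    g_field_max: float = 1.5
    physio_sd: float = 0.005  # fractional SD of the slow shared fluctuation
    trial_amp_sd: float = 0.1  # SD of per-trial amplitude modulation
    phase_skip_fraction: float = 0.5  # fraction of CSF voxels with pi phase skips
    n_noise_volumes: int = 1
    seed: int = 0

    def validate(self) -> None:
        for name in ("vaso_amplitude", "bold_amplitude", "sigma_thermal",
                     "physio_sd", "trial_amp_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.g_field_max < 1:
            raise ValueError("g_field_max must be >= 1")
        if not 0 <= self.phase_skip_fraction <= 1:
            raise ValueError("phase_skip_fraction must be in [0, 1]")
        cycle = self.rest_block_len + self.task_block_len
        if self.volumes_per_contrast_per_run % cycle:
            raise ValueError(
                "volumes_per_contrast_per_run must divide evenly into rest+task blocks"
            )

    def design(self) -> DesignTable:
        return make_design(self.volumes_per_contrast_per_run,
                           self.rest_block_len, self.task_block_len)


@dataclass
class GroundTruth:
    """Everything the generator knows that an analysis must recover."""

    clean_nulled: np.ndarray  # thermal-noise-free 4D magnitude series
    clean_notnulled: np.ndarray
    true_psc_map: np.ndarray  # per-voxel nulled-contrast PSC (negative in cortex)
    depth_map: np.ndarray  # 3D in [0,1]; NaN outside cortex
    tissue_map: np.ndarray  # 3D int: 0 background, 1 cortex, 2 csf
    g_map: GFactorMap
    design: DesignTable
    trial_amplitudes: np.ndarray  # per-trial modulation scalars

    @property
    def roi_mask(self) -> np.ndarray:
        """Cortex mask — the phantom analog of the activated-region ROI."""
        return self.tissue_map == CORTEX

    @property
    def layered_roi_mask(self) -> np.ndarray:
        """Small single-slice cortical patch for laminar analysis.

        Analog of a manually drawn layered ROI: cortex voxels restricted to
        one quadrant of the central slice, small enough that depth-bin means
        remain thermal-noise-limited at low trial counts.
        """
        nx, ny, nz = self.tissue_map.shape
        sel = np.zeros_like(self.tissue_map, dtype=bool)
        sel[nx // 2 :, ny // 2 :, nz // 2] = True
        return (self.tissue_map == CORTEX) & sel


def _smooth_field(rng: np.random.Generator, dims: Sequence[int],
                  smoothness: float) -> np.ndarray:
    """Gaussian-correlated random field, roughly unit scale."""
    field = ndimage.gaussian_filter(rng.standard_normal(tuple(dims)),
                                    sigma=smoothness, mode="wrap")
    sd = field.std()
    return field / sd if sd > 0 else field


def generate_gfactor_field(spec: PhantomSpec) -> GFactorMap:
    """Smooth positive noise-amplification field with min 1 and max g_field_max.

    Deterministic given ``spec.seed``; g_field_max = 1 degenerates to a
    uniform field of ones.
    """
    if spec.g_field_max < 1:
        raise ValueError("g_field_max must be >= 1")
    if spec.g_field_smoothness <= 0:
        raise ValueError("g_field_smoothness must be > 0")
    rng = np.random.default_rng([spec.seed, _STREAM_GFIELD])
    field = _smooth_field(rng, spec.grid_dims, spec.g_field_smoothness)
    lo, hi = field.min(), field.max()
    if spec.g_field_max == 1.0 or hi == lo:
        return GFactorMap(np.ones(spec.grid_dims))
    scaled = 1.0 + (spec.g_field_max - 1.0) * (field - lo) / (hi - lo)
    return GFactorMap(scaled)


def tissue_maps(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Analytic tissue classes and cortical depth for the curved ribbon.

    Returns ``(tissue_map, depth_map)``.  The cortex is an annulus in each
    slice whose outer radius undulates across z (a curved ribbon); depth runs
    from 0 at the inner (deep) boundary to 1 at the outer (superficial)
    boundary.  A CSF band lines the inside of the ribbon.
    """
    nx, ny, nz = spec.grid_dims
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    x, y, z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                          indexing="ij")
    r = np.hypot(x - cx, y - cy)
    r_out_base = 0.40 * min(nx, ny)
    # gentle curvature of the ribbon across slices
    r_out = r_out_base * (1.0 + 0.05 * np.sin(2 * np.pi * z / max(nz, 1)))
    r_in = 0.65 * r_out
    r_csf = 0.70 * r_in

    tissue = np.full(spec.grid_dims, BACKGROUND, dtype=np.int8)
    cortex = (r >= r_in) & (r < r_out)
    csf = (r >= r_csf) & (r < r_in)
    tissue[cortex] = CORTEX
    tissue[csf] = CSF

    depth = np.full(spec.grid_dims, np.nan)
    depth[cortex] = ((r - r_in) / (r_out - r_in))[cortex]
    return tissue, depth


def _baseline_maps(spec: PhantomSpec, tissue: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    b_n = np.zeros(spec.grid_dims)
    b_nn = np.zeros(spec.grid_dims)
    for cls, code in (("background", BACKGROUND), ("cortex", CORTEX), ("csf", CSF)):
        b_n[tissue == code] = spec.baseline_nulled[cls]
        b_nn[tissue == code] = spec.baseline_notnulled[cls]
    return b_n, b_nn


def simulate_run(spec: PhantomSpec, run_index: int = 0) -> tuple[ComplexSeries, GroundTruth]:
    """Simulate one interleaved VASO run plus its ground truth.

    The returned series holds ``2 * volumes_per_contrast_per_run`` data
    volumes (volume 0 nulled, volume 1 not-nulled, ...) followed by
    ``n_noise_volumes`` RF-off volumes of pure complex Gaussian noise with
    per-channel SD ``sigma_thermal * g(x)``.  The clean (thermal-noise-free)
    series include the trial-amplitude and physiological modulations, which
    are signal rather than thermal noise.
    """
    spec.validate()
    design = spec.design()
    tissue, depth = tissue_maps(spec)
    gmap = generate_gfactor_field(spec)
    b_n, b_nn = _baseline_maps(spec, tissue)

    # response spatial pattern: cortex only, laminar-profile weighted
    pattern = np.zeros(spec.grid_dims)
    cortex = tissue == CORTEX
    pattern[cortex] = spec.profile_shape(depth[cortex])

    n_t = spec.volumes_per_contrast_per_run
    rng_run = np.random.default_rng([spec.seed, _STREAM_RUN + run_index])

    trial_amps = 1.0 + spec.trial_amp_sd * rng_run.standard_normal(design.n_trials)
    task = design.task_indicator()
    trial_idx = design.trial_index()
    mod = np.zeros(n_t)
    mod[task] = trial_amps[trial_idx[task]]

    # one slow shared fluctuation on the interleaved timeline
    if spec.physio_sd > 0:
        raw = ndimage.gaussian_filter1d(rng_run.standard_normal(2 * n_t),
                                        sigma=8.0, mode="wrap")
        physio = spec.physio_sd * raw / raw.std()
    else:
        physio = np.zeros(2 * n_t)

    clean_nulled = (
        b_n[..., None]
        * (1.0 - spec.vaso_amplitude * pattern[..., None] * mod[None, None, None, :])
        * (1.0 + physio[0::2])[None, None, None, :]
    )
    clean_notnulled = (
        b_nn[..., None]
        * (1.0 + spec.bold_amplitude * pattern[..., None] * mod[None, None, None, :])
        * (1.0 + physio[1::2])[None, None, None, :]
    )

    # smooth static background phase, time-constant
    rng_phase = np.random.default_rng([spec.seed, _STREAM_PHASE])
    phase0 = 1.0 * _smooth_field(rng_phase, spec.grid_dims,
                                 spec.g_field_smoothness)

    total = 2 * n_t + spec.n_noise_volumes
    signal = np.zeros(spec.grid_dims + (total,), dtype=np.complex128)
    carrier = np.exp(1j * phase0)[..., None]
    signal[..., 0 : 2 * n_t : 2] = clean_nulled * carrier
    signal[..., 1 : 2 * n_t : 2] = clean_notnulled * carrier

    # CSF phase skips: affected voxels flip phase by pi on random volumes
    if spec.phase_skip_fraction > 0:
        rng_skip = np.random.default_rng([spec.seed, _STREAM_SKIP, run_index])
        csf_idx = np.argwhere(tissue == CSF)
        n_affected = int(round(spec.phase_skip_fraction * len(csf_idx)))
        if n_affected:
            chosen = csf_idx[rng_skip.choice(len(csf_idx), size=n_affected,
                                             replace=False)]
            flips = rng_skip.random((n_affected, 2 * n_t)) < 0.5
            sign = np.where(flips, -1.0, 1.0)
            signal[chosen[:, 0], chosen[:, 1], chosen[:, 2], : 2 * n_t] *= sign

    if spec.sigma_thermal > 0:
        noise = spec.sigma_thermal * gmap.values[..., None] * (
            rng_run.standard_normal(signal.shape)
            + 1j * rng_run.standard_normal(signal.shape)
        )
        signal = signal + noise

    series = ComplexSeries(signal, contrast="interleaved",
                           n_noise_volumes=spec.n_noise_volumes)

    true_psc = np.zeros(spec.grid_dims)
    true_psc[cortex] = -100.0 * spec.vaso_amplitude * pattern[cortex] * trial_amps.mean()

    truth = GroundTruth(
        clean_nulled=clean_nulled,
        clean_notnulled=clean_notnulled,
        true_psc_map=true_psc,
        depth_map=depth,
        tissue_map=tissue,
        g_map=gmap,
        design=design,
        trial_amplitudes=trial_amps,
    )
    return series, truth
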