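"""VASO-specific orchestration: strategies, BOLD correction, trial responses.

SS-SI VASO acquires blood-nulled (CBV-weighted) and not-nulled
(BOLD-weighted) volumes in an alternating fashion; volume 0 of an
interleaved series is nulled (0-based convention — "odd volumes" in 1-based
scanner counting).  Denoising can be run on the interleaved series as a
whole ("combined") or on each contrast after splitting ("separate"),
crossed with the noise-calibration source and the data domain: the
2 x 2 x 2 = 8 strategy cells, plus a no-denoise control.

BOLD correction (BOCO) divides the nulled by the not-nulled magnitude to
cancel positive BOLD contamination of the negative CBV response; trial
responses are then quantified as percent signal change (PSC) or raw
difference (delta) against the preceding rest block, discarding the first
two volumes of every block as transition periods.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .core import ComplexSeries, GFactorMap
from .denoise import (DenoiseConfig, DenoiseResult, NoiseEstimate,
                      NordicDenoiser, denoise_series)
from .phantom import DesignTable

__all__ = [
    "StrategySpec",
    "TrialPSC",
    "all_strategies",
    "split_interleaved",
    "interleave",
    "run_strategy",
    "boco",
    "trial_psc",
    "trial_delta",
    "trial_psc_map",
    "trial_delta_map",
]


@dataclass(frozen=True)
class StrategySpec:
    """One cell of the strategy matrix (or the no-denoise control)."""

    contrasts: str = "separate"  # {combined, separate}
    noise_source: str = "noise_volume"  # {noise_volume, mppca}
    data_domain: str = "magnitude"  # {complex, magnitude}
    denoise: bool = True

    def __post_init__(self) -> None:
        if self.contrasts not in ("combined", "separate"):
            raise ValueError(f"unknown contrasts {self.contrasts!r}")
        if self.noise_source not in ("noise_volume", "mppca"):
            raise ValueError(f"unknown noise_source {self.noise_source!r}")
        if self.data_domain not in ("complex", "magnitude"):
            raise ValueError(f"unknown data_domain {self.data_domain!r}")

    @classmethod
    def control(cls) -> "StrategySpec":
        """The non-denoised reference version."""
        return cls(denoise=False)

    @property
    def name(self) -> str:
        if not self.denoise:
            return "control"
        noise = "noisevol" if self.noise_source == "noise_volume" else "mppca"
        return f"{self.contrasts}-{noise}-{self.data_domain}"


def all_strategies(include_control: bool = True) -> list[StrategySpec]:
    """The eight strategy cells (plus the control when requested)."""
    cells = [
        StrategySpec(contrasts=c, noise_source=n, data_domain=d)
        for c, n, d in itertools.product(
            ("combined", "separate"), ("noise_volume", "mppca"),
            ("complex", "magnitude"))
    ]
    if include_control:
        cells.append(StrategySpec.control())
    return cells


def split_interleaved(series: ComplexSeries) -> tuple[ComplexSeries, ComplexSeries]:
    """Split an interleaved series into nulled / not-nulled contrasts.

    Volume 0 is nulled.  Trailing noise volumes are attached to both
    outputs so each contrast can calibrate its own threshold.
    """
    n_data = series.n_data_volumes
    if n_data % 2:
        raise ValueError(
            f"interleaved series must hold an even number of data volumes, got {n_data}"
        )
    noise = series.noise_volumes
    nulled_vals = np.concatenate([series.data[..., 0::2], noise], axis=-1)
    notnulled_vals = np.concatenate([series.data[..., 1::2], noise], axis=-1)
    nulled = series.copy_with(nulled_vals, contrast="nulled",
                              n_noise_volumes=series.n_noise_volumes)
    notnulled = series.copy_with(notnulled_vals, contrast="notnulled",
                                 n_noise_volumes=series.n_noise_volumes)
    return nulled, notnulled


def interleave(nulled: ComplexSeries, notnulled: ComplexSeries) -> ComplexSeries:
    """Re-interleave two contrasts; inverse of :func:`split_interleaved`."""
    if nulled.n_data_volumes != notnulled.n_data_volumes:
        raise ValueError("contrasts must have equal numbers of data volumes")
    n = nulled.n_data_volumes
    out = np.empty(nulled.grid_dims + (2 * n + nulled.n_noise_volumes,),
                   dtype=np.result_type(nulled.values, notnulled.values))
    out[..., 0 : 2 * n : 2] = nulled.data
    out[..., 1 : 2 * n : 2] = notnulled.data
    out[..., 2 * n :] = nulled.noise_volumes
    return nulled.copy_with(out, contrast="interleaved",
                            n_noise_volumes=nulled.n_noise_volumes)


def _identity_result(series: ComplexSeries, config: DenoiseConfig,
                     gmap: GFactorMap | None) -> DenoiseResult:
    """No-denoise control packaged as a DenoiseResult."""
    if gmap is None:
        gmap = GFactorMap(np.ones(series.grid_dims))
    denoised = series.copy_with(series.data.copy(), n_noise_volumes=0,
                                validate=False)
    removed = series.copy_with(np.zeros_like(series.data), n_noise_volumes=0,
                               validate=False)
    estimate = NoiseEstimate(sigma=0.0, method="control", threshold=0.0,
                             n_volumes=series.n_data_volumes)
    kept = np.full(series.grid_dims, float(series.n_data_volumes))
    return DenoiseResult(denoised=denoised, removed=removed,
                         noise_estimate=estimate, components_kept_map=kept,
                         gmap=gmap, config=config)


def _split_result(res: DenoiseResult, parity: int, contrast: str) -> DenoiseResult:
    denoised = res.denoised.copy_with(res.denoised.values[..., parity::2],
                                      contrast=contrast, n_noise_volumes=0)
    removed = res.removed.copy_with(res.removed.values[..., parity::2],
                                    contrast=contrast, n_noise_volumes=0)
    return DenoiseResult(denoised=denoised, removed=removed,
                         noise_estimate=res.noise_estimate,
                         components_kept_map=res.components_kept_map,
                         gmap=res.gmap, config=res.config)


def run_strategy(series: ComplexSeries, strategy: StrategySpec,
                 config: DenoiseConfig | None = None,
                 gmap: GFactorMap | None = None
                 ) -> tuple[DenoiseResult, DenoiseResult]:
    """Apply one strategy cell to an interleaved run.

    Combined: denoise the full interleaved series (default patch size from
    the total data-volume count), then split.  Separate: split first and
    denoise each contrast independently (patch size from the per-contrast
    count).  Returns (nulled, notnulled) results.
    """
    if config is None:
        config = DenoiseConfig()
    if not strategy.denoise:
        nulled, notnulled = split_interleaved(series)
        return (_identity_result(nulled, config, gmap),
                _identity_result(notnulled, config, gmap))
    config = replace(config, data_domain=strategy.data_domain,
                     noise_source=strategy.noise_source)
    if strategy.contrasts == "combined":
        res = denoise_series(series, config, gmap)
        return (_split_result(res, 0, "nulled"), _split_result(res, 1, "notnulled"))
    nulled, notnulled = split_interleaved(series)
    return (denoise_series(nulled, config, gmap),
            denoise_series(notnulled, config, gmap))


def boco(nulled: ComplexSeries, notnulled: ComplexSeries,
         invert_sign: bool = True) -> ComplexSeries:
    """BOLD-corrected VASO: divide nulled by not-nulled magnitudes.

    Each nulled volume is divided by the concurrently acquired not-nulled
    volume; divisors below 5% of the median not-nulled baseline are clamped
    to that floor to avoid division by values close to 0.  With
    ``invert_sign`` the series is reflected about its temporal mean so that
    activation (a CBV increase) plots positive.
    """
    if nulled.n_data_volumes != notnulled.n_data_volumes:
        raise ValueError("contrasts must have equal numbers of data volumes")
    num = np.abs(nulled.data) if nulled.has_phase else nulled.data
    den = np.abs(notnulled.data) if notnulled.has_phase else notnulled.data
    baseline = den.mean(axis=-1)
    positive = baseline[baseline > 0]
    eps = 0.05 * float(np.median(positive)) if positive.size else 1e-12
    vaso = num / np.maximum(den, eps)
    if invert_sign:
        vaso = 2.0 * vaso.mean(axis=-1, keepdims=True) - vaso
    return nulled.copy_with(vaso, contrast="vaso", n_noise_volumes=0,
                            validate=False)


def _float_data(series: ComplexSeries | np.ndarray) -> np.ndarray:
    """Real-valued (..., T) data array of a series (magnitude if complex)."""
    if isinstance(series, ComplexSeries):
        vals = series.data
    else:
        vals = np.asarray(series)
    if np.iscomplexobj(vals):
        vals = np.abs(vals)
    return vals


def _block_mean(ts: np.ndarray, onset: int, dur: int, n_discard: int) -> np.ndarray:
    """Mean over a block's volumes after dropping the first n_discard."""
    if dur <= n_discard:
        raise ValueError(
            f"block of {dur} volumes leaves nothing after discarding {n_discard}"
        )
    return ts[..., onset + n_discard : onset + dur].mean(axis=-1)


def _trial_task_rest(ts: np.ndarray, design: DesignTable, n_discard: int,
                     rest_reference: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial task and rest means; time is the last axis of ``ts``.

    ``rest_reference='preceding'`` pairs each task block with the rest block
    immediately before it; ``'run'`` uses the mean over all rest blocks.
    """
    if ts.shape[-1] != design.volumes_per_contrast:
        raise ValueError(
            f"series length {ts.shape[-1]} does not match the design "
            f"({design.volumes_per_contrast} volumes)"
        )
    task_means, rest_means = [], []
    if rest_reference == "run":
        run_rest = np.mean(
            [_block_mean(ts, o, d, n_discard) for o, d, _ in design.rest_blocks],
            axis=0,
        )
    prev_rest = None
    for onset, dur, cond in design.blocks:
        if cond == "rest":
            prev_rest = _block_mean(ts, onset, dur, n_discard)
        else:
            if rest_reference == "preceding":
                if prev_rest is None:
                    raise ValueError("task block with no preceding rest block")
                rest_means.append(prev_rest)
            elif rest_reference == "run":
                rest_means.append(run_rest)
            else:
                raise ValueError(f"unknown rest_reference {rest_reference!r}")
            task_means.append(_block_mean(ts, onset, dur, n_discard))
    return np.stack(task_means, axis=-1), np.stack(rest_means, axis=-1)


@dataclass
class TrialPSC:
    """Per-trial percent signal change of an ROI-averaged series."""

    values: np.ndarray  # (n_trials,)
    run_labels: np.ndarray  # run index per trial
    contrast: str = "vaso"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.run_labels = np.asarray(self.run_labels)
        if self.values.shape != self.run_labels.shape:
            raise ValueError("values and run_labels must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trial PSC values must be finite")


def trial_psc(series: ComplexSeries | np.ndarray, roi_mask: np.ndarray,
              design: DesignTable, n_discard: int = 2,
              rest_reference: str = "preceding", run_index: int = 0,
              contrast: str = "vaso") -> TrialPSC:
    """Trial-wise percent signal change of the ROI-averaged series.

    The series is averaged across ROI voxels first; each trial's PSC is
    100 * (task mean - rest mean) / rest mean with the first ``n_discard``
    volumes of every block removed (transition periods).
    """
    vals = _float_data(series)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise ValueError("ROI mask is empty")
    ts = vals[roi_mask].mean(axis=0)
    task, rest = _trial_task_rest(ts, design, n_discard, rest_reference)
    psc = 100.0 * (task - rest) / rest
    return TrialPSC(values=psc, run_labels=np.full(design.n_trials, run_index),
                    contrast=contrast)


def trial_delta(series: ComplexSeries | np.ndarray, roi_mask: np.ndarray,
                design: DesignTable, n_discard: int = 2,
                rest_reference: str = "preceding") -> np.ndarray:
    """Trial-wise raw difference (task mean - rest mean) of the ROI mean.

    Same contrast as :func:`trial_psc` but without the baseline division —
    the right quantity near zero baselines (laminar VASO profiles).
    """
    vals = _float_data(series)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise ValueError("ROI mask is empty")
    ts = vals[roi_mask].mean(axis=0)
    task, rest = _trial_task_rest(ts, design, n_discard, rest_reference)
    return task - rest


def trial_psc_map(series: ComplexSeries | np.ndarray, design: DesignTable,
                  n_discard: int = 2, rest_reference: str = "preceding"
                  ) -> np.ndarray:
    """Per-voxel trial PSCs, shape ``grid + (n_trials,)``."""
    vals = _float_data(series)
    task, rest = _trial_task_rest(vals, design, n_discard, rest_reference)
    with np.errstate(divide="ignore", invalid="ignore"):
        return 100.0 * (task - rest) / rest


def trial_delta_map(series: ComplexSeries | np.ndarray, design: DesignTable,
                    n_discard: int = 2, rest_reference: str = "preceding"
                    ) -> np.ndarray:
    """Per-voxel trial deltas, shape ``grid + (n_trials,)``."""
    vals = _float_data(series)
    task, rest = _trial_task_rest(vals, design, n_discard, rest_reference)
    return task - rest
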