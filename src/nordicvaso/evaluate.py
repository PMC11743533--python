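"""Evaluation battery for denoising quality.

Covers the degree of noise removal (tSNR and t-value maps), signal
preservation (ROI PSC bias, split-half voxel selection, trial-series
correlation), spatial structure of the removed component (mean difference
image, spatial autocorrelation, task-locked delta), laminar profiles with
trial subsampling, and the paired-test / Holm-Bonferroni statistics used to
compare strategy versions.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import ComplexSeries, GFactorMap
from .phantom import DesignTable
from .pipeline import TrialPSC, _float_data, trial_delta_map

__all__ = [
    "StatsConfig",
    "LaminarProfile",
    "tsnr_map",
    "tvalue_map",
    "roi_metrics",
    "compare_versions",
    "holm_bonferroni",
    "split_half_selection",
    "trial_series_correlation",
    "removed_structure",
    "laminar_profile",
    "subsample_profiles",
]


@dataclass
class StatsConfig:
    """Significance level and multiple-comparison method."""

    alpha: float = 0.05
    method: str = "holm"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class LaminarProfile:
    """Depth-binned response deltas with dispersion and voxel counts."""

    bin_centers: np.ndarray
    delta_mean: np.ndarray
    delta_se: np.ndarray
    n_voxels: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.bin_centers) > 0):
            raise ValueError("bins must be ordered by depth")
        if np.any(self.n_voxels <= 0):
            raise ValueError("reported bins must contain voxels")

    def plot(self, ax=None, label: str | None = None, **kwargs):
        """Depth profile with across-voxel standard-error band."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        line, = ax.plot(self.bin_centers, self.delta_mean, label=label,
                        **kwargs)
        ax.fill_between(self.bin_centers, self.delta_mean - self.delta_se,
                        self.delta_mean + self.delta_se,
                        color=line.get_color(), alpha=0.25, linewidth=0)
        ax.set_xlabel("cortical depth (0 = deep, 1 = superficial)")
        ax.set_ylabel("response delta")
        return ax


def tsnr_map(series: ComplexSeries | np.ndarray, detrend_order: int = 1) -> np.ndarray:
    """Temporal SNR: mean of the raw series over SD of detrended residuals.

    Detrending fits a per-voxel polynomial of the given order in time.
    Voxels with zero residual SD (e.g. an exactly linear drift at order 1)
    are flagged NaN for downstream masking.
    """
    ts = _float_data(series)
    n_t = ts.shape[-1]
    if n_t < detrend_order + 2:
        raise ValueError("need at least detrend_order + 2 volumes")
    t = np.arange(n_t, dtype=float)
    design = np.polynomial.polynomial.polyvander(t, detrend_order)
    flat = ts.reshape(-1, n_t).T  # (T, nvox)
    coef, *_ = np.linalg.lstsq(design, flat, rcond=None)
    resid = flat - design @ coef
    sd = resid.std(axis=0, ddof=detrend_order + 1).reshape(ts.shape[:-1])
    mean = ts.mean(axis=-1)
    # residuals that vanish to rounding (perfect polynomial fit) are flagged
    rms = np.sqrt(np.mean(ts**2, axis=-1))
    sd = np.where(sd <= 1e-8 * rms, 0.0, sd)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = mean / sd
    out[~np.isfinite(out)] = np.nan
    return out


def tvalue_map(trial_values: np.ndarray) -> np.ndarray:
    """One-sample t statistic of per-voxel trial responses against 0.

    ``trial_values`` has trials on the last axis (e.g. the output of
    :func:`nordicvaso.pipeline.trial_psc_map`).  Zero-variance voxels are
    flagged NaN.
    """
    vals = np.asarray(trial_values, dtype=float)
    n = vals.shape[-1]
    if n < 2:
        raise ValueError("need at least 2 trials")
    mean = vals.mean(axis=-1)
    sd = vals.std(axis=-1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[~np.isfinite(t)] = np.nan
    return t


def roi_metrics(version: str, run: int, nulled: ComplexSeries | np.ndarray,
                trial_psc: TrialPSC, roi_mask: np.ndarray,
                detrend_order: int = 1) -> dict:
    """One long-format metric row: ROI-mean tSNR, run |t|, and mean PSC."""
    tsnr = tsnr_map(nulled, detrend_order)
    roi = np.asarray(roi_mask, dtype=bool)
    vals = trial_psc.values
    t_run = stats.ttest_1samp(vals, 0.0).statistic if vals.std(ddof=1) > 0 else np.nan
    return {
        "version": version,
        "run": run,
        "tsnr": float(np.nanmean(tsnr[roi])),
        "abs_t": float(abs(t_run)) if np.isfinite(t_run) else np.nan,
        "psc": float(vals.mean()),
    }


def holm_bonferroni(pvalues: np.ndarray) -> np.ndarray:
    """Holm-Bonferroni adjusted p-values (step-down Bonferroni)."""
    p = np.asarray(pvalues, dtype=float)
    return multipletests(p, method="holm")[1]


def _paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Paired two-sided t-test with the degenerate-difference conventions.

    Identically-zero differences give (t=nan, p=1); constant non-zero
    differences give (t=nan flagged, p=0).
    """
    diff = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    if diff.size < 2:
        raise ValueError("need at least 2 paired observations")
    if diff.std(ddof=1) == 0:
        if np.allclose(diff, 0):
            return np.nan, 1.0
        return np.nan, 0.0
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def compare_versions(table: pd.DataFrame, stats_config: StatsConfig | None = None,
                     metrics: tuple[str, ...] = ("tsnr", "abs_t", "psc")
                     ) -> pd.DataFrame:
    """Pairwise paired t-tests between versions with Holm correction.

    ``table`` is long-format with columns ``version``, ``run`` and one
    column per metric; versions must share run keys.  Correction is applied
    within each metric family; the returned frame carries raw and adjusted
    p-values and significance flags at alpha.
    """
    if stats_config is None:
        stats_config = StatsConfig()
    versions = sorted(table["version"].unique())
    runs = sorted(table["run"].unique())
    wide = {m: table.pivot(index="run", columns="version", values=m)
            for m in metrics}
    for m in metrics:
        if wide[m].isna().any().any():
            raise ValueError(f"metric {m!r} missing for some version/run pairs")
    if len(runs) < 2:
        raise ValueError("need at least 2 paired runs")

    rows = []
    for metric in metrics:
        pvals = []
        pairs = list(itertools.combinations(versions, 2))
        for va, vb in pairs:
            t, p = _paired_t(wide[metric][va].values, wide[metric][vb].values)
            pvals.append(p)
            rows.append({"metric": metric, "version_a": va, "version_b": vb,
                         "t": t, "p": p})
        adj = holm_bonferroni(np.array(pvals))
        for i, (va, vb) in enumerate(pairs):
            rows[len(rows) - len(pairs) + i]["p_adj"] = adj[i]
            rows[len(rows) - len(pairs) + i]["significant"] = bool(
                adj[i] < stats_config.alpha)
    return pd.DataFrame(rows)


def split_half_selection(trial_values: np.ndarray, run_labels: np.ndarray,
                         first_runs: set | Sequence = (0, 1, 2),
                         t_threshold: float = 2.0) -> np.ndarray:
    """Voxels responding (t > threshold) in the first half of the runs.

    Selection uses only trials from ``first_runs``, leaving held-out runs
    for an unbiased PSC comparison.  Returns a boolean mask over the grid;
    an empty selection triggers a warning.
    """
    run_labels = np.asarray(run_labels)
    sel = np.isin(run_labels, list(first_runs))
    if not sel.any():
        raise ValueError("first_runs selects no trials")
    t = tvalue_map(np.asarray(trial_values)[..., sel])
    mask = np.nan_to_num(t, nan=-np.inf) > t_threshold
    if not mask.any():
        warnings.warn("split-half selection is empty", stacklevel=2)
    return mask


def trial_series_correlation(a: TrialPSC | np.ndarray,
                             b: TrialPSC | np.ndarray) -> float:
    """Pearson correlation between two per-trial response sequences."""
    va = a.values if isinstance(a, TrialPSC) else np.asarray(a, dtype=float)
    vb = b.values if isinstance(b, TrialPSC) else np.asarray(b, dtype=float)
    if va.shape != vb.shape or va.size < 3:
        raise ValueError("need equal-length sequences of at least 3 trials")
    if va.std() == 0 or vb.std() == 0:
        return np.nan
    return float(stats.pearsonr(va, vb).statistic)


def _lag1_spatial_autocorrelation(image: np.ndarray, mask: np.ndarray) -> float:
    """Average lag-1 Pearson correlation across spatial axes within a mask."""
    rs = []
    for axis in range(3):
        if image.shape[axis] < 2:
            continue
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(0, -1)
        sl_b[axis] = slice(1, None)
        pair_mask = mask[tuple(sl_a)] & mask[tuple(sl_b)]
        x = image[tuple(sl_a)][pair_mask]
        y = image[tuple(sl_b)][pair_mask]
        # relative guard: numerically-constant images have no defined r
        tol = 1e-12 * (np.abs(image[mask]).mean() + 1e-300)
        if x.size >= 3 and x.std() > tol and y.std() > tol:
            rs.append(stats.pearsonr(x, y).statistic)
    return float(np.mean(rs)) if rs else np.nan


def removed_structure(removed: ComplexSeries, gmap: GFactorMap,
                      mask: np.ndarray, design: DesignTable | None = None,
                      n_discard: int = 2
                      ) -> tuple[np.ndarray, float, np.ndarray | None]:
    """Structure of what denoising removed.

    Returns the mean removed image (for complex data the magnitude of the
    complex temporal mean difference; for magnitude data the absolute
    magnitude difference), the lag-1 spatial autocorrelation of that image
    after g-normalization within ``mask`` (unstructured noise gives values
    near 0), and — when a design is supplied — the per-voxel across-trial
    mean task delta of the removed series (task-locked removed signal).
    """
    vals = removed.data
    mean_img = np.abs(vals.mean(axis=-1))
    g_normed = mean_img / gmap.values
    autocorr = _lag1_spatial_autocorrelation(g_normed, np.asarray(mask, bool))
    delta_map = None
    if design is not None:
        # delta on the real-valued removed series (magnitude for complex)
        deltas = trial_delta_map(np.abs(vals) if np.iscomplexobj(vals) else vals,
                                 design, n_discard=n_discard)
        delta_map = deltas.mean(axis=-1)
    return mean_img, autocorr, delta_map


def laminar_profile(delta_map: np.ndarray, depth_map: np.ndarray,
                    roi_mask: np.ndarray, n_bins: int = 11) -> LaminarProfile:
    """Bin voxel deltas by cortical depth into equal-width bins.

    Per-bin mean and standard error are computed across voxels; empty bins
    are dropped with a warning.
    """
    roi = np.asarray(roi_mask, bool) & np.isfinite(depth_map)
    if not roi.any():
        raise ValueError("no ROI voxels with defined depth")
    depth = np.clip(depth_map[roi], 0.0, np.nextafter(1.0, 0.0))
    delta = np.asarray(delta_map, dtype=float)[roi]
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.digitize(depth, edges) - 1
    centers, means, ses, counts = [], [], [], []
    for b in range(n_bins):
        vals = delta[idx == b]
        if vals.size == 0:
            warnings.warn(f"depth bin {b} is empty; dropped", stacklevel=2)
            continue
        centers.append(0.5 * (edges[b] + edges[b + 1]))
        means.append(vals.mean())
        ses.append(vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else 0.0)
        counts.append(vals.size)
    return LaminarProfile(bin_centers=np.array(centers),
                          delta_mean=np.array(means),
                          delta_se=np.array(ses),
                          n_voxels=np.array(counts))


def subsample_profiles(trial_deltas: np.ndarray, depth_map: np.ndarray,
                       roi_mask: np.ndarray, factors: Sequence[int] = (1, 2, 6),
                       n_bins: int = 11
                       ) -> dict[int, dict]:
    """Laminar profiles from modular trial subsets (stability analysis).

    For subsampling factor ``f`` the trials (1-based) split into the ``f``
    subsets {k : k = r mod f}; each subset yields one profile from its
    across-trial mean delta.  The per-scheme ``dispersion`` is the mean
    across depth bins of the SD of bin means across subsets (0 for f = 1).
    """
    trial_deltas = np.asarray(trial_deltas, dtype=float)
    n_trials = trial_deltas.shape[-1]
    out: dict[int, dict] = {}
    for f in factors:
        if f > n_trials:
            raise ValueError(f"subsampling factor {f} exceeds {n_trials} trials")
        profiles = []
        for r in range(f):
            subset = trial_deltas[..., r::f].mean(axis=-1)
            profiles.append(laminar_profile(subset, depth_map, roi_mask, n_bins))
        bin_matrix = np.array([p.delta_mean for p in profiles])
        dispersion = float(bin_matrix.std(axis=0, ddof=0).mean()) if f > 1 else 0.0
        out[f] = {"profiles": profiles, "dispersion": dispersion}
    return out
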