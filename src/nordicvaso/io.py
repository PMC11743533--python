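"""NIfTI / table I/O, run configuration and the end-to-end orchestrator.

All image I/O is NIfTI-1 via nibabel (magnitude and phase stored as
separate files, phase in radians in (-pi, pi]); designs and trial tables
are plain tab-separated files; the run manifest is JSON and records every
seed and configuration so a run can be reproduced bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import ComplexSeries, GFactorMap, wrap_phase
from .denoise import DenoiseConfig, denoise_series
from .evaluate import StatsConfig, compare_versions, roi_metrics
from .phantom import DesignTable, PhantomSpec, simulate_run
from .pipeline import StrategySpec, all_strategies, boco, run_strategy, \
    trial_delta, trial_psc

logger = logging.getLogger("nordicvaso")

__all__ = [
    "read_series",
    "write_series",
    "read_gfactor",
    "write_gfactor",
    "read_design",
    "write_design",
    "RunManifest",
    "run_all",
]


def _affine(voxel_size) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def read_series(mag_path: str | Path, phase_path: str | Path | None = None,
                n_noise_volumes: int = 0, contrast: str = "interleaved"
                ) -> ComplexSeries:
    """Load a magnitude (+ optional phase) NIfTI pair as a ComplexSeries.

    Grids must match; phase is rewrapped into (-pi, pi].  Trailing noise
    volumes are flagged, not dropped.  NaN-containing volumes raise with
    the offending file and volume index.
    """
    mag_img = nib.load(str(mag_path))
    mag = np.asarray(mag_img.dataobj, dtype=float)
    if mag.ndim != 4:
        raise ValueError(f"{mag_path}: expected a 4D series, got {mag.ndim}D")
    for name, arr in (("magnitude", mag),):
        bad = np.where(~np.isfinite(arr).all(axis=(0, 1, 2)))[0]
        if bad.size:
            raise ValueError(f"{mag_path}: non-finite values in volume {bad[0]}")
    if np.any(mag < 0):
        raise ValueError(f"{mag_path}: magnitude data must be non-negative")
    voxel_size = tuple(float(z) for z in mag_img.header.get_zooms()[:3])
    if phase_path is None:
        return ComplexSeries(mag, contrast=contrast,
                             n_noise_volumes=n_noise_volumes,
                             voxel_size=voxel_size)
    ph_img = nib.load(str(phase_path))
    ph = np.asarray(ph_img.dataobj, dtype=float)
    if ph.shape != mag.shape:
        raise ValueError(
            f"{phase_path}: phase grid {ph.shape} does not match magnitude "
            f"grid {mag.shape}"
        )
    bad = np.where(~np.isfinite(ph).all(axis=(0, 1, 2)))[0]
    if bad.size:
        raise ValueError(f"{phase_path}: non-finite values in volume {bad[0]}")
    values = mag * np.exp(1j * wrap_phase(ph))
    return ComplexSeries(values, contrast=contrast,
                         n_noise_volumes=n_noise_volumes, voxel_size=voxel_size)


def write_series(series: ComplexSeries, mag_path: str | Path,
                 phase_path: str | Path | None = None) -> None:
    """Write a series as magnitude (+ phase when complex) NIfTI-1 files."""
    aff = _affine(series.voxel_size)
    nib.save(nib.Nifti1Image(np.asarray(series.magnitude, dtype=np.float64), aff),
             str(mag_path))
    if series.has_phase and phase_path is not None:
        nib.save(nib.Nifti1Image(wrap_phase(series.phase), aff), str(phase_path))


def read_gfactor(path: str | Path) -> GFactorMap:
    img = nib.load(str(path))
    vals = np.asarray(img.dataobj, dtype=float)
    if vals.ndim == 4 and vals.shape[-1] == 1:
        vals = vals[..., 0]
    return GFactorMap(vals)


def write_gfactor(gmap: GFactorMap, path: str | Path,
                  voxel_size=(1.0, 1.0, 1.0)) -> None:
    nib.save(nib.Nifti1Image(gmap.values, _affine(voxel_size)), str(path))


def write_map(values: np.ndarray, path: str | Path,
              voxel_size=(1.0, 1.0, 1.0)) -> None:
    """Write a 3D map (tSNR, t, depth, delta, ...) as NIfTI-1."""
    nib.save(nib.Nifti1Image(np.asarray(values, dtype=np.float64),
                             _affine(voxel_size)), str(path))


def read_map(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=float)


def write_design(design: DesignTable, path: str | Path) -> None:
    pd.DataFrame(design.blocks,
                 columns=["onset_volume", "duration_volumes", "condition"]
                 ).to_csv(path, sep="\t", index=False)


def read_design(path: str | Path) -> DesignTable:
    df = pd.read_csv(path, sep="\t")
    blocks = [(int(r.onset_volume), int(r.duration_volumes), str(r.condition))
              for r in df.itertuples()]
    volumes = blocks[-1][0] + blocks[-1][1]
    n_trials = sum(1 for b in blocks if b[2] == "task")
    return DesignTable(blocks=blocks, n_trials=n_trials,
                       volumes_per_contrast=volumes)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record of one end-to-end run."""

    config: dict
    seeds: dict
    software_version: str = __version__
    input_hashes: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as f:
            json.dump(dataclasses.asdict(self), f, indent=2, default=str)

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        with open(path) as f:
            d = json.load(f)
        return cls(**d)


_CONFIG_SECTIONS = {"phantom", "denoise", "strategies", "evaluation", "output", "seed"}
_PHANTOM_KEYS = {f.name for f in dataclasses.fields(PhantomSpec)}
_DENOISE_KEYS = {f.name for f in dataclasses.fields(DenoiseConfig)}


def _validate_config(cfg: dict) -> None:
    unknown = set(cfg) - _CONFIG_SECTIONS
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    bad = set(cfg.get("phantom", {})) - _PHANTOM_KEYS
    if bad:
        raise ValueError(f"unknown phantom keys: {sorted(bad)}")
    bad = set(cfg.get("denoise", {})) - _DENOISE_KEYS
    if bad:
        raise ValueError(f"unknown denoise keys: {sorted(bad)}")
    if "output" not in cfg or "dir" not in cfg["output"]:
        raise ValueError("config must provide output.dir")


def _parse_strategies(spec) -> list[StrategySpec]:
    if spec in (None, "all"):
        return all_strategies(include_control=True)
    out = []
    for name in spec:
        if name == "control":
            out.append(StrategySpec.control())
            continue
        contrasts, noise, domain = name.split("-")
        out.append(StrategySpec(
            contrasts=contrasts,
            noise_source="noise_volume" if noise == "noisevol" else "mppca",
            data_domain=domain,
        ))
    return out


def run_all(config_path: str | Path) -> RunManifest:
    """Execute simulate -> strategy matrix -> evaluation from one config.

    The YAML config has sections ``phantom`` (PhantomSpec overrides),
    ``denoise`` (DenoiseConfig overrides), ``strategies`` ("all" or a list
    of names like ``separate-noisevol-magnitude`` plus ``control``),
    ``evaluation`` and ``output`` (with ``dir``).  Fails fast on unknown
    keys; any stage failure aborts with the stage name.
    """
    config_path = Path(config_path)
    with open(config_path) as f:
        cfg = yaml.safe_load(f) or {}
    _validate_config(cfg)

    out_dir = Path(cfg["output"]["dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log")
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    seed = int(cfg.get("seed", 0))
    phantom_cfg = dict(cfg.get("phantom", {}))
    phantom_cfg.setdefault("seed", seed)
    if "grid_dims" in phantom_cfg:
        phantom_cfg["grid_dims"] = tuple(phantom_cfg["grid_dims"])
    spec = PhantomSpec(**phantom_cfg)

    denoise_cfg = dict(cfg.get("denoise", {}))
    denoise_cfg.setdefault("seed", seed)
    if isinstance(denoise_cfg.get("patch_dims"), list):
        denoise_cfg["patch_dims"] = tuple(denoise_cfg["patch_dims"])
    base_config = DenoiseConfig(**denoise_cfg)

    strategies = _parse_strategies(cfg.get("strategies"))
    eval_cfg = dict(cfg.get("evaluation", {}))
    n_discard = int(eval_cfg.get("n_discard", 2))

    manifest = RunManifest(config=cfg, seeds={"phantom": spec.seed,
                                              "threshold": base_config.seed})

    try:
        stage = "simulate"
        logger.info("stage %s: %d runs", stage, spec.n_runs)
        runs = []
        for r in range(spec.n_runs):
            series, truth = simulate_run(spec, run_index=r)
            runs.append((series, truth))
            run_dir = out_dir / f"run{r:02d}"
            run_dir.mkdir(exist_ok=True)
            write_series(series, run_dir / "mag.nii.gz", run_dir / "phase.nii.gz")
            write_design(truth.design, run_dir / "design.tsv")
            manifest.outputs[f"run{r:02d}"] = str(run_dir)
        truth0 = runs[0][1]
        write_gfactor(truth0.g_map, out_dir / "gfactor_true.nii.gz")
        write_map(np.nan_to_num(truth0.depth_map, nan=-1.0),
                  out_dir / "depth.nii.gz")

        stage = "strategies"
        roi = truth0.roi_mask
        rows = []
        trial_rows = []
        for strat in strategies:
            logger.info("stage %s: %s", stage, strat.name)
            sdir = out_dir / strat.name
            sdir.mkdir(exist_ok=True)
            for r, (series, truth) in enumerate(runs):
                res_n, res_nn = run_strategy(series, strat, base_config)
                vaso = boco(res_n.denoised, res_nn.denoised)
                psc = trial_psc(vaso, roi, truth.design, n_discard=n_discard,
                                run_index=r)
                delta = trial_delta(vaso, roi, truth.design, n_discard=n_discard)
                rows.append(roi_metrics(strat.name, r, res_n.denoised, psc, roi))
                for j, (p, d) in enumerate(zip(psc.values, delta)):
                    trial_rows.append({"version": strat.name, "run": r,
                                       "trial": j, "psc": p, "delta": d})
                if r == 0:
                    write_series(vaso, sdir / "vaso_run00.nii.gz")
            manifest.outputs[strat.name] = str(sdir)

        stage = "evaluate"
        metric_table = pd.DataFrame(rows)
        metric_table.to_csv(out_dir / "metrics.tsv", sep="\t", index=False)
        pd.DataFrame(trial_rows).to_csv(out_dir / "trials.tsv", sep="\t",
                                        index=False)
        if metric_table["version"].nunique() >= 2 and spec.n_runs >= 2:
            comparisons = compare_versions(
                metric_table, StatsConfig(alpha=float(eval_cfg.get("alpha", 0.05))))
            comparisons.to_csv(out_dir / "comparisons.tsv", sep="\t", index=False)
            manifest.outputs["comparisons"] = str(out_dir / "comparisons.tsv")
        manifest.outputs["metrics"] = str(out_dir / "metrics.tsv")
        manifest.outputs["trials"] = str(out_dir / "trials.tsv")
    except Exception as exc:
        logger.error("stage %s failed: %s (partial outputs in %s)",
                     stage, exc, out_dir)
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()

    manifest.input_hashes[str(config_path)] = _sha256(config_path)
    manifest.save(out_dir / "manifest.json")
    manifest.outputs["manifest"] = str(out_dir / "manifest.json")
    return manifest
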