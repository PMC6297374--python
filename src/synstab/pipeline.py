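"""End-to-end orchestration: preprocess -> synergies -> embedding ->
Lyapunov -> Floquet -> speed trends, from one configuration.

Every stage's effective parameters, derived seeds and output files are
echoed into a JSON run manifest, and all randomness flows from one master
seed through deterministic per-stage substreams, so identical config +
seed reproduces byte-identical result tables.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, fields as _dc_fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import emg_preprocess as prep
from . import synergy_nmf as nmf_mod
from . import synthetic_data as synth
from .floquet import floquet_from_series
from .lyapunov import lyapunov_from_series
from .speed_trends import DEFAULT_BANDS, increasing_rates
from .state_embedding import UNIFIED_DIMENSION, select_delay

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "analyze_trial"]

_VERSION = "0.1.0"


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Parameters for a full run; defaults follow the analysis conventions."""

    # inputs: either file paths or a simulate preset
    emg_path: str | None = None
    events_path: str | None = None
    fs: float = 1000.0
    preset: str | None = None            # "gait" generates synthetic trials
    speeds: tuple[float, ...] = (2.0, 3.5, 5.0, 6.5, 8.0)

    # preprocessing
    highpass_hz: float = 40.0
    lowpass_hz: float = 10.0
    drop_head: int = 10
    drop_tail: int = 10
    keep_cycles: int = 30

    # synergy extraction / selection
    n_min: int = 1
    n_max: int = 12
    n_repeats: int = 10
    n_restarts: int = 2
    nmf_max_iter: int = 500
    global_threshold: float = 90.0
    muscle_threshold: float = 75.0
    fixed_n_synergies: int | None = None  # skip CV selection when set

    # embedding
    ami_bins: int = 16
    dimension_override: int | None = UNIFIED_DIMENSION

    # stability
    theiler_window: int = 100
    horizon: int = 1000
    floquet_policy: str = "mean"

    # trends
    bands: dict = field(default_factory=lambda: dict(DEFAULT_BANDS))

    seed: int = 0
    out_dir: str = "synstab_out"

    def stage_seed(self, stage: str, extra: int | str = 0) -> int:
        """Deterministic per-stage substream of the master seed (< 2^31)."""
        h = hashlib.sha256(f"{self.seed}:{stage}:{extra}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2 ** 31 - 1)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a config file; keyword arguments (CLI flags) override it."""
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise PipelineError("config", f"{path} must contain a mapping")
        known = {f.name for f in _dc_fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineError("config", f"unknown keys in {path}: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "speeds" in data:
            data["speeds"] = tuple(data["speeds"])
        return cls(**data)


def _preset_matrix(config: PipelineConfig, speed: float) -> tuple[prep.EmgMatrix, dict]:
    """Simulate and preprocess one synthetic trial.

    The cycle-to-cycle variability scale grows linearly with the nominal
    speed label, giving the sweep a speed-like axis.
    """
    scale = 0.5 + 0.25 * (speed - 2.0)   # 0.5x variability at 2 km/h -> 2x at 8
    cfg = synth.SynthConfig(
        phase_jitter_sd=1.0 * scale,
        amp_noise_sd=0.10 * scale,
        seed=config.stage_seed("simulate", int(speed * 10)),
    )
    rec, truth = synth.synthesize_raw_recording(cfg)
    matrix = prep.preprocess(rec, config.highpass_hz, config.lowpass_hz,
                             config.drop_head, config.drop_tail,
                             config.keep_cycles)
    return matrix, truth


def analyze_trial(
    matrix: prep.EmgMatrix,
    config: PipelineConfig,
    trial: str = "trial",
) -> dict:
    """Synergy extraction + stability analysis of one preprocessed matrix."""
    M = matrix.values
    seed = config.stage_seed("synergies", trial)
    if config.fixed_n_synergies is not None:
        n_selected = config.fixed_n_synergies
        vaf_frame = None
    else:
        table = nmf_mod.cross_validated_vaf(
            M, range(config.n_min, config.n_max + 1),
            n_repeats=config.n_repeats, seed=seed, muscles=matrix.muscles,
            n_restarts=config.n_restarts, max_iter=config.nmf_max_iter,
        )
        n_selected = nmf_mod.select_num_synergies(
            table, config.global_threshold, config.muscle_threshold)
        vaf_frame = table.to_frame()
    fit = nmf_mod.nmf(M, n_selected, seed=seed, n_restarts=20,
                      max_iter=config.nmf_max_iter)

    rows = []
    for i in range(n_selected):
        x = fit.C[i]
        tau, fallback = select_delay(x, n_bins=config.ami_bins)
        d = config.dimension_override or UNIFIED_DIMENSION
        lres, _ = lyapunov_from_series(
            x, tau=tau, d=d, theiler_window=config.theiler_window,
            horizon=config.horizon)
        fres = floquet_from_series(x, tau=tau, d=d, policy=config.floquet_policy)
        rows.append({
            "trial": trial, "synergy": i + 1, "tau": tau,
            "tau_fallback": fallback, "d_E": d,
            "lambda_star": lres.lambda_star, "lambda_units": "nats/stride",
            "fit_r2": lres.fit_r2,
            "fm_mean": fres.fm_mean, "fm_max": fres.fm_max,
            "orbitally_stable": fres.orbitally_stable,
            "n_flags": len(fres.flags),
        })
    return {
        "n_synergies": n_selected,
        "synergy_set": fit,
        "vaf_table": vaf_frame,
        "stability": pd.DataFrame(rows),
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write the manifest plus result CSVs."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": _VERSION,
        "seed": config.seed,
        "config": {k: v for k, v in asdict(config).items()},
        "stages": {},
        "units": {"lambda_star": "nats/stride", "floquet_multiplier": "dimensionless"},
    }

    # ---- stage: input / simulate / preprocess
    trials: list[tuple[str, float, prep.EmgMatrix]] = []
    if config.preset == "gait":
        for speed in config.speeds:
            matrix, _ = _preset_matrix(config, speed)
            trials.append((f"gait_{speed:.1f}kmh", speed, matrix))
        manifest["stages"]["simulate"] = {"preset": "gait",
                                          "speeds": list(config.speeds)}
    elif config.emg_path is not None:
        if config.events_path is None or not Path(config.events_path).exists():
            raise PipelineError("preprocess",
                                f"events file not found: {config.events_path}")
        if not Path(config.emg_path).exists():
            raise PipelineError("preprocess",
                                f"EMG file not found: {config.emg_path}")
        events = prep.read_events_csv(config.events_path)
        rec = prep.read_emg_csv(config.emg_path, config.fs, events)
        matrix = prep.preprocess(rec, config.highpass_hz, config.lowpass_hz,
                                 config.drop_head, config.drop_tail,
                                 config.keep_cycles)
        trials.append((Path(config.emg_path).stem, float("nan"), matrix))
    else:
        raise PipelineError("preprocess", "neither input files nor a preset given")

    for name, _, matrix in trials:
        matrix.to_csv(out / f"{name}_matrix.csv")
        matrix.save_normalization(out / f"{name}_normalization.json")
    manifest["stages"]["preprocess"] = {
        "trials": [n for n, _, _ in trials],
        "keep_cycles": config.keep_cycles,
        "time_steps": int(trials[0][2].T),
    }

    # ---- stages: synergies + embedding + stability per trial
    stab_frames = []
    n_selected = {}
    for name, speed, matrix in trials:
        try:
            res = analyze_trial(matrix, config, trial=name)
        except nmf_mod.NoSelectionError as exc:
            raise PipelineError("synergies", f"{name}: {exc}") from exc
        n_selected[name] = res["n_synergies"]
        pd.DataFrame(res["synergy_set"].W, index=matrix.muscles).to_csv(
            out / f"{name}_W.csv", header=False)
        pd.DataFrame(res["synergy_set"].C).to_csv(out / f"{name}_C.csv",
                                                  header=False)
        if res["vaf_table"] is not None:
            res["vaf_table"].to_csv(out / f"{name}_vaf.csv", index=False)
        df = res["stability"].copy()
        df.insert(1, "speed", speed)
        stab_frames.append(df)
    stability = pd.concat(stab_frames, ignore_index=True)
    stability.to_csv(out / "stability.csv", index=False, float_format="%.10g")
    manifest["stages"]["synergies"] = {"n_selected": n_selected}
    manifest["stages"]["embedding"] = {
        "dimension": config.dimension_override or UNIFIED_DIMENSION,
        "tau_per_trial_synergy": stability[["trial", "synergy", "tau"]]
        .to_dict("records"),
    }
    manifest["stages"]["lyapunov"] = {
        "theiler_window": config.theiler_window,
        "fit_window_samples": [0, 100],
        "n_results": int(len(stability)),
    }
    manifest["stages"]["floquet"] = {
        "policy": config.floquet_policy, "n_sections": 100,
        "n_results": int(len(stability)),
    }

    # ---- stage: trends (needs >= 2 distinct speeds in each band)
    trend_info: dict = {"computed": False}
    speeds = stability["speed"].dropna().unique()
    if len(speeds) >= 2:
        df = stability.rename(columns={"trial": "subject"})
        try:
            trends = increasing_rates(df, config.bands)
            trends.to_csv(out / "trends.csv", index=False, float_format="%.10g")
            trend_info = {"computed": True, "bands": config.bands}
        except Exception as exc:  # single-speed bands etc.
            trend_info = {"computed": False, "reason": str(exc)}
    manifest["stages"]["trends"] = trend_info

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
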