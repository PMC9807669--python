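"""End-to-end pipeline: simulate -> preprocess -> components -> fits -> stats.

``run_pipeline`` executes the full analysis on synthetic cohorts of
control and rod/cone-transducin double-knockout (DKO) animals:

1. simulate an LED intensity series (sweep sets per animal x dose),
   a saturating stacked LED+laser protocol, and photopic ERGs;
2. SNR-gated sweep averaging;
3. P1/N1/P2 component metrics (latency, P1N1 amplitude) and ERG
   features;
4. integrated power, per-animal normalization, pooled and per-animal
   Naka-Rushton fits;
5. unpaired t-tests on maximal amplitude, saturation amplitude ratio,
   and fitted parameters.

Every artifact is written as plain text together with a manifest
recording the configuration hash, seed and software version; identical
configuration and seed produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import replace
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .components import detect_components, detect_erg_features
from .group_compare import amplitude_ratio, unpaired_t_test
from .io import write_tidy_metrics
from .preprocess import AveragedWaveform, average_sweeps
from .response_curve import fit_response_table, normalize_by_animal, vep_power
from .synthetic import PRESETS, SyntheticConfig, simulate_erg_sweeps, simulate_stacked_sweeps, simulate_vep_sweeps

__all__ = ["DEFAULT_CONFIG", "ConfigError", "validate_config", "run_pipeline"]


class ConfigError(ValueError):
    """Invalid or unknown pipeline configuration key."""


DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "simulate": {
        "genotypes": ["control", "dko"],
        # 9 half-log-spaced doses across the 4-decade LED series
        "doses_photons_um2": [float(d) for d in np.logspace(3, 7, 9)],
        "n_animals": 4,
        "n_sweeps": 20,
        "n_laser_sweeps": 7,
        "noise_sd_uv": 15.0,
        "artifact_amp_uv": 200.0,
        "sample_rate_hz": 50_000.0,
        "pre_s": 0.2,
        "post_s": 0.6,
        "amplitude_cv": 0.25,
        "latency_jitter_s": 0.005,
        "erg": {"enabled": True, "n_animals": 5},
        "saturation": {
            "enabled": True,
            "laser_dose_photons_um2": 1.4e6,
            "led_dose_photons_um2": 1.0e7,
        },
    },
    "preprocess": {
        "snr_threshold": 1.0,
        "baseline_window_s": 0.1,
        "response_window_s": 0.4,
    },
    "components": {"search_window_s": 0.4, "k_sigma": 3.0, "blank_s": 0.01},
    "fit": {"mode": "both", "min_intensities_per_animal": 4},
    "compare": {"equal_variance": True, "alpha": 0.05},
}


def _merge(default: dict, override: dict, path: str = "") -> dict:
    out = dict(default)
    for key, value in override.items():
        here = f"{path}.{key}" if path else key
        if key not in default:
            raise ConfigError(f"unknown configuration key {here!r}")
        if isinstance(default[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"configuration key {here!r} must be a mapping")
            out[key] = _merge(default[key], value, here)
        else:
            out[key] = value
    return out


def validate_config(config: dict | None) -> dict:
    """Merge a (possibly partial) config over the defaults; unknown keys
    raise :class:`ConfigError` before any computation."""
    return _merge(DEFAULT_CONFIG, config or {})


def _animal_rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([seed, *key])


def _animal_effects(
    rng: np.random.Generator, amplitude_cv: float, latency_jitter_s: float
) -> tuple[float, float]:
    gain = float(np.exp(rng.normal(0.0, amplitude_cv))) if amplitude_cv > 0 else 1.0
    jitter = float(rng.normal(0.0, latency_jitter_s)) if latency_jitter_s > 0 else 0.0
    return gain, jitter


def _laser_window_view(avg: AveragedWaveform, laser_onset_s: float) -> AveragedWaveform:
    """Re-reference an averaged stacked record to the laser onset."""
    return AveragedWaveform(
        trace=avg.trace,
        sample_rate_hz=avg.sample_rate_hz,
        onset_s=avg.onset_s + laser_onset_s,
        n_included=avg.n_included,
        n_excluded=avg.n_excluded,
        baseline_uv=avg.baseline_uv,
        meta=avg.meta,
    )


def run_pipeline(config: dict | None = None, out_dir: str | Path | None = None) -> dict[str, Any]:
    """Run the full synthetic-cohort analysis.

    Returns a dict with DataFrames ``metrics`` (tidy long format),
    ``fits``, ``comparisons``, ``erg`` and the ``manifest`` dict.  When
    ``out_dir`` is given, all tables are also written there as CSV plus
    ``manifest.json``.
    """
    cfg = validate_config(config)
    seed = int(cfg["seed"])
    sim = cfg["simulate"]
    pre_cfg = cfg["preprocess"]
    comp_cfg = cfg["components"]
    doses = [float(d) for d in sim["doses_photons_um2"]]
    genotypes = list(sim["genotypes"])

    base_kwargs = dict(
        sample_rate_hz=float(sim["sample_rate_hz"]),
        n_sweeps=int(sim["n_sweeps"]),
        pre_s=float(sim["pre_s"]),
        post_s=float(sim["post_s"]),
        noise_sd_uv=float(sim["noise_sd_uv"]),
        artifact_amp_uv=float(sim["artifact_amp_uv"]),
    )
    avg_kwargs = dict(
        snr_threshold=float(pre_cfg["snr_threshold"]),
        response_window_s=float(pre_cfg["response_window_s"]),
        baseline_window_s=float(pre_cfg["baseline_window_s"]),
    )
    detect_kwargs = dict(
        search_window_s=float(comp_cfg["search_window_s"]),
        k_sigma=float(comp_cfg["k_sigma"]),
        blank_s=float(comp_cfg["blank_s"]),
    )

    metric_rows: list[dict[str, Any]] = []
    power_rows: list[dict[str, Any]] = []

    def add_metric(animal: str, genotype: str, dose: float, metric: str, value: float) -> None:
        metric_rows.append(
            {
                "animal_id": animal,
                "genotype": genotype,
                "dose_photons_um2": dose,
                "metric": metric,
                "value": value,
            }
        )

    # ---- stage 1-4: LED intensity series -------------------------------
    for g_idx, genotype in enumerate(genotypes):
        preset = PRESETS[genotype]
        for a_idx in range(int(sim["n_animals"])):
            animal = f"{genotype}_{a_idx + 1:02d}"
            rng = _animal_rng(seed, 1, g_idx, a_idx)
            gain, jitter = _animal_effects(
                rng, float(sim["amplitude_cv"]), float(sim["latency_jitter_s"])
            )
            preset_a = replace(preset, base_latency_s=max(preset.base_latency_s + jitter, 1e-3))
            scfg = SyntheticConfig(seed=seed, genotype=genotype, **base_kwargs)
            for dose in doses:
                sweeps = simulate_vep_sweeps(scfg, preset_a, dose, rng=rng, gain=gain)
                sweeps.meta["animal_id"] = animal
                avg = average_sweeps(sweeps, **avg_kwargs)
                add_metric(animal, genotype, dose, "n_included", avg.n_included)
                add_metric(animal, genotype, dose, "n_excluded", avg.n_excluded)
                result = detect_components(avg, **detect_kwargs)
                if result.ok:
                    assert result.components is not None
                    add_metric(animal, genotype, dose, "latency_s", result.components.latency_s)
                    add_metric(animal, genotype, dose, "p1n1_uv", result.components.p1n1_amplitude_uv)
                if avg.valid:
                    power = vep_power(avg, window_s=float(pre_cfg["response_window_s"]))
                else:
                    power = 0.0
                add_metric(animal, genotype, dose, "power_v2s", power)
                power_rows.append(
                    {
                        "animal_id": animal,
                        "genotype": genotype,
                        "dose_photons_um2": dose,
                        "power_v2s": power,
                    }
                )

    power_df = pd.DataFrame(power_rows)
    power_df = normalize_by_animal(power_df)
    for row in power_df.itertuples(index=False):
        add_metric(
            row.animal_id, row.genotype, row.dose_photons_um2, "normalized_power", row.normalized_power
        )

    fit_mode = str(cfg["fit"]["mode"])
    fit_frames = []
    for genotype in genotypes:
        sub = power_df[power_df["genotype"] == genotype]
        modes = ["pooled", "per_animal"] if fit_mode == "both" else [fit_mode]
        for mode in modes:
            fits = fit_response_table(
                sub,
                mode=mode,
                min_intensities_per_animal=int(cfg["fit"]["min_intensities_per_animal"]),
            )
            fits.insert(0, "genotype", genotype)
            fit_frames.append(fits)
    fits_df = pd.concat(fit_frames, ignore_index=True)

    # ---- stage 5: saturating stacked stimulus --------------------------
    sat = sim["saturation"]
    if sat["enabled"]:
        laser_dose = float(sat["laser_dose_photons_um2"])
        led_dose = float(sat["led_dose_photons_um2"])
        for g_idx, genotype in enumerate(genotypes):
            preset = PRESETS[genotype]
            for a_idx in range(int(sim["n_animals"])):
                animal = f"{genotype}_{a_idx + 1:02d}"
                rng = _animal_rng(seed, 2, g_idx, a_idx)
                gain, jitter = _animal_effects(
                    rng, float(sim["amplitude_cv"]), float(sim["latency_jitter_s"])
                )
                preset_a = replace(preset, base_latency_s=max(preset.base_latency_s + jitter, 1e-3))
                alone_cfg = SyntheticConfig(
                    seed=seed,
                    genotype=genotype,
                    **{**base_kwargs, "n_sweeps": int(sim["n_laser_sweeps"])},
                )
                alone = average_sweeps(
                    simulate_vep_sweeps(alone_cfg, preset_a, laser_dose, rng=rng, gain=gain),
                    **avg_kwargs,
                )
                res_alone = detect_components(alone, **detect_kwargs)
                if not res_alone.ok:
                    warnings.warn(f"{animal}: no measurable laser-alone response; skipped")
                    continue
                assert res_alone.components is not None
                amp_alone = res_alone.components.p1n1_amplitude_uv

                stacked_cfg = SyntheticConfig(
                    seed=seed, genotype=genotype, **{**base_kwargs, "post_s": 1.6}
                )
                stacked = average_sweeps(
                    simulate_stacked_sweeps(
                        stacked_cfg, preset_a, laser_dose, led_dose, rng=rng, gain=gain
                    ),
                    **avg_kwargs,
                )
                laser_view = _laser_window_view(stacked, stacked.meta["laser_onset_s"])
                res_plus = detect_components(laser_view, **detect_kwargs)
                amp_plus = (
                    res_plus.components.p1n1_amplitude_uv
                    if res_plus.ok and res_plus.components is not None
                    else 0.0
                )
                add_metric(animal, genotype, laser_dose, "amp_laser_alone_uv", amp_alone)
                add_metric(animal, genotype, laser_dose, "amp_laser_plus_led_uv", amp_plus)
                add_metric(
                    animal, genotype, laser_dose, "amplitude_ratio", amplitude_ratio(amp_plus, amp_alone)
                )

    # ---- stage 6: photopic ERGs ----------------------------------------
    erg_rows: list[dict[str, Any]] = []
    erg_cfg = sim["erg"]
    if erg_cfg["enabled"]:
        for g_idx, genotype in enumerate(genotypes):
            preset = PRESETS[genotype]
            for a_idx in range(int(erg_cfg["n_animals"])):
                animal = f"{genotype}_erg_{a_idx + 1:02d}"
                rng = _animal_rng(seed, 3, g_idx, a_idx)
                gain, _ = _animal_effects(rng, float(sim["amplitude_cv"]), 0.0)
                scfg = SyntheticConfig(seed=seed, genotype=genotype, **base_kwargs)
                avg = average_sweeps(simulate_erg_sweeps(scfg, preset, rng=rng, gain=gain), **avg_kwargs)
                feats = detect_erg_features(avg, k_sigma=float(comp_cfg["k_sigma"]))
                erg_rows.append(
                    {
                        "animal_id": animal,
                        "genotype": genotype,
                        "response_present": bool(feats.response_present),
                        "a_time_s": feats.a_time_s,
                        "a_uv": feats.a_uv,
                        "b_time_s": feats.b_time_s,
                        "b_uv": feats.b_uv,
                        "op_rms_uv": feats.op_rms_uv,
                    }
                )
    erg_df = pd.DataFrame(erg_rows)

    # ---- stage 7: group comparisons ------------------------------------
    metrics_df = pd.DataFrame(metric_rows)
    comparisons = _group_comparisons(metrics_df, fits_df, genotypes, doses, cfg["compare"])

    manifest = {
        "package": "vepscope",
        "version": __version__,
        "seed": seed,
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "outputs": ["metrics.csv", "fits.csv", "comparisons.csv", "erg.csv", "manifest.json"],
    }

    result = {
        "metrics": metrics_df,
        "fits": fits_df,
        "comparisons": comparisons,
        "erg": erg_df,
        "manifest": manifest,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_tidy_metrics(out / "metrics.csv", metrics_df)
        fits_df.to_csv(out / "fits.csv", index=False)
        comparisons.to_csv(out / "comparisons.csv", index=False)
        erg_df.to_csv(out / "erg.csv", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, sort_keys=True, indent=2)
            fh.write("\n")
    return result


def _metric_groups(
    metrics: pd.DataFrame, metric: str, genotypes: list[str], dose: float | None = None
) -> list[np.ndarray]:
    sub = metrics[metrics["metric"] == metric]
    if dose is not None:
        sub = sub[np.isclose(sub["dose_photons_um2"], dose)]
    return [sub.loc[sub["genotype"] == g, "value"].to_numpy() for g in genotypes]


def _group_comparisons(
    metrics: pd.DataFrame,
    fits: pd.DataFrame,
    genotypes: list[str],
    doses: list[float],
    compare_cfg: dict,
) -> pd.DataFrame:
    """Unpaired t-tests on the headline group metrics (first genotype =
    group A, second = group B)."""
    if len(genotypes) != 2:
        return pd.DataFrame()
    results = []
    equal_var = bool(compare_cfg["equal_variance"])
    alpha = float(compare_cfg["alpha"])

    def compare(metric_name: str, a: np.ndarray, b: np.ndarray) -> None:
        if a.size >= 2 and b.size >= 2:
            results.append(unpaired_t_test(a, b, equal_var, metric=metric_name, alpha=alpha))

    a, b = _metric_groups(metrics, "p1n1_uv", genotypes, dose=max(doses))
    compare("max_p1n1_uv", a, b)
    a, b = _metric_groups(metrics, "amplitude_ratio", genotypes)
    compare("amplitude_ratio", a, b)

    per_animal = fits[(fits["scope"] == "per_animal") & fits["reliable"] & fits["converged"]]
    grp = [per_animal[per_animal["genotype"] == g] for g in genotypes]
    compare("log10_i50", np.log10(grp[0]["i50"].to_numpy()), np.log10(grp[1]["i50"].to_numpy()))
    compare("slope", grp[0]["slope"].to_numpy(), grp[1]["slope"].to_numpy())

    return pd.DataFrame(
        [
            {
                "metric": r.metric,
                "group_a": genotypes[0],
                "mean_a": r.mean_a,
                "sem_a": r.sem_a,
                "n_a": r.n_a,
                "group_b": genotypes[1],
                "mean_b": r.mean_b,
                "sem_b": r.sem_b,
                "n_b": r.n_b,
                "t": r.t,
                "df": r.df,
                "p": r.p,
                "alpha": r.alpha,
                "significant": r.significant,
            }
            for r in results
        ]
    )
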