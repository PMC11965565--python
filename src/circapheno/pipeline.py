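"""End-to-end orchestration: simulate -> preprocess -> features -> phenotype
-> GR -> chronosensitivity.

The pipeline runs entirely on synthetic inputs with known ground truth:
a panel of cell lines is generated from the four circadian phenotype
archetypes (each line a coupled-oscillator population with
archetype-specific coupling, period and noise, recorded through two
reporters offset by a fixed phase lag), together with growth curves and
dose-response families for a small drug set.  Every stage writes a tidy
CSV into the run directory; a manifest records the configuration hash,
seeds and per-stage status, and completed stages are skipped on re-runs
with an unchanged configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import autocorr, chronosense, decay, growth, mra, phenotyping, wavelet
from .exceptions import ConfigurationError
from .preprocess import (
    DEFAULT_CUTOFF_H,
    DEFAULT_HEAD_TRIM_H,
    DEFAULT_MAX_LEN_H,
    TimeSeries,
    normalize_envelope,
    sinc_detrend,
    trim,
)
from .simulate import (
    SimulationConfig,
    SyntheticRecordingSpec,
    generate_dose_response,
    render_recording,
    simulate_population,
)

log = logging.getLogger("circapheno.pipeline")

#: per-archetype simulation conditions (coupling, mean period, recording
#: noise, growth rate per hour); these generate the demo panel
ARCHETYPE_CONDITIONS: Dict[str, dict] = {
    "functional": dict(kappa=0.05, period_h=24.0, noise_sd=0.02, growth_k=0.015, lag_h=8.0),
    "weak": dict(kappa=3e-4, period_h=25.0, noise_sd=0.03, growth_k=0.025, lag_h=2.0),
    "unstable": dict(kappa=0.02, period_h=26.0, noise_sd=0.10, growth_k=0.022, lag_h=4.0),
    "dysfunctional": dict(kappa=1e-5, period_h=29.0, noise_sd=0.08, growth_k=0.030, lag_h=1.0),
}

#: demo drugs: GR_inf either tied to clock strength (clock-dependent drug)
#: or flat across the panel (clock-independent control drug)
DEMO_DRUGS: Dict[str, dict] = {
    "clockdep": dict(GEC50=1.0, h_GR=2.0, clock_dependent=True),
    "flatdrug": dict(GEC50=1.0, h_GR=2.0, clock_dependent=False),
}
DEMO_DOSES = tuple(float(c) for c in np.logspace(-2, 2, 6))


@dataclass
class RunConfig:
    out_dir: str = "circapheno_run"
    seed: int = 0
    n_lines_per_phenotype: int = 3
    drugs: Tuple[str, ...] = tuple(DEMO_DRUGS)
    head_trim_h: float = DEFAULT_HEAD_TRIM_H
    max_len_h: float = DEFAULT_MAX_LEN_H
    cutoff_h: float = DEFAULT_CUTOFF_H
    min_ridge_h: float = wavelet.MIN_RIDGE_H
    stages: Tuple[str, ...] = ("simulate", "features", "phenotype", "gr", "chronosense")
    max_len_overrides: Dict[str, float] = field(default_factory=dict)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ConfigurationError(f"unknown config keys: {sorted(bad)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "drugs" in raw:
            raw["drugs"] = tuple(raw["drugs"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))


# ------------------------------------------------------------- simulation

def _panel(config: RunConfig) -> List[Tuple[str, str]]:
    return [
        (f"{arch}_{i}", arch)
        for arch in ARCHETYPE_CONDITIONS
        for i in range(config.n_lines_per_phenotype)
    ]


def simulate_panel(config: RunConfig) -> Tuple[Dict[str, Dict[str, TimeSeries]], pd.DataFrame, dict]:
    """Synthesize the demo panel: recordings, growth curves, dose responses."""
    rng = np.random.default_rng(config.seed)
    recordings: Dict[str, Dict[str, TimeSeries]] = {}
    growth_rows = []
    dose_data = {}
    truth_rows = []
    for line, arch in _panel(config):
        cond = ARCHETYPE_CONDITIONS[arch]
        sim_seed = int(rng.integers(0, 2**31 - 1))
        sig = simulate_population(
            SimulationConfig(
                coupling_strength=cond["kappa"],
                mean_period_h=cond["period_h"],
                duration_steps=1380,
                seed=sim_seed,
            )
        )
        recordings[line] = {}
        for reporter, lag in (("Bmal1", 0.0), ("Per2", cond["lag_h"])):
            lagged = replace_signal_with_lag(sig, lag)
            rec = render_recording(
                SyntheticRecordingSpec(
                    base=lagged,
                    duration_h=min(137.9, lagged.times[-1]),
                    trend_coeffs=(0.5, -0.002),
                    spike_magnitude=3.0,
                    spike_span_h=5.0,
                    noise_sd=cond["noise_sd"],
                    seed=int(rng.integers(0, 2**31 - 1)),
                    sample_id=f"{line}_{reporter}",
                    meta={"cell_line": line, "reporter": reporter, "phenotype": arch},
                )
            )
            recordings[line][reporter] = rec

        t = np.arange(0.0, 96.0 + 1.0, 2.0)
        counts = 100.0 * np.exp(cond["growth_k"] * t)
        counts = counts * (1.0 + rng.normal(0, 0.02, len(t)))
        for ti, yi in zip(t, counts):
            growth_rows.append((line, ti, yi))

        for drug in config.drugs:
            spec = DEMO_DRUGS[drug]
            if spec["clock_dependent"]:
                # stronger clocks respond more cytotoxically
                strength = {"functional": -0.6, "weak": 0.1, "unstable": -0.2,
                            "dysfunctional": 0.3}[arch]
                gr_inf = strength + rng.normal(0, 0.05)
            else:
                gr_inf = 0.0 + rng.normal(0, 0.05)
            gr_inf = float(np.clip(gr_inf, -1.0, 1.0))
            curves, truth = generate_dose_response(
                {"GR_inf": gr_inf, "GEC50": spec["GEC50"], "h_GR": spec["h_GR"]},
                DEMO_DOSES,
                k0=cond["growth_k"],
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            dose_data[(line, drug)] = curves
            truth_rows.append(dict(cell_line=line, drug=drug, phenotype=arch, **truth))

    growth_df = pd.DataFrame(growth_rows, columns=["cell_line", "time_h", "count"])
    return recordings, growth_df, {"dose": dose_data, "truth": pd.DataFrame(truth_rows)}


def replace_signal_with_lag(sig, lag_h: float):
    """Time-shift a population signal by ``lag_h`` (periodic-ish via clipping)."""
    from .simulate import PopulationSignal

    shifted = np.interp(sig.times + lag_h, sig.times, sig.ensemble_mean)
    return PopulationSignal(
        times=sig.times, mean_field=sig.mean_field, ensemble_mean=shifted,
        periods=sig.periods, config=sig.config,
    )


# --------------------------------------------------------------- features

def extract_features(
    recordings: Dict[str, Dict[str, TimeSeries]],
    config: Optional[RunConfig] = None,
) -> pd.DataFrame:
    """Per-cell-line, reporter-averaged circadian feature table.

    Each recording is trimmed, sinc-detrended and amplitude-normalized;
    autocorrelation, multiresolution, wavelet-ridge and decay readouts
    are computed per reporter and averaged per line; the phase-difference
    variability between the two reporters is computed per line.
    """
    config = config or RunConfig()
    processed: Dict[str, Dict[str, object]] = {}
    spectra_unnorm = []
    for line, reps in recordings.items():
        processed[line] = {}
        for reporter, rec in reps.items():
            max_len = config.max_len_overrides.get(rec.sample_id, config.max_len_h)
            ts = trim(rec, config.head_trim_h, max_len)
            d = normalize_envelope(sinc_detrend(ts, config.cutoff_h))
            spec_u = wavelet.cwt_spectrum(d, normalized=False)
            spec_n = wavelet.cwt_spectrum(d, normalized=True)
            processed[line][reporter] = (d, spec_u, spec_n)
            spectra_unnorm.append(spec_u)

    thr = wavelet.global_threshold(spectra_unnorm)
    rows = {}
    for line, reps in processed.items():
        per_reporter = []
        ridges_norm = {}
        for reporter, (d, spec_u, spec_n) in reps.items():
            ac = autocorr.analyze(d)
            dec = mra.decompose(mra.resample(d))
            ridge_u = wavelet.extract_ridge(spec_u, mode="global", threshold=thr)
            ridge_n = wavelet.extract_ridge(spec_n, mode="adaptive")
            ridges_norm[reporter] = ridge_n
            summ_u = wavelet.ridge_readouts(ridge_u, config.min_ridge_h)
            summ_n = wavelet.ridge_readouts(ridge_n, config.min_ridge_h)
            fit = decay.fit_decay(d, model="damped_sinusoid")
            per_reporter.append(
                dict(
                    rhythmicity_index=ac.rhythmicity_index,
                    lag_h=ac.period_lag_h,
                    period_h=summ_n.period_mean_h,
                    period_cv=summ_n.period_cv,
                    amplitude=summ_u.amplitude_mean,
                    amplitude_cv=summ_u.amplitude_cv,
                    ridge_length_h=summ_u.ridge_length_h,
                    circadian_band_pct=dec.band_fractions["circadian"],
                    infradian_band_pct=dec.band_fractions["infradian"],
                    noise_band_pct=dec.band_fractions["noise"],
                    decay_gamma=fit.gamma if fit.accepted else np.nan,
                    decay_A0=fit.A0 if fit.accepted else np.nan,
                )
            )
        row = pd.DataFrame(per_reporter).mean().to_dict()
        reps_list = list(ridges_norm)
        if len(reps_list) >= 2:
            pdiff = wavelet.phase_difference(ridges_norm[reps_list[0]], ridges_norm[reps_list[1]])
            row["phase_diff_var"] = pdiff.circular_std if not pdiff.excluded else np.nan
            row["phase_diff_mean"] = pdiff.circular_mean if not pdiff.excluded else np.nan
        rows[line] = row
    table = pd.DataFrame(rows).T
    table.index.name = "cell_line"
    return table


def fit_panel_gr(dose_data: Dict[Tuple[str, str], pd.DataFrame]) -> pd.DataFrame:
    """GR sigmoid fits for every (cell line, drug) dose-response family."""
    rows = []
    for (line, drug), curves in dose_data.items():
        control = curves[curves["conc_uM"] == 0.0]
        ctrl_curve = growth.GrowthCurve(control["time_h"].to_numpy(), control["count"].to_numpy())
        dose_curves = {
            c: growth.GrowthCurve(g["time_h"].to_numpy(), g["count"].to_numpy())
            for c, g in curves[curves["conc_uM"] > 0].groupby("conc_uM")
        }
        per_dose = growth.per_dose_gr_from_curves(dose_curves, ctrl_curve)
        fit = growth.fit_gr_curve(per_dose)
        rows.append(
            dict(cell_line=line, drug=drug, GR_inf=fit.GR_inf, GEC50=fit.GEC50,
                 h_GR=fit.h_GR, GR50=fit.GR50, GR_AOC=fit.GR_AOC, fit_ok=fit.fit_ok)
        )
    return pd.DataFrame(rows)


# ------------------------------------------------------------------- run

def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages, writing CSVs and a run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    cfg_hash = config.config_hash()
    manifest = {"config_hash": cfg_hash, "seed": config.seed, "stages": {}}
    if manifest_path.exists():
        old = json.loads(manifest_path.read_text())
        if old.get("config_hash") == cfg_hash:
            manifest = old
    config.to_yaml(out / "config.yaml")

    def done(stage: str, output: Path) -> bool:
        return manifest["stages"].get(stage) == "ok" and output.exists()

    def mark(stage: str, status: str) -> None:
        manifest["stages"][stage] = status
        manifest_path.write_text(json.dumps(manifest, indent=1))

    state: dict = {}
    try:
        if "simulate" in config.stages:
            rec_path = out / "recordings.csv"
            log.info("stage simulate")
            recordings, growth_df, drug_data = simulate_panel(config)
            state.update(recordings=recordings, growth=growth_df, drug=drug_data)
            flat = [rec for reps in recordings.values() for rec in reps.values()]
            from .simulate import write_recording_csv

            write_recording_csv(rec_path, flat)
            growth_df.to_csv(out / "growth_curves.csv", index=False)
            drug_data["truth"].to_csv(out / "drug_ground_truth.csv", index=False)
            mark("simulate", "ok")

        if "features" in config.stages:
            feat_path = out / "features.csv"
            if done("features", feat_path):
                log.info("stage features: cached")
                state["features"] = pd.read_csv(feat_path, index_col=0)
            else:
                if "recordings" not in state:
                    raise ConfigurationError(
                        "features stage needs the simulate stage (or cached outputs)"
                    )
                log.info("stage features")
                table = extract_features(state["recordings"], config)
                k_by_line = {}
                for line, g in state["growth"].groupby("cell_line"):
                    curve = growth.smooth_growth(
                        growth.GrowthCurve(g["time_h"].to_numpy(), g["count"].to_numpy())
                    )
                    k_by_line[line] = growth.fit_growth_rate(curve).k
                table["growth_rate"] = pd.Series(k_by_line)
                table.to_csv(feat_path)
                state["features"] = table
                mark("features", "ok")

        if "phenotype" in config.stages:
            log.info("stage phenotype")
            table = state["features"]
            assign = phenotyping.select_k_and_cluster(
                table[list(phenotyping.CLUSTER_FEATURES)], seed=config.seed
            )
            pd.DataFrame(
                {"cluster": assign.cluster_id, "phenotype": assign.labels}
            ).to_csv(out / "phenotypes.csv")
            state["phenotypes"] = assign
            mark("phenotype", "ok")

        if "gr" in config.stages:
            log.info("stage gr")
            gr_table = fit_panel_gr(state["drug"]["dose"])
            gr_table.to_csv(out / "gr_fits.csv", index=False)
            state["gr"] = gr_table
            mark("gr", "ok")

        if "chronosense" in config.stages:
            log.info("stage chronosense")
            table = state["features"].dropna(axis=1, how="any")
            gr_table = state["gr"]
            sens = gr_table.pivot(index="cell_line", columns="drug", values="GR_inf")
            ranking = chronosense.rank_drugs(table, sens)
            ranking.to_csv(out / "chronosensitivity.csv", index=False)
            mark("chronosense", "ok")
    except Exception:
        failed = next(
            (s for s in config.stages if manifest["stages"].get(s) != "ok"), "unknown"
        )
        mark(failed, "failed")
        raise
    return out
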