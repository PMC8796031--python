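"""Resection-referenced metrics, the regularization sweep, and the pipeline.

A localization is scored against a reference resection volume by two
numbers: the *resection distance* (Euclidean distance in mm from the map
maximum to the nearest source point inside the resection; 0 when the
maximum lies inside) and the *relative power* (maximum map value outside
the resection divided by the maximum inside; values below 1 mean the global
maximum is inside, 0 means no power outside at all, values can exceed 1
arbitrarily when the inside power is comparatively small).

The regularization sweep repeats every localization method over the
diagonal-loading grid α = 0, 0.002, …, 0.2 (101 values, with the common
toolbox default 0.05 on the grid) and records both metrics per cell;
dipole-scan results do not depend on α and are computed once.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .forward import (Leadfield, SourceSpace, build_sphere_head,
                      build_source_grid, eeg_sphere_leadfield,
                      meg_sphere_leadfield, place_sensors)
from .simulate import (ResectionVolume, SpikeDataset, make_resection,
                       make_spike_waveform, simulate_spike_trials)
from .preprocess import (average_trials, estimate_noise_std, filter_dataset,
                         find_rising_flank_midpoint, normalize_meeg)
from .inverse import (SourceMap, SingularCovarianceError, beamformer_power_map,
                      dipole_scan, estimate_covariance, regularize_covariance)

__all__ = [
    "SweepRecord",
    "DEFAULT_ALPHAS",
    "resection_distance",
    "relative_power",
    "regularization_sweep",
    "run_pipeline",
    "default_config",
    "source_map_table",
    "plot_sweep_curves",
]

# alpha = 0 (none) to 0.2 (very strong) in steps of 0.002: 101 values
DEFAULT_ALPHAS = np.round(np.arange(0, 101) * 0.002, 6)


@dataclass
class SweepRecord:
    """One (method × modality × model × α) cell of the sweep."""

    alpha: float
    method: str                   # "bf-avg" | "bf-evt" | "dip"
    modality: str
    model: str
    resection_distance_mm: float
    relative_power: float
    argmax_index: int
    gof_at_argmax: float | None = None
    error: str | None = None


def resection_distance(source_map: SourceMap, resection: ResectionVolume,
                       sources: SourceSpace) -> float:
    """Distance (mm) from the map maximum to the nearest resection point."""
    members = resection.member_indices
    if members.size == 0:
        raise ValueError("resection volume is empty")
    amax = source_map.argmax_index
    if np.isin(amax, members):
        return 0.0
    d = np.linalg.norm(sources.points[members] - sources.points[amax], axis=1)
    return float(d.min())


def relative_power(source_map: SourceMap, resection: ResectionVolume) -> float:
    """Max map value outside the resection over the max value inside.

    Returns ``inf`` when the inside maximum is zero (undefined ratio).
    """
    members = resection.member_indices
    values = source_map.values
    outside = np.setdiff1d(np.arange(values.size), members)
    if outside.size == 0:
        raise ValueError("resection covers the whole source space")
    max_in = values[members].max()
    max_out = values[outside].max()
    if max_in <= 0:
        return float("inf")
    return float(max_out / max_in)


def _choose_analysis_index(evoked, analysis_index):
    if analysis_index is not None:
        return int(analysis_index)
    try:
        return find_rising_flank_midpoint(evoked)
    except ValueError:
        return evoked.peak_index


def regularization_sweep(dataset: SpikeDataset, leadfield: Leadfield,
                         resection: ResectionVolume, sources: SourceSpace,
                         methods=("bf-avg", "bf-evt", "dip"),
                         alphas=None, *, analysis_index: int | None = None,
                         variant: str = "unit_norm",
                         cov_window_ms=None, model: str = "",
                         meg_tsvd: bool | None = None) -> list[SweepRecord]:
    """Localize with every method across the α grid and score each cell.

    Beamformer cells that fail (e.g. inverting a rank-deficient covariance
    at α = 0) are recorded with NaN metrics and the error message rather
    than aborting the sweep. The dipole scan is α-independent: it runs once
    and its record is replicated across the grid.
    """
    alphas = DEFAULT_ALPHAS if alphas is None else np.asarray(alphas, float)
    if alphas.size == 0:
        raise ValueError("alphas must be nonempty")
    evoked = average_trials(dataset)
    idx = _choose_analysis_index(evoked, analysis_index)
    modality = leadfield.modality
    if meg_tsvd is None:
        meg_tsvd = modality == "meg"

    records: list[SweepRecord] = []
    if "dip" in methods:
        gof_map = dipole_scan(leadfield, evoked.data[:, idx],
                              meg_tsvd=meg_tsvd)
        gof_map.modality, gof_map.model = modality, model
        dist = resection_distance(gof_map, resection, sources)
        rel = relative_power(gof_map, resection)
        amax = gof_map.argmax_index
        for a in alphas:
            records.append(SweepRecord(
                alpha=float(a), method="dip", modality=modality, model=model,
                resection_distance_mm=dist, relative_power=rel,
                argmax_index=amax,
                gof_at_argmax=float(gof_map.values[amax])))

    for method, mode in (("bf-avg", "average_based"),
                         ("bf-evt", "event_related")):
        if method not in methods:
            continue
        cov0 = estimate_covariance(dataset, mode=mode,
                                   window_ms=cov_window_ms)
        for a in alphas:
            try:
                cov = regularize_covariance(cov0, float(a))
                pmap = beamformer_power_map(leadfield, cov, evoked.data,
                                            idx, variant=variant)
                pmap.method, pmap.model = method, model
                records.append(SweepRecord(
                    alpha=float(a), method=method, modality=modality,
                    model=model,
                    resection_distance_mm=resection_distance(
                        pmap, resection, sources),
                    relative_power=relative_power(pmap, resection),
                    argmax_index=pmap.argmax_index))
            except (SingularCovarianceError, np.linalg.LinAlgError) as err:
                records.append(SweepRecord(
                    alpha=float(a), method=method, modality=modality,
                    model=model, resection_distance_mm=float("nan"),
                    relative_power=float("nan"), argmax_index=-1,
                    error=str(err)))
    return records


def records_to_frame(records: list[SweepRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])


def source_map_table(source_map: SourceMap, sources: SourceSpace
                     ) -> np.ndarray:
    """Rows of (index, x, y, z, value) for delimited-text export."""
    return np.column_stack([sources.indices, sources.points,
                            source_map.values])


def plot_sweep_curves(frame: pd.DataFrame, out_path):
    """Distance and relative-power curves over α, one panel row per modality.

    Requires matplotlib (optional dependency); lines are drawn per
    method × model within each modality panel.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ok = frame[frame["error"].isna()]
    modalities = sorted(ok["modality"].unique())
    fig, axes = plt.subplots(len(modalities), 2, squeeze=False,
                             figsize=(9, 2.8 * len(modalities)))
    for row, mod in enumerate(modalities):
        sub = ok[ok["modality"] == mod]
        for (method, model), g in sub.groupby(["method", "model"]):
            g = g.sort_values("alpha")
            label = f"{method} {model}"
            axes[row][0].plot(g["alpha"], g["resection_distance_mm"],
                              label=label)
            axes[row][1].plot(g["alpha"], g["relative_power"], label=label)
        axes[row][0].set_ylabel(f"{mod}\ndistance (mm)")
        axes[row][1].set_ylabel("relative power")
        axes[row][1].axhline(1.0, color="k", lw=0.5, ls=":")
    for ax in axes[-1]:
        ax.set_xlabel("regularization α")
    axes[0][0].legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def default_config() -> dict:
    """Baseline pipeline configuration (patient-2-like scale)."""
    return {
        "seed": 0,
        "head": {
            "radii_mm": [80.0, 85.0, 92.0],
            "profiles": {
                "3C-standard": [0.33, 0.01, 0.43],
                "3C-calibrated": [0.33, 0.0167, 0.43],
            },
            "true_profile": "3C-standard",
        },
        "sensors": {"n_eeg": 70, "n_meg": 271, "meg_offset_mm": 20.0,
                    "coverage": "hemisphere"},
        "grid": {"spacing_mm": 10.0, "margin_mm": 2.0},
        "source": {
            "position_mm": [30.0, 0.0, 50.0],   # snapped to the grid
            "orientation": [1.0, 0.0, 0.0],
            "amplitude_nam": 100.0,
            "snr": 5.0,
            "n_trials": 54,
            "srate": 1200.0,
            "noise_model": "ar1",
            "amp_jitter": 0.2,
            "latency_jitter_ms": 5.0,
        },
        "filter": {"low": 2.0, "high": 80.0, "notch": 50.0, "order": 6},
        "analysis": {"time_point": "flank_midpoint", "variant": "unit_norm",
                     "cov_window_ms": None},
        "resection": {"radius_mm": 12.0},
        "sweep": {
            "alphas": None,  # default 0:0.002:0.2
            "methods": ["bf-avg", "bf-evt", "dip"],
            "modalities": ["eeg", "meg", "meeg"],
        },
        "eeg_n_terms": 60,
        "out_dir": None,
        "plots": False,   # write sweep-curve figures (needs matplotlib)
    }


def _merge_config(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, val in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(val, dict):
            out[key] = _merge_config(out[key], val)
        else:
            out[key] = val
    return out


def _validate_config(cfg: dict):
    if cfg["head"]["true_profile"] not in cfg["head"]["profiles"]:
        raise ValueError("head.true_profile must name one of head.profiles")
    for mod in cfg["sweep"]["modalities"]:
        if mod not in ("eeg", "meg", "meeg"):
            raise ValueError(f"unknown modality '{mod}' in sweep.modalities")
    for m in cfg["sweep"]["methods"]:
        if m not in ("bf-avg", "bf-evt", "dip"):
            raise ValueError(f"unknown method '{m}' in sweep.methods")
    if not cfg["source"]["snr"] > 0:
        raise ValueError("source.snr must be positive")


def run_pipeline(config: dict | str | None = None) -> dict:
    """Simulate → preprocess → sweep → evaluate, returning a report bundle.

    ``config`` is a (partial) dict merged over :func:`default_config`, or a
    path to a YAML/JSON file with the same structure. The bundle holds the
    per-cell sweep table (pandas DataFrame), an argmin-distance summary per
    method × modality × model, the resection and geometry objects, and a
    machine-readable manifest (config, seed, library versions) sufficient
    to replay the run. If ``out_dir`` is set the tables and manifest are
    written there as delimited text / JSON.
    """
    if isinstance(config, (str, bytes)) or hasattr(config, "read_text"):
        import yaml
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = _merge_config(default_config(), config or {})
    _validate_config(cfg)
    seed = int(cfg["seed"])

    # geometry and forward models
    radii = cfg["head"]["radii_mm"]
    profiles = {label: build_sphere_head(radii, cond, label=label)
                for label, cond in cfg["head"]["profiles"].items()}
    true_head = profiles[cfg["head"]["true_profile"]]
    eeg_sens = place_sensors(true_head, "eeg", cfg["sensors"]["n_eeg"],
                             0.0, cfg["sensors"]["coverage"])
    meg_sens = place_sensors(true_head, "meg", cfg["sensors"]["n_meg"],
                             cfg["sensors"]["meg_offset_mm"],
                             cfg["sensors"]["coverage"])
    sources = build_source_grid(true_head, cfg["grid"]["spacing_mm"],
                                cfg["grid"]["margin_mm"])
    n_terms = cfg["eeg_n_terms"]
    eeg_lfs = {label: eeg_sphere_leadfield(head, eeg_sens, sources,
                                           n_terms=n_terms)
               for label, head in profiles.items()}
    meg_lf = meg_sphere_leadfield(meg_sens, sources)

    # ground truth: source at the resection center
    src_cfg = cfg["source"]
    true_index = sources.nearest_index(src_cfg["position_mm"])
    resection = make_resection(sources, true_index,
                               cfg["resection"]["radius_mm"])
    orientation = np.asarray(src_cfg["orientation"], float)
    orientation = orientation / np.linalg.norm(orientation)

    srate = float(src_cfg["srate"])
    waveform = make_spike_waveform(srate)
    raw = simulate_spike_trials(
        {"eeg": eeg_lfs[cfg["head"]["true_profile"]], "meg": meg_lf},
        true_index, orientation, src_cfg["amplitude_nam"], waveform,
        src_cfg["n_trials"], noise_model=src_cfg["noise_model"],
        snr=src_cfg["snr"], seed=seed, srate=srate,
        amp_jitter=src_cfg["amp_jitter"],
        latency_jitter_ms=src_cfg["latency_jitter_ms"])

    flt = cfg["filter"]
    datasets = {mod: filter_dataset(ds, low=flt["low"], high=flt["high"],
                                    notch=flt["notch"], order=flt["order"])
                for mod, ds in raw.items()}

    analysis_cfg = cfg["analysis"]
    records: list[SweepRecord] = []
    for model, eeg_lf in eeg_lfs.items():
        lf_by_mod: dict[str, tuple[SpikeDataset, Leadfield]] = {}
        if "eeg" in cfg["sweep"]["modalities"]:
            lf_by_mod["eeg"] = (datasets["eeg"], eeg_lf)
        if "meg" in cfg["sweep"]["modalities"]:
            lf_by_mod["meg"] = (datasets["meg"], meg_lf)
        if "meeg" in cfg["sweep"]["modalities"]:
            eeg_ev = average_trials(datasets["eeg"])
            meg_ev = average_trials(datasets["meg"])
            norms = (estimate_noise_std(eeg_ev), estimate_noise_std(meg_ev))
            comb_ev, comb_lf = normalize_meeg((eeg_ev, eeg_lf),
                                              (meg_ev, meg_lf), norms)
            comb_trials = np.concatenate(
                [datasets["eeg"].trials / norms[0].stds[None, :, None],
                 datasets["meg"].trials / norms[1].stds[None, :, None]],
                axis=1)
            comb_ds = SpikeDataset(
                trials=comb_trials, srate=srate,
                peak_index=datasets["eeg"].peak_index, modality="meeg",
                channel_names=list(comb_ev.channel_names),
                tmin=datasets["eeg"].tmin, truth=datasets["eeg"].truth)
            lf_by_mod["meeg"] = (comb_ds, comb_lf)
        for mod, (ds, lf) in lf_by_mod.items():
            evoked = average_trials(ds)
            idx = (evoked.peak_index
                   if analysis_cfg["time_point"] == "peak"
                   else _choose_analysis_index(evoked, None))
            records.extend(regularization_sweep(
                ds, lf, resection, sources,
                methods=cfg["sweep"]["methods"],
                alphas=cfg["sweep"]["alphas"], analysis_index=idx,
                variant=analysis_cfg["variant"],
                cov_window_ms=analysis_cfg["cov_window_ms"], model=model))

    frame = records_to_frame(records)
    ok = frame[frame["error"].isna()]
    summary = (ok.sort_values(["modality", "model", "method", "alpha"])
               .groupby(["modality", "model", "method"], as_index=False)
               .apply(lambda g: g.loc[g["resection_distance_mm"].idxmin(),
                                      ["alpha", "resection_distance_mm",
                                       "relative_power"]],
                      include_groups=False))
    import scipy
    manifest = {
        "config": cfg,
        "seed": seed,
        "true_source_index": int(true_index),
        "versions": {"numpy": np.__version__, "scipy": scipy.__version__,
                     "pandas": pd.__version__},
    }
    bundle = {
        "records": frame,
        "summary": summary,
        "manifest": manifest,
        "sources": sources,
        "resection": resection,
        "datasets": datasets,
        "leadfields": {"eeg": eeg_lfs, "meg": meg_lf},
    }
    out_dir = cfg.get("out_dir")
    if out_dir:
        from pathlib import Path
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        frame.to_csv(out / "sweep_records.tsv", sep="\t", index=False)
        summary.to_csv(out / "summary.tsv", sep="\t", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        if cfg.get("plots"):
            plot_sweep_curves(frame, out / "sweep_curves.png")
    return bundle
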