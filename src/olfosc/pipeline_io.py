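"""Container formats, run configuration, and the end-to-end pipeline runner.

Datasets travel as an HDF5 container (per-participant ``/participants/<id>/
signals`` blocks of trials × regions × samples, a shared ``/time`` axis, and
``fs`` / region-label attributes) with the behavioral table as a sidecar TSV.
The runner chains simulate → TFR → {mixed-effects maps, connectivity →
{decoding, Granger}, PAC, bursts} according to stage toggles, deriving a
named child seed per stage from the master seed and writing a manifest with
parameter echo and per-stage output checksums so a rerun with the same seed
is verifiable bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml
from numpy.random import SeedSequence

from . import bursts as bursts_mod
from . import connectivity as conn_mod
from . import decode as decode_mod
from . import masslme as masslme_mod
from . import pac as pac_mod
from . import tfr as tfr_mod
from .synthdata import (
    BEHAVIOR_COLUMNS,
    ConfigurationError,
    InjectedEffect,
    SimConfig,
    TrialSet,
)

logger = logging.getLogger("olfosc")

__all__ = [
    "RunConfig",
    "median_split",
    "write_dataset",
    "read_dataset",
    "run_pipeline",
]

REQUIRED_BEHAVIOR_COLUMNS = set(BEHAVIOR_COLUMNS)


# ---------------------------------------------------------------------------
# Median split
# ---------------------------------------------------------------------------

def median_split(
    behav: pd.DataFrame,
    column: str = "intensity",
    out_column: str = "intensity_class",
    min_range: float = 1.0,
) -> pd.DataFrame:
    """Within-participant median split of a continuous rating.

    Trials strictly above the participant's median become 'high'; ties at
    the median go to 'low'. Participants whose rating range is below
    ``min_range`` (too little variability to dichotomize meaningfully) are
    flagged in a boolean ``flagged_low_variability`` column; all-identical
    ratings additionally log an exclusion entry.
    """
    behav = behav.copy()
    classes = np.empty(len(behav), dtype=object)
    flagged = np.zeros(len(behav), dtype=bool)
    for pid, idx in behav.groupby("participant").groups.items():
        vals = behav.loc[idx, column].to_numpy(float)
        med = np.median(vals)
        classes[behav.index.get_indexer(idx)] = np.where(
            vals > med, "high", "low"
        )
        rng_ = vals.max() - vals.min()
        if rng_ < min_range:
            flagged[behav.index.get_indexer(idx)] = True
            if rng_ == 0:
                logger.warning(
                    "participant %s: all-identical %s ratings; excluded",
                    pid, column,
                )
            else:
                logger.warning(
                    "participant %s: %s range %.2f < %.2f; flagged",
                    pid, column, rng_, min_range,
                )
    behav[out_column] = classes
    behav["flagged_low_variability"] = flagged
    return behav


# ---------------------------------------------------------------------------
# Container I/O
# ---------------------------------------------------------------------------

def write_dataset(
    path: str | Path,
    trial_sets: list[TrialSet],
    behav: pd.DataFrame,
    behav_path: str | Path | None = None,
) -> Path:
    """Write the HDF5 signal container and the sidecar behavioral TSV."""
    path = Path(path)
    behav_path = Path(behav_path) if behav_path else path.with_suffix(".tsv")
    with h5py.File(path, "w") as f:
        f.attrs["fs"] = trial_sets[0].fs
        f.attrs["regions"] = list(trial_sets[0].regions)
        f.create_dataset("time", data=trial_sets[0].time)
        grp = f.create_group("participants")
        for ts in trial_sets:
            g = grp.create_group(ts.participant)
            g.create_dataset("signals", data=ts.data)
    behav.to_csv(behav_path, sep="\t", index=False)
    return path


def read_dataset(
    path: str | Path, behav_path: str | Path | None = None
) -> tuple[list[TrialSet], pd.DataFrame]:
    """Read a dataset container; validates the schema and trial alignment."""
    path = Path(path)
    behav_path = Path(behav_path) if behav_path else path.with_suffix(".tsv")
    if not path.exists():
        raise FileNotFoundError(path)
    behav = pd.read_csv(behav_path, sep="\t")
    missing = sorted(REQUIRED_BEHAVIOR_COLUMNS - set(behav.columns))
    if missing:
        raise ConfigurationError(
            "behavioral table missing column(s): " + ", ".join(missing)
        )
    trial_sets: list[TrialSet] = []
    with h5py.File(path, "r") as f:
        for key in ("time",):
            if key not in f:
                raise ConfigurationError(f"container missing dataset '{key}'")
        for attr in ("fs", "regions"):
            if attr not in f.attrs:
                raise ConfigurationError(f"container missing attribute '{attr}'")
        fs = float(f.attrs["fs"])
        regions = tuple(
            r.decode() if isinstance(r, bytes) else str(r)
            for r in f.attrs["regions"]
        )
        time = f["time"][:]
        if "participants" not in f:
            raise ConfigurationError("container missing group 'participants'")
        for pid in sorted(f["participants"]):
            g = f["participants"][pid]
            if "signals" not in g:
                raise ConfigurationError(
                    f"participant {pid} missing dataset 'signals'"
                )
            trial_sets.append(
                TrialSet(
                    data=g["signals"][:], time=time, fs=fs,
                    participant=pid, regions=regions,
                )
            )
    n_trials = sum(ts.n_trials for ts in trial_sets)
    if n_trials != len(behav):
        raise ConfigurationError(
            f"behavioral rows ({len(behav)}) != trials in container ({n_trials})"
        )
    return trial_sets, behav


# ---------------------------------------------------------------------------
# Run configuration and pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """All pipeline parameters; validates before any stage runs and
    round-trips losslessly through YAML."""

    output_dir: str = "olfosc_output"
    dataset_path: str | None = None  # None → simulate
    seed: int = 0

    # stage toggles
    run_lme: bool = True
    run_connectivity: bool = True
    run_decode: bool = True
    run_pac: bool = True
    run_bursts: bool = True

    # simulation
    n_participants: int = 6
    n_trials: int = 40
    fs: float = 512.0
    epoch: tuple[float, float] = (-1.0, 4.0)
    odor_window: tuple[float, float] = (0.0, 2.0)
    effects: list[dict] = field(default_factory=list)

    # tfr
    freq_min: float = 2.0
    freq_max: float = 100.0
    freq_step: float = 1.0
    base_cycles: float = 8.0
    frame_rate: float = 100.0

    # statistics
    predictor: str = "intensity"
    n_perm: int = 1000
    forming_alpha: float = 0.05
    weight_exponent: float = 2.0

    # connectivity / decoding / pac / bursts
    granger_window: tuple[float, float] = (0.0, 2.0)
    smoothing_hz: float = 3.0
    beta_band: tuple[float, float] = (12.0, 30.0)
    gamma_band: tuple[float, float] = (70.0, 100.0)
    decode_bin_hz: float = 12.0
    decode_bin_sec: float = 0.100
    n_shuffles: int = 1000
    pac_phase_band: tuple[float, float] = (12.0, 16.0)
    pac_amp_band: tuple[float, float] = (70.0, 90.0)
    pac_window_center: float = 1.025
    burst_bands: tuple[tuple[float, float], ...] = (
        bursts_mod.BETA_BAND,
        bursts_mod.GAMMA_BAND,
    )

    def validate(self) -> None:
        self.sim_config()  # raises on invalid simulation parameters
        if self.n_perm < 1:
            raise ConfigurationError("n_perm must be >= 1")
        if self.n_perm < 1000:
            warnings.warn(
                f"n_perm={self.n_perm} below the recommended 1000",
                stacklevel=2,
            )
        if not 0 < self.forming_alpha < 1:
            raise ConfigurationError("forming_alpha must be in (0, 1)")
        if self.freq_max >= self.fs / 2:
            raise ConfigurationError("freq_max must be below Nyquist")

    def sim_config(self) -> SimConfig:
        return SimConfig(
            n_participants=self.n_participants,
            n_trials=self.n_trials,
            fs=self.fs,
            epoch=tuple(self.epoch),
            odor_window=tuple(self.odor_window),
            effect_spec=tuple(
                InjectedEffect(
                    **{
                        **e,
                        "regions": tuple(e["regions"]),
                        "band": tuple(e["band"]),
                        "time_window": tuple(e["time_window"])
                        if e.get("time_window")
                        else None,
                        "phase_band": tuple(e["phase_band"])
                        if e.get("phase_band")
                        else None,
                    }
                )
                for e in self.effects
            ),
            seed=self.seed,
        )

    def freqs(self) -> np.ndarray:
        return np.arange(self.freq_min, self.freq_max + 1e-9, self.freq_step)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_jsonable(asdict(self)), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cfg = cls(**raw)
        # tuples arrive as lists from YAML; normalize for round-trip equality
        for name in ("epoch", "odor_window", "granger_window", "beta_band",
                     "gamma_band", "pac_phase_band", "pac_amp_band"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        cfg.burst_bands = tuple(tuple(b) for b in cfg.burst_bands)
        return cfg


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def _checksum(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write report tables.

    Returns the manifest (also written to ``manifest.json`` in the output
    directory): stage parameters, named child seeds, and per-stage output
    checksums. Any stage error aborts with the stage name; outputs of
    completed stages are preserved on disk.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = SeedSequence(config.seed)
    child = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(
            ("simulate", "lme", "decode", "pac", "bursts"), seeds.spawn(5)
        )
    }
    manifest: dict = {
        "config": _jsonable(asdict(config)),
        "seeds": child,
        "stages": {},
    }

    stage = "simulate"
    try:
        if config.dataset_path:
            trial_sets, behav = read_dataset(config.dataset_path)
            behav = median_split(behav) if "intensity_class" not in behav else behav
        else:
            from .synthdata import generate_dataset

            trial_sets, behav = generate_dataset(config.sim_config())
            write_dataset(out / "dataset.h5", trial_sets, behav)
        manifest["stages"][stage] = {
            "n_participants": len(trial_sets),
            "checksum": _checksum(trial_sets[0].data),
        }
        logger.info("stage %s done", stage)

        stage = "tfr"
        freqs = config.freqs()
        tfr_ob = [
            tfr_mod.superlet_transform(
                ts.data[:, ts.region_index("OB"), :], freqs,
                base_cycles=config.base_cycles, frame_rate=config.frame_rate,
                fs=ts.fs, time=ts.time,
            )
            for ts in trial_sets
        ]
        tfr_pc = [
            tfr_mod.superlet_transform(
                ts.data[:, ts.region_index("PC"), :], freqs,
                base_cycles=config.base_cycles, frame_rate=config.frame_rate,
                fs=ts.fs, time=ts.time,
            )
            for ts in trial_sets
        ]
        pooled_ob = tfr_mod.concat_tfr(tfr_ob)
        manifest["stages"][stage] = {"checksum": _checksum(pooled_ob.power)}
        logger.info("stage %s done", stage)

        if config.run_lme:
            stage = "lme"
            stat, clusters = masslme_mod.lme_cluster_analysis(
                pooled_ob, behav, predictor=config.predictor,
                n_perm=config.n_perm, seed=child["lme"],
                forming_alpha=config.forming_alpha,
                weight_exponent=config.weight_exponent,
            )
            _write_cluster_tsv(out / "lme_clusters.tsv", clusters, "OB")
            manifest["stages"][stage] = {
                "n_clusters": len(clusters.clusters),
                "min_p": clusters.min_p,
                "checksum": _checksum(stat.t),
            }
            logger.info("stage %s done", stage)

        gcs = None
        if config.run_connectivity:
            stage = "granger"
            gcs = []
            for ts in trial_sets:
                csd = conn_mod.multitaper_csd(
                    ts, window=config.granger_window,
                    smoothing_hz=config.smoothing_hz,
                )
                gc = conn_mod.spectral_granger(csd)
                gc.participant = ts.participant
                gcs.append(gc)
            rows = []
            for band_name, band in (("beta", config.beta_band),
                                    ("gamma", config.gamma_band)):
                contrast = conn_mod.direction_contrast(gcs, band)
                rows.append(
                    {"band": band_name, "t": contrast["t"], "p": contrast["p"],
                     "mean_contrast": contrast["mean_contrast"]}
                )
            pd.DataFrame(rows).to_csv(out / "granger.tsv", sep="\t", index=False)
            manifest["stages"][stage] = {"bands": rows}
            logger.info("stage %s done", stage)

        if config.run_decode:
            stage = "decode"
            coh_by_class: dict[str, dict[str, tfr_mod.CoherenceMap]] = {}
            offset = 0
            for ts, tx, ty in zip(trial_sets, tfr_ob, tfr_pc):
                sub = behav.iloc[offset : offset + ts.n_trials]
                offset += ts.n_trials
                per_class = {}
                for cls in ("low", "high"):
                    idx = np.flatnonzero(
                        (sub["intensity_class"] == cls).to_numpy()
                    )
                    if idx.size >= 2:
                        per_class[cls] = tfr_mod.coherence_spectrogram(
                            tx, ty, idx, label=cls
                        )
                coh_by_class[ts.participant] = per_class
            grid = decode_mod.build_searchlight_grid(
                pooled_ob.freqs, pooled_ob.frames,
                bin_hz=config.decode_bin_hz, bin_sec=config.decode_bin_sec,
            )
            feats, labels, parts = decode_mod.build_features(coh_by_class, grid)
            dmap = decode_mod.shuffle_null_test(
                feats, labels, parts, grid, n_shuffles=config.n_shuffles,
                seed=child["decode"], forming_alpha=config.forming_alpha,
                weight_exponent=config.weight_exponent,
            )
            _write_decode_tsv(out / "decode_clusters.tsv", dmap)
            manifest["stages"][stage] = {
                "max_accuracy": float(dmap.accuracy.max()),
                "n_clusters": len(dmap.clusters.clusters),
            }
            logger.info("stage %s done", stage)

        if config.run_pac:
            stage = "pac"
            mi_all, rows = [], []
            for ts in trial_sets:
                res = pac_mod.trial_pac(
                    ts, phase_band=config.pac_phase_band,
                    amp_band=config.pac_amp_band,
                    window_center=config.pac_window_center,
                )
                mi_all.append(res.mi)
                for j, mi in enumerate(res.mi):
                    rows.append(
                        {"participant": ts.participant, "trial": j, "mi": mi,
                         "window": f"{res.window[0]:.3f}-{res.window[1]:.3f}"}
                    )
            pd.DataFrame(rows).to_csv(out / "pac_mi.tsv", sep="\t", index=False)
            mi = np.concatenate(mi_all)
            pac_stats = pac_mod.pac_lme(mi, behav, predictor=config.predictor)
            manifest["stages"][stage] = {
                "t": pac_stats["t"], "p": pac_stats["p"],
                "checksum": _checksum(mi),
            }
            logger.info("stage %s done", stage)

        if config.run_bursts:
            stage = "bursts"
            rows = []
            band = config.burst_bands[0]
            all_events = []
            offset = 0
            for ts, tmap in zip(trial_sets, tfr_ob):
                events = bursts_mod.detect_bursts(tmap, band, region="OB")
                for ev in events:
                    rows.append(
                        {"participant": ts.participant, "trial": ev.trial,
                         "band": f"{band[0]:g}-{band[1]:g}",
                         "onset": ev.onset, "offset": ev.offset,
                         "peak_freq": ev.peak_freq,
                         "duration_cycles": ev.duration_cycles}
                    )
                all_events.append(events)
            pd.DataFrame(rows).to_csv(out / "bursts.tsv", sep="\t", index=False)
            manifest["stages"][stage] = {"n_events": len(rows)}
            logger.info("stage %s done", stage)

    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _write_cluster_tsv(path: Path, clusters: masslme_mod.ClusterResult,
                       region: str) -> None:
    rows = []
    for c in clusters.clusters:
        rows.append(
            {
                "region": region,
                "freq_lo": c.get("freq_range", (np.nan, np.nan))[0],
                "freq_hi": c.get("freq_range", (np.nan, np.nan))[1],
                "time_lo": c.get("time_range", (np.nan, np.nan))[0],
                "time_hi": c.get("time_range", (np.nan, np.nan))[1],
                "mass": c["mass"],
                "peak_t": c["peak_t"],
                "p_corrected": c["p_corrected"],
            }
        )
    pd.DataFrame(
        rows,
        columns=["region", "freq_lo", "freq_hi", "time_lo", "time_hi",
                 "mass", "peak_t", "p_corrected"],
    ).to_csv(path, sep="\t", index=False)


def _write_decode_tsv(path: Path, dmap) -> None:
    rows = []
    for c in dmap.clusters.clusters:
        rows.append(
            {
                "freq_lo": c.get("freq_range", (np.nan, np.nan))[0],
                "freq_hi": c.get("freq_range", (np.nan, np.nan))[1],
                "time_lo": c.get("time_range", (np.nan, np.nan))[0],
                "time_hi": c.get("time_range", (np.nan, np.nan))[1],
                "mass": c["mass"],
                "p_corrected": c["p_corrected"],
            }
        )
    pd.DataFrame(
        rows,
        columns=["freq_lo", "freq_hi", "time_lo", "time_hi", "mass",
                 "p_corrected"],
    ).to_csv(path, sep="\t", index=False)
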