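"""End-to-end orchestration: simulate -> behavior -> decode -> time
generalization -> source mapping -> spectral analysis -> power bins ->
band-filtered decoding -> report.

Every stage reads its inputs from the run directory and writes its outputs
there (HDF5 for arrays, JSON for statistics, CSV for tables), so deleting a
downstream artifact and re-running regenerates identical content for the
same config and seed.  Default sizes are CI-scale; ``RunConfig.full_scale()``
selects the full design (33 subjects, 5000 cluster permutations, 500
label permutations for the z maps).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import bincouple, decode, sigproc, sourcemap, stats, synthgen

log = logging.getLogger("oscmem")

STAGES = ("simulate", "behavior", "decode", "timegen", "sourcemap", "tfr",
          "bins", "banddecode", "report")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    sim: synthgen.SimulationConfig = field(
        default_factory=lambda: synthgen.SimulationConfig(n_subjects=12))
    decode_sfreq: float = 100.0
    highpass_hz: float = 0.5
    highpass_order: int = 6
    cov_lowpass_hz: float = 30.0
    probe_window: tuple = (-0.2, 0.7)       # s around probe onset
    train_window: tuple = (0.4, 0.7)        # s after probe onset
    pre_distractor: float = 0.5             # s before distractor (test window)
    retention_window: tuple = (0.0, 1.0)    # s, full test axis for matrices
    tfr_freqs: tuple = (2.0, 30.0, 1.0)     # lo, hi, step (Hz)
    tfr_window: tuple = (-1.5, 0.5)         # s around distractor onset
    tfr_step: float = 0.025
    tfr_cycles: float = 4.0
    binpower_window: tuple = (0.4, 1.0)     # s after retention onset
    lcmv_lam: float = 0.05
    n_perm_cluster: int = 1000
    n_perm_z: int = 100
    min_valid_rt: int = 10                  # per condition, for the RT test
    virtual_sensor: str = "truth"           # truth | argmax
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.sim, dict):
            self.sim = synthgen.SimulationConfig.from_dict(self.sim)
        self.sim.seed = self.seed

    @classmethod
    def full_scale(cls, seed: int = 0) -> "RunConfig":
        cfg = cls(seed=seed)
        cfg.sim.n_subjects = 33
        cfg.n_perm_cluster = 5000
        cfg.n_perm_z = 500
        return cfg

    # -- lossless text round-trip -------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"] = self.sim.to_dict()
        for key in ("probe_window", "train_window", "retention_window",
                    "tfr_freqs", "tfr_window", "binpower_window"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("probe_window", "train_window", "retention_window",
                    "tfr_freqs", "tfr_window", "binpower_window"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(),
                                             sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    # -- derived windows (absolute epoch time) ------------------------------
    @property
    def abs_probe_window(self) -> tuple:
        t = self.sim.t_probe
        return (t + self.probe_window[0], t + self.probe_window[1])

    @property
    def abs_train_window(self) -> tuple:
        t = self.sim.t_probe
        return (t + self.train_window[0], t + self.train_window[1])

    @property
    def abs_test_window(self) -> tuple:
        t = self.sim.t_distractor
        return (t - self.pre_distractor, t)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if np.isnan(f) else f
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _write_json(path, payload) -> None:
    Path(path).write_text(json.dumps(_jsonable(payload), indent=2,
                                     sort_keys=True))


def _preprocessed(cfg: RunConfig, epochs: synthgen.EpochSet
                  ) -> synthgen.EpochSet:
    """The standard preprocessing for every analysis path: zero-phase
    high-pass on the raw epochs."""
    spec = sigproc.FilterSpec("highpass", (cfg.highpass_hz,),
                              order=cfg.highpass_order, zero_phase=True)
    return sigproc.filter_epochs(epochs, spec)


def _iter_preprocessed(cfg: RunConfig, rundir: Path):
    path = rundir / "epochs.h5"
    for key in synthgen.subject_keys(path):
        ep, st = synthgen.load_epochs(path, key)
        yield _preprocessed(cfg, ep), st


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: RunConfig, rundir: Path) -> Path:
    out = rundir / "epochs.h5"
    sim = synthgen.Simulator(cfg.sim)
    synthgen.save_epochs(out, sim.iter_subjects(), sim.truth_skeleton())
    return out


def behavioral_analysis(trials: pd.DataFrame, min_valid_rt: int = 10) -> dict:
    """Per-subject accuracy and mean RT per condition, a one-sided paired t
    for each measure (strong hypothesized worse: lower accuracy, slower RT),
    and paired Cohen's d.  Subjects with fewer than ``min_valid_rt`` correct
    trials in either condition are dropped from the RT test."""
    per = (trials.groupby(["subject", "condition"])
           .agg(accuracy=("response_correct", "mean"),
                n_trials=("response_correct", "size")).reset_index())
    rts = (trials[trials.response_correct]
           .groupby(["subject", "condition"])
           .agg(rt=("rt_ms", "mean"), n_valid=("rt_ms", "size"))
           .reset_index())
    acc = per.pivot(index="subject", columns="condition", values="accuracy")
    if acc.isna().any().any():
        raise ValueError("a subject lacks trials in one condition")
    t_acc, df_acc, p_acc = stats.paired_t(acc["strong"], acc["weak"],
                                          sided="less")
    d_acc = stats.cohens_d(acc["strong"], acc["weak"])

    rt = rts.pivot(index="subject", columns="condition", values="rt")
    n_valid = rts.pivot(index="subject", columns="condition",
                        values="n_valid")
    keep = (n_valid >= min_valid_rt).all(axis=1) & rt.notna().all(axis=1)
    rt = rt[keep]
    rt_stats = None
    if len(rt) >= 2:
        t_rt, df_rt, p_rt = stats.paired_t(rt["strong"], rt["weak"],
                                           sided="greater")
        rt_stats = {"t": t_rt, "df": df_rt, "p_one_sided": p_rt,
                    "cohens_d": stats.cohens_d(rt["strong"], rt["weak"]),
                    "n_subjects": len(rt),
                    "mean_strong_ms": float(rt["strong"].mean()),
                    "mean_weak_ms": float(rt["weak"].mean())}
    return {
        "accuracy": {"t": t_acc, "df": df_acc, "p_one_sided": p_acc,
                     "cohens_d": d_acc, "n_subjects": len(acc),
                     "mean_strong": float(acc["strong"].mean()),
                     "mean_weak": float(acc["weak"].mean())},
        "rt": rt_stats,
        "per_subject": {"accuracy": acc.reset_index().to_dict("list"),
                        "rt": rt.reset_index().to_dict("list")},
    }


def stage_behavior(cfg: RunConfig, rundir: Path) -> dict:
    path = rundir / "epochs.h5"
    tables = [synthgen.load_epochs(path, k)[0].trials
              for k in synthgen.subject_keys(path)]
    rec = behavioral_analysis(pd.concat(tables, ignore_index=True),
                              cfg.min_valid_rt)
    _write_json(rundir / "behavior.json", rec)
    return rec


def onset_detection(times: np.ndarray, group_auc: np.ndarray,
                    n_perm: int = 1000, seed: int | None = None,
                    alpha: float = 0.05):
    """Earliest time inside the first significant positive cluster of a
    group one-sample cluster test of AUC time courses against 0.5; None if
    no cluster survives."""
    res = stats.cluster_permutation(group_auc - 0.5, n_perm=n_perm, seed=seed)
    onsets = [times[c.cells.min()] for c in res.significant(alpha)
              if c.mass > 0]
    return (float(min(onsets)) if onsets else None), res


def stage_decode(cfg: RunConfig, rundir: Path) -> dict:
    cv = decode.CVSpec(seed=cfg.seed)
    aucs, weights, times = [], [], None
    for ep, _ in _iter_preprocessed(cfg, rundir):
        res = decode.temporal_decoding(
            ep, ep.trials["probe_in_set"].to_numpy(), cfg.abs_probe_window,
            cv=cv, decode_sfreq=cfg.decode_sfreq, fit_full=True)
        aucs.append(res.auc)
        weights.append(res.full_weights)
        times = res.times
    aucs = np.array(aucs)
    onset, cluster = onset_detection(times - cfg.sim.t_probe, aucs,
                                     n_perm=cfg.n_perm_cluster,
                                     seed=cfg.seed + 101)
    with h5py.File(rundir / "decode.h5", "w") as f:
        f.create_dataset("times", data=times)
        f.create_dataset("auc", data=aucs)
        f.create_dataset("weights", data=np.array(weights))
    peak = float(aucs.mean(axis=0).max())
    rec = {"onset_s_post_probe": onset, "peak_group_auc": peak,
           "min_cluster_p": cluster.min_p,
           "mean_auc_train_window": float(
               aucs[:, (times >= cfg.abs_train_window[0] - 1e-9)
                    & (times <= cfg.abs_train_window[1] + 1e-9)].mean())}
    _write_json(rundir / "decode.json", rec)
    return rec


def stage_timegen(cfg: RunConfig, rundir: Path) -> dict:
    test_window = (cfg.sim.t_retention + cfg.retention_window[0],
                   cfg.sim.t_retention + cfg.retention_window[1])
    mats = {"strong": [], "weak": []}
    strengths = {"strong": [], "weak": []}
    tg_ref = None
    for ep, _ in _iter_preprocessed(cfg, rundir):
        labels = ep.trials["probe_in_set"].to_numpy()
        groups = {c: (ep.trials["condition"] == c).to_numpy()
                  for c in synthgen.CONDITIONS}
        tg = decode.time_generalization(ep, labels, cfg.abs_probe_window,
                                        test_window, groups=groups,
                                        decode_sfreq=cfg.decode_sfreq)
        tg_ref = tg["strong"]
        for c in synthgen.CONDITIONS:
            mats[c].append(tg[c].auc)
            strengths[c].append(decode.memory_strength(
                tg[c], cfg.abs_train_window, cfg.abs_test_window))
    train_times, test_times = tg_ref.train_times, tg_ref.test_times
    trm = ((train_times >= cfg.abs_train_window[0] - 1e-9)
           & (train_times <= cfg.abs_train_window[1] + 1e-9))
    tem = ((test_times >= cfg.abs_test_window[0] - 1e-9)
           & (test_times <= cfg.abs_test_window[1] + 1e-9))
    strong = np.array(mats["strong"])
    weak = np.array(mats["weak"])
    block = np.ix_(np.arange(strong.shape[0]), np.flatnonzero(trm),
                   np.flatnonzero(tem))
    contrast = stats.cluster_permutation(strong[block], weak[block],
                                         n_perm=cfg.n_perm_cluster,
                                         seed=cfg.seed + 202)
    t_s, df_s, p_s = stats.one_sample_t(np.array(strengths["strong"]), 0.5)
    t_w, df_w, p_w = stats.one_sample_t(np.array(strengths["weak"]), 0.5)
    t_c, df_c, p_c = stats.paired_t(np.array(strengths["strong"]),
                                    np.array(strengths["weak"]))
    with h5py.File(rundir / "timegen.h5", "w") as f:
        f.create_dataset("train_times", data=train_times)
        f.create_dataset("test_times", data=test_times)
        for c in synthgen.CONDITIONS:
            f.create_dataset(f"auc_{c}", data=np.array(mats[c]))
        f.create_dataset("contrast_t", data=contrast.stat_map)
        f.create_dataset("contrast_mask", data=contrast.mask)
    rec = {
        "strength": {c: strengths[c] for c in synthgen.CONDITIONS},
        "strength_mean": {c: float(np.mean(strengths[c]))
                          for c in synthgen.CONDITIONS},
        "condition_paired_t": {"t": t_c, "df": df_c, "p": p_c},
        "below_chance": {
            "strong": {"t": t_s, "df": df_s, "p": p_s},
            "weak": {"t": t_w, "df": df_w, "p": p_w}},
        "contrast_cluster_min_p": contrast.min_p,
        "contrast_n_significant": len(contrast.significant()),
    }
    _write_json(rundir / "timegen.json", rec)
    return rec


def stage_sourcemap(cfg: RunConfig, rundir: Path) -> dict:
    truth = synthgen.load_truth(rundir / "epochs.h5")
    adjacency = synthgen.grid_adjacency(truth.forward)
    zmaps = []
    filters_last = None
    for si, (ep, _) in enumerate(_iter_preprocessed(cfg, rundir)):
        low = sigproc.filter_epochs(
            ep, sigproc.FilterSpec("lowpass", (cfg.cov_lowpass_hz,),
                                   order=6, zero_phase=True))
        cov = sourcemap.epoch_covariance(low)
        filters = sourcemap.lcmv_filters(truth.forward, cov, cfg.lcmv_lam)
        filters_last = filters
        dec = sigproc.resample_epochs(low, cfg.decode_sfreq)
        mask = dec.time_mask(cfg.abs_train_window)
        X = dec.data[:, :, mask]
        labels = ep.trials["probe_in_set"].to_numpy()
        # collapsed over the post-probe decoding interval before z-scoring
        zmap = sourcemap.permutation_zscore(X, labels, cov, filters,
                                            n_perm=cfg.n_perm_z,
                                            seed=cfg.seed + 303 + si,
                                            collapse=True)
        zmaps.append(zmap.z[:, 0])
    zmaps = np.array(zmaps)
    group = stats.cluster_permutation(zmaps, adjacency=adjacency,
                                      n_perm=cfg.n_perm_cluster,
                                      seed=cfg.seed + 304)
    group_mean = zmaps.mean(axis=0)
    argmax = int(np.argmax(group_mean))
    vs_index = (truth.planted_source_index if cfg.virtual_sensor == "truth"
                else argmax)
    with h5py.File(rundir / "sourcemap.h5", "w") as f:
        f.create_dataset("z_collapsed", data=zmaps)
        f.create_dataset("group_mean_z", data=group_mean)
        f.create_dataset("group_t", data=group.stat_map)
        f.create_dataset("group_mask", data=group.mask)
        f.create_dataset("filters", data=filters_last.filters)
        f.create_dataset("grid", data=truth.forward.grid)
    rec = {"argmax_source": argmax,
           "planted_source": truth.planted_source_index,
           "virtual_sensor_source": vs_index,
           "group_cluster_min_p": group.min_p,
           "n_significant_clusters": len(group.significant())}
    _write_json(rundir / "sourcemap.json", rec)
    return rec


def _virtual_sensor_series(cfg: RunConfig, rundir: Path):
    """Virtual-sensor single-trial series per subject (recomputed from the
    epochs and the sourcemap stage's choice of grid point)."""
    truth = synthgen.load_truth(rundir / "epochs.h5")
    rec = json.loads((rundir / "sourcemap.json").read_text())
    vs = int(rec["virtual_sensor_source"])
    for ep, st in _iter_preprocessed(cfg, rundir):
        low = sigproc.filter_epochs(
            ep, sigproc.FilterSpec("lowpass", (cfg.cov_lowpass_hz,),
                                   order=6, zero_phase=True))
        cov = sourcemap.epoch_covariance(low)
        filters = sourcemap.lcmv_filters(truth.forward, cov, cfg.lcmv_lam)
        yield ep, st, sourcemap.virtual_sensor(ep, filters, vs)


def stage_tfr(cfg: RunConfig, rundir: Path) -> dict:
    lo, hi, step = cfg.tfr_freqs
    freqs = np.arange(lo, hi + step / 2, step)
    t0 = cfg.sim.t_distractor
    tfr_times = np.arange(t0 + cfg.tfr_window[0],
                          t0 + cfg.tfr_window[1] + 1e-9, cfg.tfr_step)
    power = {c: [] for c in synthgen.CONDITIONS}
    for ep, _, series in _virtual_sensor_series(cfg, rundir):
        for c in synthgen.CONDITIONS:
            m = (ep.trials["condition"] == c).to_numpy()
            res = sigproc.tfr_hanning(series[m], ep.times, ep.sfreq,
                                      freqs=freqs, tfr_times=tfr_times,
                                      cycles=cfg.tfr_cycles, mode="induced")
            power[c].append(res.power)
    strong = np.array(power["strong"])
    weak = np.array(power["weak"])
    valid = ~np.isnan(strong[0])
    diff = np.where(valid, strong - weak, 0.0)
    contrast = stats.cluster_permutation(diff, n_perm=cfg.n_perm_cluster,
                                         seed=cfg.seed + 404)
    with h5py.File(rundir / "tfr.h5", "w") as f:
        f.create_dataset("freqs", data=freqs)
        f.create_dataset("times", data=tfr_times)
        for c in synthgen.CONDITIONS:
            f.create_dataset(f"power_{c}", data=np.array(power[c]))
        f.create_dataset("contrast_t", data=contrast.stat_map)
        f.create_dataset("contrast_mask", data=contrast.mask)
    rec = {"cluster_min_p": contrast.min_p,
           "n_significant_clusters": len(contrast.significant()),
           "mean_power_strong": float(np.nanmean(strong)),
           "mean_power_weak": float(np.nanmean(weak))}
    _write_json(rundir / "tfr.json", rec)
    return rec


def stage_bins(cfg: RunConfig, rundir: Path) -> dict:
    t_ret = cfg.sim.t_retention
    window = (t_ret + cfg.binpower_window[0], t_ret + cfg.binpower_window[1])
    test_window = cfg.abs_test_window        # 0.5 s before the distractor
    records = []
    for ep, st, series in _virtual_sensor_series(cfg, rundir):
        labels = ep.trials["probe_in_set"].to_numpy()
        powers = {band.name: sigproc.band_power(series, ep.times, ep.sfreq,
                                                band, window)
                  for band in (sigproc.ALPHA, sigproc.BETA)}
        records.extend(bincouple.bin_analysis_subject(
            ep, labels, powers, cfg.abs_train_window, test_window,
            subject=st.subject, decode_sfreq=cfg.decode_sfreq))
    summary = bincouple.BinDecodingSummary.from_records(records)
    summary.frame.to_csv(rundir / "bins.csv", index=False)
    table = summary.anova_table()
    anova = stats.rm_anova_2x2(table, factors=("band", "bin"))
    rec = {"rm_anova": anova.as_dict(), "bands": {}}
    for band in ("alpha", "beta"):
        df = summary.band(band)
        t, dof, p = stats.paired_t(df["strength_low"], df["strength_high"])
        r, rp = bincouple.modulation_strength_correlation(summary, band)
        rec["bands"][band] = {
            "strength_low_mean": float(df["strength_low"].mean()),
            "strength_high_mean": float(df["strength_high"].mean()),
            "paired_t_low_vs_high": {"t": t, "df": dof, "p": p},
            "modulation_mean": float(df["modulation"].mean()),
            "correlation_modulation_vs_high_minus_low": {"r": r, "p": rp},
        }
    _write_json(rundir / "bins.json", rec)
    return rec


def stage_banddecode(cfg: RunConfig, rundir: Path) -> dict:
    cv = decode.CVSpec(seed=cfg.seed)
    per_spec: dict[str, list] = {s.name: [] for s in decode.DEFAULT_BAND_SPECS}
    for ep, _ in _iter_preprocessed(cfg, rundir):
        labels = ep.trials["probe_in_set"].to_numpy()
        res = decode.band_filtered_decoding(ep, labels, cfg.abs_probe_window,
                                            cv=cv,
                                            decode_sfreq=cfg.decode_sfreq)
        for name, r in res.items():
            per_spec[name].append(r.mean_auc(cfg.abs_train_window))
    rec = {"mean_auc": {k: {"per_subject": v, "mean": float(np.mean(v))}
                        for k, v in per_spec.items()}}
    theta = np.array(per_spec["theta"])
    broad = np.array(per_spec["broadband"])
    theta_env = np.array(per_spec["theta_env"])
    if theta.size >= 2:
        t1, d1, p1 = stats.paired_t(theta, broad)
        t2, d2, p2 = stats.paired_t(theta, theta_env)
        rec["theta_vs_broadband"] = {"t": t1, "df": d1, "p": p1}
        rec["theta_real_vs_env"] = {"t": t2, "df": d2, "p": p2}
    _write_json(rundir / "banddecode.json", rec)
    return rec


def stage_report(cfg: RunConfig, rundir: Path) -> dict:
    report = {"config": cfg.to_dict()}
    for name, fname in (("behavior", "behavior.json"),
                        ("decoding", "decode.json"),
                        ("time_generalization", "timegen.json"),
                        ("sourcemap", "sourcemap.json"),
                        ("tfr", "tfr.json"),
                        ("bins", "bins.json"),
                        ("band_decoding", "banddecode.json")):
        p = rundir / fname
        report[name] = json.loads(p.read_text()) if p.exists() else None
    _write_json(rundir / "report.json", report)
    return report


_STAGE_FN = {
    "simulate": stage_simulate,
    "behavior": stage_behavior,
    "decode": stage_decode,
    "timegen": stage_timegen,
    "sourcemap": stage_sourcemap,
    "tfr": stage_tfr,
    "bins": stage_bins,
    "banddecode": stage_banddecode,
    "report": stage_report,
}

_STAGE_OUTPUTS = {
    "simulate": ("epochs.h5",),
    "behavior": ("behavior.json",),
    "decode": ("decode.h5", "decode.json"),
    "timegen": ("timegen.h5", "timegen.json"),
    "sourcemap": ("sourcemap.h5", "sourcemap.json"),
    "tfr": ("tfr.h5", "tfr.json"),
    "bins": ("bins.csv", "bins.json"),
    "banddecode": ("banddecode.json",),
    "report": ("report.json",),
}


def run_stage(name: str, cfg: RunConfig, rundir: Path, force: bool = False):
    rundir = Path(rundir)
    rundir.mkdir(parents=True, exist_ok=True)
    outputs = [rundir / f for f in _STAGE_OUTPUTS[name]]
    if not force and all(p.exists() for p in outputs):
        log.info("stage %-10s cached", name)
        return None
    t0 = time.perf_counter()
    try:
        result = _STAGE_FN[name](cfg, rundir)
    except Exception as err:
        log.error("stage %s failed: %s", name, err)
        raise RuntimeError(f"stage {name!r} failed") from err
    log.info("stage %-10s seed=%d elapsed=%.1fs", name, cfg.seed,
             time.perf_counter() - t0)
    return result


def run_all(cfg: RunConfig, rundir, force: bool = False) -> dict:
    """Execute every stage in dependency order; returns the group report."""
    rundir = Path(rundir)
    rundir.mkdir(parents=True, exist_ok=True)
    cfg.save(rundir / "config.yaml")
    manifest = {"stages": {}, "seed": cfg.seed}
    for name in STAGES:
        run_stage(name, cfg, rundir, force=force)
        manifest["stages"][name] = list(_STAGE_OUTPUTS[name])
    _write_json(rundir / "manifest.json", manifest)
    return json.loads((rundir / "report.json").read_text())
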