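"""Synthetic multi-subject MEG-like epoch generator with known ground truth.

Emulates an auditory Sternberg experiment: per trial, a memory set is
retained (retention onset at t = 0 s), a distractor plays at t = 1 s, a
probe at t = 2 s, and a response prompt at t = 2.7 s.  Each simulated
subject yields an epoch tensor (trials x channels x samples) plus a trial
table (condition, probe label, block, behavior).

Planted structure, all recoverable from :class:`GroundTruth`:

* a decodable spatial pattern (a lead-field column of one grid source, or
  a sensor-level vector) carried by a theta-band transient 0.3-0.7 s after
  the probe; probe-in-set and probe-out-of-set trials carry different
  patterns;
* a weaker reactivation of the same patterns throughout the retention
  period, scaled per condition (sign may be negative, which inverts the
  decodable pattern before strong distractors);
* alpha (13 Hz) and beta (21 Hz) oscillations emitted by the same grid
  source, with log-normal per-trial amplitudes anti-coupled to the trial
  reactivation factor;
* 1/f background noise in every channel;
* Bernoulli accuracies and log-normal reaction times with a small
  condition effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterator

import h5py
import numpy as np
import pandas as pd
from scipy import fft

CONDITIONS = ("strong", "weak")

# substream ids so that independent draws never share a bit stream
_STREAM_LEADFIELD = 11
_STREAM_PATTERNS = 12
_STREAM_SUBJECT = 1000


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """All knobs of the generator.  ``seed`` fully determines the output.

    Amplitudes are expressed in units of the per-channel background-noise
    standard deviation (``noise_std``).
    """

    n_subjects: int = 33
    n_trials: int = 288           # 12 blocks x 24 trials
    n_blocks: int = 12            # six per distractor condition
    n_channels: int = 32
    n_sources: int = 64           # toy lattice grid
    sfreq_raw: float = 256.0
    epoch_window: tuple[float, float] = (-2.0, 2.75)  # s, re retention onset
    t_retention: float = 0.0
    t_distractor: float = 1.0
    t_probe: float = 2.0
    t_prompt: float = 2.7

    # memory pattern: amplitude of the post-probe transient
    pattern_snr: float = 2.0
    pattern_at_sensor: bool = False   # True: patterns are sensor vectors only
    # mean retention-period reactivation per condition (sign allowed)
    reactivation_gain: dict = field(
        default_factory=lambda: {"strong": -0.3, "weak": 2.2})
    # log-normal sd of the per-subject gain multiplier
    reactivation_heterogeneity: float = 0.3
    # log-normal sd of the per-trial reactivation factor
    reactivation_trial_sigma: float = 0.7

    # oscillatory source
    osc_freqs: dict = field(default_factory=lambda: {"alpha": 13.0, "beta": 21.0})
    osc_amp: dict = field(default_factory=lambda: {"alpha": 2.2, "beta": 1.6})
    # coefficients on log-amplitude per unit latent z (negative => high power
    # goes with weak reactivation)
    coupling_alpha: float = -0.8
    coupling_beta: float = -0.6
    # half-range of the uniform per-subject alpha-coupling multiplier
    # (1 +/- this value; the beta coupling is homogeneous across subjects:
    # beta carries the overall bin effect, alpha the individually varying
    # modulation)
    coupling_alpha_heterogeneity: float = 0.75
    # residual sd of log amplitude per band; the larger alpha residual keeps
    # the median-split gap in the regime where it scales with the subject's
    # coupling strength
    osc_residual_sigma: dict = field(
        default_factory=lambda: {"alpha": 0.65, "beta": 0.4})
    # multiplicative condition effect on oscillator amplitude
    osc_condition_gain: dict = field(
        default_factory=lambda: {"strong": 1.15, "weak": 1.0})

    noise_exponent: float = 1.0       # 1/f^exponent background
    noise_std: float = 1.0

    acc_probs: dict = field(default_factory=lambda: {"strong": 0.83, "weak": 0.85})
    rt_mean_ms: dict = field(default_factory=lambda: {"strong": 579.0, "weak": 570.0})
    rt_sigma: float = 0.3             # sd of log RT

    dtype: str = "float32"            # epoch tensor dtype; amplitudes are O(1)
    seed: int = 0

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        if self.n_blocks % 2:
            raise ValueError("n_blocks must be even (half per condition)")
        if self.n_trials % (2 * self.n_blocks):
            raise ValueError("n_trials must be divisible by 2 * n_blocks")
        if self.n_channels < 2 or self.n_sources < 2:
            raise ValueError("need at least 2 channels and 2 sources")
        t0, t1 = self.epoch_window
        for t in (self.t_retention, self.t_distractor, self.t_probe, self.t_prompt):
            if not (t0 <= t <= t1):
                raise ValueError(f"event time {t} outside epoch window")
        for p in self.acc_probs.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("accuracy probabilities must lie in [0, 1]")
        for name, val in asdict(self).items():
            if isinstance(val, (int, float)) and not np.isfinite(val):
                raise ValueError(f"non-finite config value: {name}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["epoch_window"] = list(self.epoch_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "epoch_window" in d:
            d["epoch_window"] = tuple(d["epoch_window"])
        return cls(**d)

    @property
    def times(self) -> np.ndarray:
        n = int(round((self.epoch_window[1] - self.epoch_window[0]) * self.sfreq_raw))
        return self.epoch_window[0] + np.arange(n) / self.sfreq_raw


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ForwardModel:
    """Toy fixed-orientation forward model on a 3-D lattice grid."""

    leadfield: np.ndarray   # (n_sources, n_channels), unit-norm rows
    grid: np.ndarray        # (n_sources, 3) lattice coordinates
    dims: tuple[int, int, int]

    @property
    def n_sources(self) -> int:
        return self.leadfield.shape[0]

    @property
    def n_channels(self) -> int:
        return self.leadfield.shape[1]


@dataclass
class EpochSet:
    """Trials x channels x samples tensor plus a trial table."""

    data: np.ndarray        # (n_trials, n_channels, n_samples)
    times: np.ndarray       # (n_samples,), uniform grid, step 1/sfreq
    sfreq: float
    trials: pd.DataFrame    # subject, block, condition, probe_in_set, ...

    def __post_init__(self):
        if self.data.shape[2] != self.times.size:
            raise ValueError("data/times length mismatch")
        if self.data.shape[0] != len(self.trials):
            raise ValueError("data/trial-table length mismatch")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def copy_with(self, data: np.ndarray, times: np.ndarray | None = None,
                  sfreq: float | None = None) -> "EpochSet":
        return EpochSet(data=data,
                        times=self.times.copy() if times is None else times,
                        sfreq=self.sfreq if sfreq is None else sfreq,
                        trials=self.trials.copy())

    def time_mask(self, window: tuple[float, float]) -> np.ndarray:
        lo, hi = window
        return (self.times >= lo - 1e-9) & (self.times <= hi + 1e-9)

    def crop(self, window: tuple[float, float]) -> "EpochSet":
        m = self.time_mask(window)
        return self.copy_with(self.data[:, :, m], times=self.times[m])


@dataclass
class SubjectTruth:
    """Planted per-trial quantities for one simulated subject."""

    subject: int
    reactivation: np.ndarray      # (n_trials,) signed retention amplitude
    trial_factor: np.ndarray      # (n_trials,) positive log-normal factor
    alpha_amp: np.ndarray         # (n_trials,) oscillator amplitudes
    beta_amp: np.ndarray
    gain_multiplier: float        # per-subject reactivation multiplier
    alpha_coupling: float         # realized per-subject coupling coefficient
    beta_coupling: float


@dataclass
class GroundTruth:
    """Everything needed to recompute any planted quantity."""

    memory_pattern: np.ndarray        # (n_channels,) probe-in-set pattern
    foil_pattern: np.ndarray          # (n_channels,) probe-out pattern
    planted_source_index: int         # grid index carrying pattern + rhythms
    forward: ForwardModel
    subjects: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def _lattice_dims(n: int) -> tuple[int, int, int]:
    """Three near-equal integer factors of n (used as grid dimensions)."""
    best = None
    for a in range(1, int(round(n ** (1 / 3))) + 2):
        if n % a:
            continue
        rest = n // a
        for b in range(a, int(np.sqrt(rest)) + 1):
            if rest % b:
                continue
            c = rest // b
            dims = (a, b, c)
            score = c - a
            if best is None or score < best[0]:
                best = (score, dims)
    if best is None:
        return (1, 1, n)
    return best[1]


def _fibonacci_sphere(n: int, radius: float, center: np.ndarray) -> np.ndarray:
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    pts = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    return center + radius * pts


def make_leadfield(config: SimulationConfig) -> ForwardModel:
    """Deterministic smooth toy lead field, sources x channels, unit-norm rows.

    Sources sit on a 3-D lattice; sensors on a surrounding sphere.  Each
    source is a fixed-orientation dipole in a homogeneous medium; gains fall
    off with squared distance, so neighbouring grid points have similar
    sensor projections.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, _STREAM_LEADFIELD])
    dims = _lattice_dims(config.n_sources)
    gx, gy, gz = np.meshgrid(*[np.arange(d, dtype=float) for d in dims],
                             indexing="ij")
    grid = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    center = grid.mean(axis=0)
    half_diag = np.linalg.norm(grid - center, axis=1).max()
    radius = max(2.0, 1.6 * half_diag)
    sensors = _fibonacci_sphere(config.n_channels, radius, center)

    # smooth orientation field: mostly +z with a spatially smooth perturbation
    raw = rng.standard_normal((config.n_sources, 3))
    d2 = ((grid[:, None, :] - grid[None, :, :]) ** 2).sum(-1)
    smooth = np.exp(-d2 / 2.0)
    smooth /= smooth.sum(axis=1, keepdims=True)
    orient = np.array([0.0, 0.0, 1.0]) + 0.4 * smooth @ raw
    orient /= np.linalg.norm(orient, axis=1, keepdims=True)

    diff = sensors[None, :, :] - grid[:, None, :]       # (src, ch, 3)
    dist = np.linalg.norm(diff, axis=2)
    gains = np.einsum("sd,scd->sc", orient, diff) / dist ** 3
    norms = np.linalg.norm(gains, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("lead field has a zero row")
    return ForwardModel(leadfield=gains / norms, grid=grid, dims=dims)


def grid_adjacency(fwd: ForwardModel) -> np.ndarray:
    """Boolean adjacency (6-connectivity) of the lattice grid."""
    grid = fwd.grid
    d2 = ((grid[:, None, :] - grid[None, :, :]) ** 2).sum(-1)
    return np.isclose(d2, 1.0)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _plateau(times: np.ndarray, start: float, stop: float,
             ramp: float) -> np.ndarray:
    """Smooth plateau window: raised-cosine ramps, flat top, zero outside."""
    env = np.zeros_like(times)
    up = (times >= start) & (times < start + ramp)
    env[up] = 0.5 * (1 - np.cos(np.pi * (times[up] - start) / ramp))
    flat = (times >= start + ramp) & (times <= stop - ramp)
    env[flat] = 1.0
    down = (times > stop - ramp) & (times <= stop)
    env[down] = 0.5 * (1 - np.cos(np.pi * (stop - times[down]) / ramp))
    return env


def _hann_bump(times: np.ndarray, start: float, stop: float) -> np.ndarray:
    env = np.zeros_like(times)
    m = (times >= start) & (times <= stop)
    env[m] = 0.5 * (1 - np.cos(2 * np.pi * (times[m] - start) / (stop - start)))
    return env


def _one_over_f_noise(rng: np.random.Generator, shape: tuple[int, ...],
                      n_samples: int, sfreq: float, exponent: float,
                      std: float, dtype=np.float32) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent amplitude spectrum, unit variance
    scaled to ``std``, generated in the frequency domain.

    Built in single precision with in-place spectral shaping; the epoch
    tensors dominate the generator's memory and runtime.
    """
    freqs = np.fft.rfftfreq(n_samples, 1.0 / sfreq)
    amp = np.zeros(freqs.size, dtype=dtype)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    ctype = np.complex64 if dtype == np.float32 else np.complex128
    spec = np.empty(shape + (freqs.size,), dtype=ctype)
    re = rng.standard_normal(shape + (freqs.size,), dtype=dtype)
    re *= amp
    spec.real = re
    re = rng.standard_normal(shape + (freqs.size,), dtype=dtype)
    re *= amp
    spec.imag = re
    # scipy.fft keeps single precision; numpy would upcast complex64
    x = fft.irfft(spec, n=n_samples, axis=-1).astype(dtype, copy=False)
    # theoretical std of irfft of CN(0, 2 amp^2) coefficients
    sigma = np.sqrt(2.0 * np.sum(amp.astype(np.float64) ** 2)) / n_samples
    x *= dtype(std / sigma)
    return x


class Simulator:
    """Deterministic study simulator; per-subject generation is streamable."""

    def __init__(self, config: SimulationConfig):
        config.validate()
        self.config = config
        self.forward = make_leadfield(config)
        rng = np.random.default_rng([config.seed, _STREAM_PATTERNS])
        # the planted source: interior-most grid point (max distance to hull),
        # jittered choice kept deterministic
        grid = self.forward.grid
        center = grid.mean(axis=0)
        self.source_index = int(np.argmin(((grid - center) ** 2).sum(axis=1)))
        lf_row = self.forward.leadfield[self.source_index]
        if config.pattern_at_sensor:
            p = rng.standard_normal(config.n_channels)
            p /= np.linalg.norm(p)
        else:
            p = lf_row.copy()
        # foil pattern: random sensor vector orthogonal to the memory pattern
        q = rng.standard_normal(config.n_channels)
        q -= (q @ p) * p
        q /= np.linalg.norm(q)
        self.memory_pattern = p
        self.foil_pattern = q
        # per-subject heterogeneity (drawn once for the whole study)
        self.gain_multipliers = np.exp(
            config.reactivation_heterogeneity
            * rng.standard_normal(config.n_subjects)
            - config.reactivation_heterogeneity ** 2 / 2)
        het = config.coupling_alpha_heterogeneity
        self.alpha_couplings = config.coupling_alpha * rng.uniform(
            1.0 - het, 1.0 + het, config.n_subjects)

    def truth_skeleton(self) -> GroundTruth:
        return GroundTruth(memory_pattern=self.memory_pattern,
                           foil_pattern=self.foil_pattern,
                           planted_source_index=self.source_index,
                           forward=self.forward)

    # -- per-subject --------------------------------------------------------
    def subject(self, subject: int) -> tuple[EpochSet, SubjectTruth]:
        cfg = self.config
        if not 0 <= subject < cfg.n_subjects:
            raise IndexError("subject index out of range")
        rng = np.random.default_rng([cfg.seed, _STREAM_SUBJECT + subject])
        times = cfg.times
        n_samples = times.size
        per_block = cfg.n_trials // cfg.n_blocks

        # blockwise condition assignment, half the blocks per condition
        block_cond = np.array(
            ["strong"] * (cfg.n_blocks // 2) + ["weak"] * (cfg.n_blocks // 2))
        rng.shuffle(block_cond)
        block = np.repeat(np.arange(cfg.n_blocks), per_block)
        condition = block_cond[block]
        # probe in/out balanced within every block
        probe_in = np.zeros(cfg.n_trials, dtype=bool)
        for b in range(cfg.n_blocks):
            idx = np.where(block == b)[0]
            half = rng.permutation(idx)[: per_block // 2]
            probe_in[half] = True

        # latent trial state drives reactivation and oscillator amplitudes
        z = rng.standard_normal(cfg.n_trials)
        sig_r = cfg.reactivation_trial_sigma
        trial_factor = np.exp(sig_r * z - sig_r ** 2 / 2)
        gain = np.array([cfg.reactivation_gain[c] for c in condition])
        reactivation = gain * self.gain_multipliers[subject] * trial_factor

        c_a = self.alpha_couplings[subject]
        c_b = cfg.coupling_beta
        res_a = cfg.osc_residual_sigma["alpha"]
        res_b = cfg.osc_residual_sigma["beta"]
        cond_osc = np.array([cfg.osc_condition_gain[c] for c in condition])
        alpha_amp = (cfg.osc_amp["alpha"] * cond_osc
                     * np.exp(c_a * z + res_a * rng.standard_normal(cfg.n_trials)
                              - (c_a ** 2 + res_a ** 2) / 2))
        beta_amp = (cfg.osc_amp["beta"] * cond_osc
                    * np.exp(c_b * z + res_b * rng.standard_normal(cfg.n_trials)
                             - (c_b ** 2 + res_b ** 2) / 2))

        # --- assemble the signal ------------------------------------------
        dtype = np.dtype(cfg.dtype).type
        data = _one_over_f_noise(rng, (cfg.n_trials, cfg.n_channels),
                                 n_samples, cfg.sfreq_raw,
                                 cfg.noise_exponent, cfg.noise_std,
                                 dtype=dtype)

        probe_env = _hann_bump(times, cfg.t_probe + 0.3,
                               cfg.t_probe + 0.7).astype(dtype)
        retention_env = _plateau(times, cfg.t_retention + 0.05,
                                 cfg.t_distractor + 0.05, 0.15).astype(dtype)
        osc_env = _plateau(times, -0.1, cfg.t_distractor + 0.2,
                           0.15).astype(dtype)

        pattern = np.where(probe_in[:, None], self.memory_pattern[None, :],
                           self.foil_pattern[None, :]).astype(dtype)
        # post-probe transient (theta-band bump, trial-consistent polarity)
        # plus the retention-period reactivation of the same patterns
        envelope = (dtype(cfg.pattern_snr) * probe_env[None, :]
                    + reactivation.astype(dtype)[:, None]
                    * retention_env[None, :])          # (trials, samples)
        data += pattern[:, :, None] * envelope[:, None, :]

        # oscillatory source with random phase per trial
        lf = self.forward.leadfield[self.source_index].astype(dtype)
        osc = np.zeros((cfg.n_trials, n_samples), dtype=dtype)
        for amp, f in ((alpha_amp, cfg.osc_freqs["alpha"]),
                       (beta_amp, cfg.osc_freqs["beta"])):
            phase = rng.uniform(0, 2 * np.pi, cfg.n_trials)
            osc += (amp[:, None] * np.sin(
                2 * np.pi * f * times[None, :] + phase[:, None])).astype(dtype)
        osc *= osc_env[None, :]
        data += osc[:, None, :] * lf[None, :, None]

        # --- behavior -------------------------------------------------------
        acc = np.array([cfg.acc_probs[c] for c in condition])
        correct = rng.uniform(size=cfg.n_trials) < acc
        rt_mean = np.array([cfg.rt_mean_ms[c] for c in condition])
        rt = np.exp(np.log(rt_mean) - cfg.rt_sigma ** 2 / 2
                    + cfg.rt_sigma * rng.standard_normal(cfg.n_trials))

        trials = pd.DataFrame({
            "subject": subject,
            "trial": np.arange(cfg.n_trials),
            "block": block,
            "condition": condition,
            "probe_in_set": probe_in,
            "response_correct": correct,
            "rt_ms": rt,
        })
        epochs = EpochSet(data=data, times=times, sfreq=cfg.sfreq_raw,
                          trials=trials)
        truth = SubjectTruth(subject=subject, reactivation=reactivation,
                             trial_factor=trial_factor, alpha_amp=alpha_amp,
                             beta_amp=beta_amp,
                             gain_multiplier=float(self.gain_multipliers[subject]),
                             alpha_coupling=float(c_a), beta_coupling=float(c_b))
        return epochs, truth

    def iter_subjects(self) -> Iterator[tuple[EpochSet, SubjectTruth]]:
        for s in range(self.config.n_subjects):
            yield self.subject(s)


def simulate_dataset(config: SimulationConfig
                     ) -> tuple[list[EpochSet], GroundTruth]:
    """Simulate every subject of the study; see :class:`Simulator` for a
    streaming interface that avoids holding all subjects in memory."""
    sim = Simulator(config)
    truth = sim.truth_skeleton()
    epochs = []
    for ep, st in sim.iter_subjects():
        epochs.append(ep)
        truth.subjects.append(st)
    return epochs, truth


# ---------------------------------------------------------------------------
# HDF5 persistence
# ---------------------------------------------------------------------------

_TRIAL_COLS = ("subject", "trial", "block", "condition", "probe_in_set",
               "response_correct", "rt_ms")


def _write_trials(grp: h5py.Group, trials: pd.DataFrame) -> None:
    t = grp.create_group("trials")
    for col in _TRIAL_COLS:
        vals = trials[col].to_numpy()
        if vals.dtype == object or vals.dtype.kind == "U":
            vals = np.array([str(v).encode() for v in vals])
        t.create_dataset(col, data=vals)


def _read_trials(grp: h5py.Group) -> pd.DataFrame:
    out = {}
    for col in _TRIAL_COLS:
        vals = grp["trials"][col][()]
        if vals.dtype.kind == "S":
            vals = np.array([v.decode() for v in vals])
        out[col] = vals
    df = pd.DataFrame(out)
    df["probe_in_set"] = df["probe_in_set"].astype(bool)
    df["response_correct"] = df["response_correct"].astype(bool)
    return df


def save_epochs(path, subjects: Iterator[tuple[EpochSet, SubjectTruth]],
                truth: GroundTruth, dtype: str = "f4") -> None:
    """Write one group per subject (/data, /times, /trials) plus /truth."""
    with h5py.File(path, "w") as f:
        for ep, st in subjects:
            g = f.create_group(f"subject_{st.subject:03d}")
            g.create_dataset("data", data=ep.data.astype(dtype),
                             compression="gzip", compression_opts=1)
            g.create_dataset("times", data=ep.times)
            g.attrs["sfreq"] = ep.sfreq
            _write_trials(g, ep.trials)
            gt = g.create_group("truth")
            for name in ("reactivation", "trial_factor", "alpha_amp", "beta_amp"):
                gt.create_dataset(name, data=getattr(st, name))
            gt.attrs["gain_multiplier"] = st.gain_multiplier
            gt.attrs["alpha_coupling"] = st.alpha_coupling
            gt.attrs["beta_coupling"] = st.beta_coupling
        tg = f.create_group("truth")
        tg.create_dataset("memory_pattern", data=truth.memory_pattern)
        tg.create_dataset("foil_pattern", data=truth.foil_pattern)
        tg.create_dataset("leadfield", data=truth.forward.leadfield)
        tg.create_dataset("grid", data=truth.forward.grid)
        tg.attrs["dims"] = truth.forward.dims
        tg.attrs["planted_source_index"] = truth.planted_source_index


def subject_keys(path) -> list[str]:
    with h5py.File(path, "r") as f:
        return sorted(k for k in f.keys() if k.startswith("subject_"))


def load_epochs(path, key: str) -> tuple[EpochSet, SubjectTruth]:
    with h5py.File(path, "r") as f:
        g = f[key]
        ep = EpochSet(data=g["data"][()],
                      times=g["times"][()], sfreq=float(g.attrs["sfreq"]),
                      trials=_read_trials(g))
        gt = g["truth"]
        st = SubjectTruth(
            subject=int(ep.trials["subject"].iloc[0]),
            reactivation=gt["reactivation"][()],
            trial_factor=gt["trial_factor"][()],
            alpha_amp=gt["alpha_amp"][()], beta_amp=gt["beta_amp"][()],
            gain_multiplier=float(gt.attrs["gain_multiplier"]),
            alpha_coupling=float(gt.attrs["alpha_coupling"]),
            beta_coupling=float(gt.attrs["beta_coupling"]))
    return ep, st


def load_truth(path) -> GroundTruth:
    with h5py.File(path, "r") as f:
        tg = f["truth"]
        fwd = ForwardModel(leadfield=tg["leadfield"][()], grid=tg["grid"][()],
                           dims=tuple(int(d) for d in tg.attrs["dims"]))
        return GroundTruth(memory_pattern=tg["memory_pattern"][()],
                           foil_pattern=tg["foil_pattern"][()],
                           planted_source_index=int(tg.attrs["planted_source_index"]),
                           forward=fwd)
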