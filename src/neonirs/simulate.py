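"""Synthetic study generator.

Emulates the design of a neonatal vowel-learning fNIRS study: three
participant groups (experimental, active control, passive control), three
test phases (T0 baseline, T1 post-training, T2 post-consolidation), and for
every subject x phase a 3-min resting window followed by an 8-min test
session of randomly ordered 6-s forward/backward vowel trials with 12-16 s
inter-trial intervals, recorded by a two-wavelength (760/850 nm) array at
10 Hz.

Evoked responses are built from a gamma-shaped haemodynamic kernel whose
peak amplitude and peak time carry the plantable group x phase x stimulus
effects; deoxyhaemoglobin is a negatively scaled, delayed copy of the
oxyhaemoglobin trace.  Physiological noise (drift, Mayer waves, respiration,
cardiac pulsation, broadband noise) is added in concentration units;
measurement artifacts (spike jumps and large excursions exceeding 20% of the
device dynamic range) are injected in intensity units after the forward
Beer-Lambert projection, so the preprocessing chain has recoverable targets
at every stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats as _stats

from .montage import Montage, make_montage
from .signals import HemoSeries, MbllParams, RawRecording

GROUPS = ("experimental", "active", "passive")
PHASES = ("T0", "T1", "T2")
STIMULI = ("forward", "backward")

__all__ = [
    "GROUPS", "PHASES", "STIMULI",
    "EventSchedule", "NoiseSpec", "GroundTruth", "StudyConfig", "StudyData",
    "make_test_schedule", "make_training_schedule", "hrf_kernel",
    "simulate_session", "simulate_resting", "forward_mbll", "simulate_study",
    "simulate_feature_table", "simulate_pair_table",
]


# --------------------------------------------------------------------------
# Event schedules
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ScheduledEvent:
    onset: float          # seconds from session start
    duration: float       # seconds
    stimulus_type: str    # "forward" | "backward"
    trial_index: int


@dataclass(frozen=True)
class EventSchedule:
    events: tuple[ScheduledEvent, ...]
    session_kind: str = "test"    # "test" | "training_block" | "resting"
    duration: float = 0.0         # total session span in seconds

    def __post_init__(self) -> None:
        onsets = [e.onset for e in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("event onsets must be strictly increasing")

    @property
    def n_events(self) -> int:
        return len(self.events)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for e in self.events:
            out[e.stimulus_type] = out.get(e.stimulus_type, 0) + 1
        return out


def make_test_schedule(n_forward: int = 12, n_backward: int = 12,
                       trial_dur: float = 6.0,
                       iti_range: tuple[float, float] = (12.0, 16.0),
                       seed: int | np.random.SeedSequence = 0,
                       start_offset: float = 2.0) -> EventSchedule:
    """Randomized test-session schedule: equal-status forward/backward trials,
    each followed by one uniformly drawn silent inter-trial interval.

    ``start_offset`` is a silent lead-in before the first trial so that the
    first epoch's pre-stimulus baseline lies inside the recording.
    """
    if n_forward < 1 and n_backward < 1:
        raise ValueError("need at least one trial")
    lo, hi = iti_range
    if lo > hi:
        raise ValueError("iti_range must satisfy low <= high")
    rng = np.random.default_rng(seed)
    types = ["forward"] * n_forward + ["backward"] * n_backward
    rng.shuffle(types)
    events, t = [], float(start_offset)
    for i, st in enumerate(types):
        events.append(ScheduledEvent(round(t, 4), trial_dur, st, i))
        t += trial_dur + rng.uniform(lo, hi)
    return EventSchedule(tuple(events), "test", duration=t)


def make_training_schedule(n_stimuli: int = 12, n_repetitions: int = 6,
                           trial_dur: float = 6.0,
                           iti: float = 2.0) -> EventSchedule:
    """Fixed-interval training block (forward vowel strings only)."""
    if n_stimuli < 1 or n_repetitions < 1:
        raise ValueError("counts must be >= 1")
    n = n_stimuli * n_repetitions
    events = tuple(
        ScheduledEvent(i * (trial_dur + iti), trial_dur, "forward", i)
        for i in range(n)
    )
    return EventSchedule(events, "training_block",
                         duration=n * (trial_dur + iti))


# --------------------------------------------------------------------------
# Haemodynamic kernel
# --------------------------------------------------------------------------

def hrf_kernel(t_grid: np.ndarray, peak_time: float = 8.0,
               dispersion: float = 3.0, amplitude: float = 1.0) -> np.ndarray:
    """Gamma-density haemodynamic kernel.

    Single-peaked nonnegative curve with its maximum exactly ``amplitude``
    at ``peak_time``; ``dispersion`` is the gamma standard deviation in
    seconds.  Zero for t <= 0.  With the defaults the curve falls below 1%
    of its peak by 20 s.
    """
    if peak_time <= 0 or dispersion <= 0:
        raise ValueError("peak_time and dispersion must be positive")
    t = np.asarray(t_grid, dtype=float)
    # gamma(shape a, scale b): mode (a-1)b = peak_time, sd sqrt(a) b = dispersion
    b = (-peak_time + math.sqrt(peak_time ** 2 + 4 * dispersion ** 2)) / 2.0
    a = 1.0 + peak_time / b
    out = np.zeros_like(t)
    pos = t > 0
    logpeak = (a - 1) * (math.log(peak_time) - 1.0) - math.lgamma(a) - a * math.log(b) + (a - 1)
    # evaluate pdf / pdf(mode) in log space for stability
    with np.errstate(divide="ignore"):
        logf = (a - 1) * np.log(t[pos]) - t[pos] / b
    logmode = (a - 1) * math.log(peak_time) - peak_time / b
    out[pos] = amplitude * np.exp(logf - logmode)
    return out


# --------------------------------------------------------------------------
# Noise and ground truth
# --------------------------------------------------------------------------

@dataclass
class NoiseSpec:
    """Physiological + instrumental noise parameters.

    Concentration-domain components (umol/l): ``drift_amplitude`` (very slow
    sinusoid), ``drift_slope`` (linear, umol/l per s), ``oscillators``
    [(freq Hz, amplitude, phase_jitter rad)] covering Mayer (~0.1 Hz),
    respiratory (~0.7 Hz) and cardiac (~2.5 Hz) bands, ``white_sd``.
    Intensity-domain components (device units / fractions): ``spike_rate``
    (events per minute per channel) with amplitudes drawn from
    ``spike_amp_range``, and ``artifact_rate`` excursions per minute per
    channel with peak-to-peak amplitude ``artifact_amp_range`` expressed as a
    fraction of the device dynamic range (> 0.2 so the artifact-rejection
    rule fires); ``measure_sd`` is broadband detector noise.
    """

    drift_amplitude: float = 0.5
    drift_slope: float = 0.0005
    oscillators: tuple = ((0.1, 0.25, 0.3), (0.7, 0.15, 0.3), (2.5, 0.2, 0.3))
    white_sd: float = 0.15
    spike_rate: float = 1.0
    spike_amp_range: tuple[float, float] = (0.08, 0.18)
    artifact_rate: float = 0.5
    artifact_amp_range: tuple[float, float] = (0.25, 0.6)
    artifact_duration: float = 2.0
    measure_sd: float = 0.002

    def __post_init__(self) -> None:
        if self.drift_amplitude < 0 or self.white_sd < 0:
            raise ValueError("noise amplitudes must be >= 0")
        for f, a, _ in self.oscillators:
            if a < 0:
                raise ValueError("oscillator amplitudes must be >= 0")
            if f >= 5.0:
                raise ValueError("oscillator frequency must stay below the "
                                 "5 Hz Nyquist limit at 10 Hz sampling")

    @classmethod
    def quiet(cls) -> "NoiseSpec":
        """All noise sources disabled."""
        return cls(0.0, 0.0, (), 0.0, 0.0, (0.0, 0.0), 0.0, (0.25, 0.25), 2.0, 0.0)


def _cell(group: str, phase: str, stim: str | None = None) -> str:
    return f"{group}|{phase}" + (f"|{stim}" if stim else "")


@dataclass
class GroundTruth:
    """Plantable effect structure for a synthetic study.

    ``amp_effects`` / ``lat_effects`` map "group|phase|stimulus" cells to
    {"base": value, "per_channel": {channel_id: value}} giving the evoked
    kernel's peak amplitude (umol/l) and peak time (s) per channel.
    ``conn_base_z`` is the baseline inter-channel coupling on the Fisher-z
    scale, ``conn_phase_z`` adds a global phase offset, and ``conn_effects``
    maps "group|phase" to [[chan_a, chan_b, dz], ...] pair increments.
    """

    amp_effects: dict = field(default_factory=dict)
    lat_effects: dict = field(default_factory=dict)
    conn_base_z: float = 0.17
    conn_phase_z: dict = field(default_factory=dict)
    conn_effects: dict = field(default_factory=dict)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    hrf_dispersion: float = 3.0
    hb_ratio: float = -0.3
    hb_delay: float = 1.0
    resting_sd: float = 0.8
    seed: int = 0

    # -- construction ------------------------------------------------------
    @classmethod
    def null(cls, noise: NoiseSpec | None = None, base_amplitude: float = 0.0,
             peak_time: float = 8.0) -> "GroundTruth":
        gt = cls(noise=noise or NoiseSpec())
        for g in GROUPS:
            for p in PHASES:
                for s in STIMULI:
                    key = _cell(g, p, s)
                    gt.amp_effects[key] = {"base": base_amplitude, "per_channel": {}}
                    gt.lat_effects[key] = {"base": peak_time, "per_channel": {}}
        return gt

    @classmethod
    def default(cls, montage: Montage, amp_delta: float = 0.8,
                lat_delta: float = -2.5, conn_delta: float = 0.5,
                base_amplitude: float = 1.0,
                noise: NoiseSpec | None = None) -> "GroundTruth":
        """Study-like effect structure.

        Experimental neonates acquire, relative to active controls, (i) a
        larger forward-minus-backward amplitude difference after consolidation
        (T2), maximal over superior temporal / supramarginal / inferior
        parietal channels; (ii) a shorter forward-response peak latency after
        training (T1 and T2), maximal over inferior frontal channels; and the
        two trained groups gain resting coupling at T2 among the
        frontal-temporal channels (``conn_delta`` on the z scale).
        """
        gt = cls.null(noise=noise, base_amplitude=base_amplitude)
        amp_ch = [c.channel_id for c in montage.channels
                  if c.region_label in ("ST", "SM", "IP")]
        lat_ch = [c.channel_id for c in montage.channels
                  if c.region_label == "IF"]
        for stim, sign in (("forward", +0.5), ("backward", -0.5)):
            key = _cell("experimental", "T2", stim)
            gt.amp_effects[key]["per_channel"] = {
                c: sign * amp_delta for c in amp_ch}
        for phase in ("T1", "T2"):
            key = _cell("experimental", phase, "forward")
            gt.lat_effects[key]["per_channel"] = {c: lat_delta for c in lat_ch}
        gt.conn_phase_z = {"T0": 0.0, "T1": 0.05, "T2": 0.2}
        net = sorted(set(amp_ch) | set(lat_ch))
        pairs = [[a, b] for i, a in enumerate(net) for b in net[i + 1:]]
        for g in ("experimental", "active"):
            gt.conn_effects[_cell(g, "T2")] = [
                [a, b, conn_delta] for a, b in pairs]
        return gt

    # -- lookups -----------------------------------------------------------
    def _vector(self, table: dict, group: str, phase: str, stim: str,
                channel_ids: list[int]) -> np.ndarray:
        key = _cell(group, phase, stim)
        if key not in table:
            raise KeyError(f"no ground-truth cell for {key}")
        cell = table[key]
        out = np.full(len(channel_ids), float(cell["base"]))
        per = cell.get("per_channel", {})
        for i, c in enumerate(channel_ids):
            if c in per:
                out[i] += float(per[c])
            elif str(c) in per:     # JSON round trips keys to str
                out[i] += float(per[str(c)])
        return out

    def amplitude_vector(self, group, phase, stim, channel_ids):
        return self._vector(self.amp_effects, group, phase, stim, channel_ids)

    def peak_vector(self, group, phase, stim, channel_ids):
        return self._vector(self.lat_effects, group, phase, stim, channel_ids)

    def resting_corr(self, group: str, phase: str,
                     channel_ids: list[int]) -> np.ndarray:
        """Target inter-channel correlation matrix (PSD-projected)."""
        n = len(channel_ids)
        z = np.full((n, n), self.conn_base_z + self.conn_phase_z.get(phase, 0.0))
        idx = {c: i for i, c in enumerate(channel_ids)}
        for a, b, dz in self.conn_effects.get(_cell(group, phase), []):
            if a in idx and b in idx:
                z[idx[a], idx[b]] += dz
                z[idx[b], idx[a]] += dz
        r = np.tanh(z)
        np.fill_diagonal(r, 1.0)
        return project_psd(r)

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["noise"]["oscillators"] = [list(o) for o in self.noise.oscillators]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        d = dict(d)
        nd = dict(d.pop("noise"))
        nd["oscillators"] = tuple(tuple(o) for o in nd["oscillators"])
        nd["spike_amp_range"] = tuple(nd["spike_amp_range"])
        nd["artifact_amp_range"] = tuple(nd["artifact_amp_range"])
        return cls(noise=NoiseSpec(**nd), **d)


def project_psd(r: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Project a symmetric matrix onto the PSD cone (eigenvalue clipping)
    and renormalise to unit diagonal."""
    w, v = np.linalg.eigh((r + r.T) / 2.0)
    if w.min() >= 0:
        return r
    w = np.clip(w, floor, None)
    m = (v * w) @ v.T
    d = np.sqrt(np.diag(m))
    m = m / np.outer(d, d)
    np.fill_diagonal(m, 1.0)
    return m


# --------------------------------------------------------------------------
# Session / resting simulation (concentration domain)
# --------------------------------------------------------------------------

def _physio_noise(n_ch: int, n_samples: int, fs: float, noise: NoiseSpec,
                  rng: np.random.Generator) -> np.ndarray:
    t = np.arange(n_samples) / fs
    out = rng.normal(0.0, noise.white_sd, (n_ch, n_samples)) \
        if noise.white_sd > 0 else np.zeros((n_ch, n_samples))
    if noise.drift_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi, n_ch)
        out += noise.drift_amplitude * np.sin(
            2 * np.pi * 0.004 * t[None, :] + phase[:, None])
    if noise.drift_slope != 0:
        out += noise.drift_slope * t[None, :] * rng.normal(1.0, 0.3, (n_ch, 1))
    for f, a, jit in noise.oscillators:
        if a <= 0:
            continue
        phase = rng.uniform(0, 2 * np.pi, n_ch)
        fj = f * (1.0 + rng.normal(0, 0.02, n_ch))
        pj = np.cumsum(rng.normal(0, jit / math.sqrt(fs * 10), (n_ch, n_samples)), axis=1)
        out += a * np.sin(2 * np.pi * fj[:, None] * t[None, :]
                          + phase[:, None] + pj)
    return out


def _delay(x: np.ndarray, n: int) -> np.ndarray:
    if n <= 0:
        return x.copy()
    out = np.zeros_like(x)
    out[:, n:] = x[:, :-n]
    return out


def simulate_session(montage: Montage, schedule: EventSchedule,
                     ground_truth: GroundTruth, group: str, phase: str,
                     subject_seed: int | np.random.SeedSequence = 0,
                     duration_s: float | None = None,
                     sampling_rate: float = 10.0,
                     ) -> tuple[HemoSeries, HemoSeries]:
    """Simulate one test session, returning (clean, noisy) HemoSeries.

    The clean series is the superposition of per-event gamma kernels with
    cell-specific per-channel amplitude and peak time; Hb is a negatively
    scaled, delayed copy of HbO.  The noisy series adds the concentration-
    domain components of the NoiseSpec.
    """
    fs = sampling_rate
    # 20 s tail so the last epoch (-2..20 s) fits inside the recording
    dur = duration_s if duration_s is not None else schedule.duration + 20.0
    last = max(e.onset + e.duration for e in schedule.events)
    if last > dur:
        raise ValueError("schedule extends beyond the requested duration")
    n_samples = int(round(dur * fs))
    n_ch = montage.n_channels
    cids = montage.channel_ids
    hbo = np.zeros((n_ch, n_samples))
    t = np.arange(n_samples) / fs
    for ev in schedule.events:
        amps = ground_truth.amplitude_vector(group, phase, ev.stimulus_type, cids)
        peaks = ground_truth.peak_vector(group, phase, ev.stimulus_type, cids)
        rel = t - ev.onset
        for pk in np.unique(peaks):
            kern = hrf_kernel(rel, peak_time=pk,
                              dispersion=ground_truth.hrf_dispersion)
            sel = peaks == pk
            hbo[sel] += amps[sel, None] * kern[None, :]
    nd = int(round(ground_truth.hb_delay * fs))
    hb = ground_truth.hb_ratio * _delay(hbo, nd)
    clean = HemoSeries(hbo, hb, fs, channel_ids=list(cids))
    clean.log_step("simulate_session", group=group, phase=phase, noise=False)

    rng = np.random.default_rng(subject_seed)
    noise_hbo = _physio_noise(n_ch, n_samples, fs, ground_truth.noise, rng)
    noise_hb = 0.3 * _physio_noise(n_ch, n_samples, fs, ground_truth.noise, rng)
    noisy = HemoSeries(hbo + noise_hbo, hb + noise_hb, fs,
                       channel_ids=list(cids))
    noisy.log_step("simulate_session", group=group, phase=phase, noise=True)
    return clean, noisy


def simulate_resting(montage: Montage, duration_s: float,
                     conn_target: np.ndarray | None = None,
                     noise_params: NoiseSpec | None = None,
                     seed: int | np.random.SeedSequence = 0,
                     sampling_rate: float = 10.0,
                     resting_sd: float = 0.8,
                     hb_ratio: float = -0.3, hb_delay: float = 1.0,
                     ) -> HemoSeries:
    """Band-limited (<= 0.2 Hz dominant) resting-state series whose population
    inter-channel correlation matrix equals ``conn_target`` (identity if
    omitted; PSD-enforced by eigenvalue projection)."""
    if duration_s < 10:
        raise ValueError("resting duration must be >= 10 s")
    from .preprocess import _bandpass_sos  # shared filter design
    from scipy.signal import sosfiltfilt

    fs = sampling_rate
    n = int(round(duration_s * fs))
    n_ch = montage.n_channels
    rng = np.random.default_rng(seed)
    if conn_target is None:
        conn_target = np.eye(n_ch)
    else:
        conn_target = project_psd(np.asarray(conn_target, dtype=float))
    # identically filtered independent sources keep the mixing exact
    pad = int(20 * fs)
    white = rng.standard_normal((n_ch, n + 2 * pad))
    sos = _bandpass_sos(0.01, 0.2, fs)
    band = sosfiltfilt(sos, white, axis=1)[:, pad:pad + n]
    band -= band.mean(axis=1, keepdims=True)
    band /= band.std(axis=1, keepdims=True)
    try:
        L = np.linalg.cholesky(conn_target)
    except np.linalg.LinAlgError as exc:
        raise RuntimeError("target correlation matrix not PSD after "
                           "projection") from exc
    hbo = resting_sd * (L @ band)
    hb = hb_ratio * _delay(hbo, int(round(hb_delay * fs)))
    out = HemoSeries(hbo, hb, fs, channel_ids=list(montage.channel_ids))
    out.log_step("simulate_resting", duration_s=duration_s)
    return out


# --------------------------------------------------------------------------
# Forward modified Beer-Lambert projection
# --------------------------------------------------------------------------

def forward_mbll(hemo: HemoSeries, params: MbllParams | None = None,
                 distance: float = 2.3, i0: float = 1.0,
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Project concentrations to two-wavelength OD changes and intensities.

    dOD_l(t) = (eps_l,HbO dHbO + eps_l,Hb dHb) * distance * dpf_l with
    concentrations in mM, then I_l(t) = i0 * base**(-dOD_l(t)).  Exact linear
    inverse of :func:`neonirs.preprocess.od_to_hemo`.

    Returns (od, intensity), each shaped (channels, 2, time).
    """
    params = params or MbllParams()
    eps = params.eps_matrix
    conc = np.stack([hemo.hbo, hemo.hb], axis=1) / 1000.0  # umol/l -> mM
    od = np.einsum("lc,kct->klt", eps, conc.transpose(0, 1, 2))
    od = np.stack([
        od[:, 0, :] * distance * params.dpf[0],
        od[:, 1, :] * distance * params.dpf[1],
    ], axis=1)
    intensity = i0 * params.log_base ** (-od)
    return od, intensity


# --------------------------------------------------------------------------
# Whole-study simulation
# --------------------------------------------------------------------------

@dataclass
class StudyConfig:
    """Design parameters of a simulated study (defaults = the study design)."""

    group_sizes: dict = field(default_factory=lambda: {
        "experimental": 22, "active": 23, "passive": 21})
    phases: tuple = PHASES
    n_channels: int = 52
    n_forward: int = 12
    n_backward: int = 12
    trial_dur: float = 6.0
    iti_range: tuple[float, float] = (12.0, 16.0)
    resting_duration: float = 180.0
    sampling_rate: float = 10.0
    distance: float = 2.3
    i0: float = 1.0
    dynamic_range: tuple[float, float] = (0.0, 2.0)
    mbll: MbllParams = field(default_factory=MbllParams)

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.group_sizes.values()):
            raise ValueError("every group needs at least one subject")

    @property
    def subjects(self) -> list[tuple[str, str]]:
        """Deterministic (subject_id, group) list."""
        out = []
        for g in sorted(self.group_sizes):
            for i in range(self.group_sizes[g]):
                out.append((f"{g[:3]}{i + 1:02d}", g))
        return out


@dataclass
class StudyData:
    """Handle to a simulated study; recordings are regenerated on demand so
    large studies never have to be held in memory at once."""

    config: StudyConfig
    ground_truth: GroundTruth
    montage: Montage
    seed: int

    def _streams(self, subject_index: int, phase_index: int):
        base = np.random.SeedSequence(
            entropy=self.seed, spawn_key=(subject_index, phase_index))
        return base.spawn(4)  # schedule, session, resting, artifacts

    def schedule(self, subject_index: int, phase_index: int) -> EventSchedule:
        cfg = self.config
        ss = self._streams(subject_index, phase_index)[0]
        return make_test_schedule(cfg.n_forward, cfg.n_backward,
                                  cfg.trial_dur, cfg.iti_range, seed=ss)

    def recording(self, subject_index: int, phase_index: int,
                  ) -> tuple[RawRecording, EventSchedule, dict]:
        """Raw recording = resting window followed by the test session.

        Returns (raw, schedule-with-onsets-in-recording-time, annotation).
        """
        cfg = self.config
        gt = self.ground_truth
        sid, group = cfg.subjects[subject_index]
        phase = cfg.phases[phase_index]
        s_sched, s_sess, s_rest, s_art = self._streams(subject_index, phase_index)
        sched = make_test_schedule(cfg.n_forward, cfg.n_backward,
                                   cfg.trial_dur, cfg.iti_range, seed=s_sched)
        _, noisy = simulate_session(self.montage, sched, gt, group, phase,
                                    subject_seed=s_sess,
                                    sampling_rate=cfg.sampling_rate)
        r_target = gt.resting_corr(group, phase, self.montage.channel_ids)
        rest = simulate_resting(self.montage, cfg.resting_duration,
                                conn_target=r_target, seed=s_rest,
                                sampling_rate=cfg.sampling_rate,
                                resting_sd=gt.resting_sd,
                                hb_ratio=gt.hb_ratio, hb_delay=gt.hb_delay)
        hbo = np.concatenate([rest.hbo, noisy.hbo], axis=1)
        hb = np.concatenate([rest.hb, noisy.hb], axis=1)
        full = HemoSeries(hbo, hb, cfg.sampling_rate,
                          channel_ids=list(self.montage.channel_ids))
        _, intensity = forward_mbll(full, cfg.mbll, cfg.distance, cfg.i0)
        intensity = _add_intensity_artifacts(
            intensity, gt.noise, cfg.sampling_rate, cfg.dynamic_range,
            np.random.default_rng(s_art))
        raw = RawRecording(intensity, cfg.sampling_rate, cfg.dynamic_range,
                           subject_id=sid, group=group, phase=phase)
        offset = cfg.resting_duration
        shifted = EventSchedule(
            tuple(ScheduledEvent(e.onset + offset, e.duration,
                                 e.stimulus_type, e.trial_index)
                  for e in sched.events),
            "test", duration=sched.duration + offset)
        annot = {"resting_onset": 0.0, "resting_duration": cfg.resting_duration,
                 "test_onset": offset}
        return raw, shifted, annot

    def iter_recordings(self):
        for si in range(len(self.config.subjects)):
            for pi in range(len(self.config.phases)):
                yield (si, pi) + self.recording(si, pi)


def _add_intensity_artifacts(intensity: np.ndarray, noise: NoiseSpec,
                             fs: float, dynamic_range: tuple[float, float],
                             rng: np.random.Generator,
                             clip: bool = False) -> np.ndarray:
    """Inject detector noise, spike jumps and large motion excursions
    (peak-to-peak beyond ``artifact_amp_range`` x dynamic-range width)."""
    out = intensity.copy()
    n_ch, _, n = out.shape
    width = dynamic_range[1] - dynamic_range[0]
    minutes = n / fs / 60.0
    if noise.measure_sd > 0:
        out += rng.normal(0, noise.measure_sd, out.shape)
    for c in range(n_ch):
        n_spk = rng.poisson(noise.spike_rate * minutes)
        for _ in range(n_spk):
            i = rng.integers(0, n)
            w = rng.integers(2, 5)
            amp = rng.uniform(*noise.spike_amp_range) * rng.choice([-1, 1])
            out[c, :, i:i + w] += amp
        n_art = rng.poisson(noise.artifact_rate * minutes)
        for _ in range(n_art):
            i = rng.integers(0, n)
            half = max(int(noise.artifact_duration * fs / 2), 1)
            lo, hi = max(0, i - 2 * half), min(n, i + 2 * half)
            tt = np.arange(lo, hi) - i
            # zero-mean motion wiggle with controlled peak-to-peak, so big
            # artifacts trip the 20%-of-range rule without clipping at the
            # dynamic-range limits (the study saw no detector saturation)
            bump = np.exp(-0.5 * (tt / half) ** 2) * np.sin(np.pi * tt / (2 * half))
            span = bump.max() - bump.min()
            if span <= 0:
                continue
            amp = rng.uniform(*noise.artifact_amp_range) * width
            out[c, :, lo:hi] += (amp / span) * bump * rng.choice([-1, 1])
    if clip:
        out = np.clip(out, dynamic_range[0], dynamic_range[1])
    return out


def simulate_study(config: StudyConfig | None = None, seed: int = 0,
                   ground_truth: GroundTruth | None = None) -> StudyData:
    """Build a study handle: montage + ground truth + per-subject streams.

    Recordings are generated lazily through :meth:`StudyData.recording`;
    identical (config, seed) always reproduce identical data.
    """
    config = config or StudyConfig()
    montage = make_montage(config.n_channels)
    gt = ground_truth or GroundTruth.default(montage)
    gt.seed = seed
    return StudyData(config, gt, montage, seed)


# --------------------------------------------------------------------------
# Model-level simulators (used to validate the inference layer)
# --------------------------------------------------------------------------

def simulate_feature_table(n_per_group: int = 8, n_channels: int = 8,
                           n_trials_per_cond: int = 12,
                           effects: dict | None = None,
                           subject_re_sd: dict | None = None,
                           channel_re_sd: dict | None = None,
                           resid_sd: float = 1.0, seed: int = 0,
                           response: str = "mean_amplitude"):
    """Generate a balanced trial-feature table directly under the mixed model.

    ``effects`` maps fixed-term names (see :mod:`neonirs.contrasts`, e.g.
    "stim:grp2:ph2") to coefficients on the contrast-coding scale;
    ``subject_re_sd`` / ``channel_re_sd`` map random-term names to standard
    deviations.  Returns (table, effects) with the response written into
    ``response``.
    """
    import pandas as pd
    from .contrasts import code_contrasts, FIXED_TERMS, SUBJECT_RE_TERMS

    effects = effects or {}
    subject_re_sd = subject_re_sd or {}
    channel_re_sd = channel_re_sd or {}
    rng = np.random.default_rng(seed)
    rows = []
    subjects = []
    for gi, g in enumerate(GROUPS):
        for i in range(n_per_group):
            subjects.append((f"{g[:3]}{i:02d}", g))
    channels = list(range(1, n_channels + 1))
    for sid, g in subjects:
        for p in PHASES:
            for s in STIMULI:
                for tr in range(n_trials_per_cond):
                    for ch in channels:
                        rows.append((sid, g, p, ch, tr, s))
    tab = pd.DataFrame(rows, columns=[
        "subject_id", "group", "phase", "channel_id", "trial_index",
        "stimulus_type"])
    design = code_contrasts(tab)
    y = np.zeros(len(tab))
    for term, beta in effects.items():
        y += beta * design[term].to_numpy()
    subj_codes = tab["subject_id"].astype("category").cat.codes.to_numpy()
    chan_codes = tab["channel_id"].astype("category").cat.codes.to_numpy()
    n_subj, n_chan = subj_codes.max() + 1, chan_codes.max() + 1
    for term, sd in subject_re_sd.items():
        if sd <= 0:
            continue
        b = rng.normal(0, sd, n_subj)
        x = design[term].to_numpy() if term != "1" else np.ones(len(tab))
        y += b[subj_codes] * x
    for term, sd in channel_re_sd.items():
        if sd <= 0:
            continue
        b = rng.normal(0, sd, n_chan)
        x = design[term].to_numpy() if term != "1" else np.ones(len(tab))
        y += b[chan_codes] * x
    y += rng.normal(0, resid_sd, len(tab))
    tab[response] = y
    tab["valid"] = True
    return tab


def simulate_pair_table(n_per_group: int = 8, n_pairs: int = 10,
                        effects: dict | None = None,
                        subject_re_sd: dict | None = None,
                        pair_re_sd: dict | None = None,
                        resid_sd: float = 0.3, seed: int = 0):
    """Balanced connectivity pair table (one z per subject x phase x pair)
    generated directly under the reduced group x phase mixed model."""
    import pandas as pd
    from .contrasts import code_contrasts

    effects = effects or {}
    subject_re_sd = subject_re_sd or {}
    pair_re_sd = pair_re_sd or {}
    rng = np.random.default_rng(seed)
    subjects = [(f"{g[:3]}{i:02d}", g) for g in GROUPS
                for i in range(n_per_group)]
    pairs = [(a, a + 1) for a in range(1, n_pairs + 1)]
    rows = [(sid, g, p, a, b)
            for sid, g in subjects for p in PHASES for a, b in pairs]
    tab = pd.DataFrame(rows, columns=["subject_id", "group", "phase",
                                      "chan_a", "chan_b"])
    design = code_contrasts(tab, stimulus=False)
    y = np.zeros(len(tab))
    for term, beta in effects.items():
        y += beta * design[term].to_numpy()
    subj_codes = tab["subject_id"].astype("category").cat.codes.to_numpy()
    pair_lab = tab["chan_a"].astype(str) + "-" + tab["chan_b"].astype(str)
    pair_codes = pair_lab.astype("category").cat.codes.to_numpy()
    for term, sd in subject_re_sd.items():
        if sd <= 0:
            continue
        b = rng.normal(0, sd, subj_codes.max() + 1)
        x = design[term].to_numpy() if term != "1" else np.ones(len(tab))
        y += b[subj_codes] * x
    for term, sd in pair_re_sd.items():
        if sd <= 0:
            continue
        b = rng.normal(0, sd, pair_codes.max() + 1)
        x = design[term].to_numpy() if term != "1" else np.ones(len(tab))
        y += b[pair_codes] * x
    y += rng.normal(0, resid_sd, len(tab))
    tab["z"] = y
    return tab
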