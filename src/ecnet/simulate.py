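"""Synthetic cohorts with known ground truth.

The generator emulates the statistical structure the analysis assumes, not
scalp biophysics:

* band-limited sources built by zero-phase band-pass filtering white noise
  (order-4 Butterworth) into one of the five classic bands;
* directed lagged couplings: a receiver channel carries the sender's
  band-limited source delayed by a fixed lag tau and scaled by a strength in
  [0, 1], on top of its own independent broadband noise;
* instantaneous volume-conduction-like mixing via a full-rank zero-lag
  mixing matrix (identity plus small symmetric leakage by default);
* stereotyped blink transients with a fixed frontal-weighted scalp
  topography at Poisson-drawn times;
* group-structured subjective (SAM valence/arousal/dominance, integers 1-9)
  and behavioral (reaction time, accuracy) outcomes drawn from Gaussians
  around group means and truncated/rounded into valid ranges.

Every generated object is returned together with its ground truth (coupling
edge list, blink times, group effect parameters) so downstream recovery
tests read the truth instead of re-deriving it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal

from .config import DEFAULT_BANDS
from .io import EEGRecording
from .montage import Montage, default_montage

GROUPS = ("GB&W", "CCI", "WCI")


@dataclass
class Coupling:
    sender: str
    receiver: str
    lag_ms: float
    strength: float
    band: str = "alpha"

    def __post_init__(self) -> None:
        if self.lag_ms <= 0:
            raise ValueError("causal coupling needs lag > 0")
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("strength must be in [0, 1]")
        if self.band not in DEFAULT_BANDS:
            raise ValueError(f"unknown band {self.band!r}")


@dataclass
class CouplingSpec:
    couplings: list[Coupling] = field(default_factory=list)
    noise_sd: float = 10.0        # uV, broadband per-channel noise
    duration: float = 30.0        # s
    fs: float = 256.0             # Hz
    mixing: np.ndarray | None = None   # channels x channels, zero-lag
    montage: Montage | None = None

    def resolved_montage(self) -> Montage:
        return self.montage or default_montage()


def leakage_mixing(n: int, gain: float = 0.1,
                   positions: np.ndarray | None = None) -> np.ndarray:
    """Identity plus symmetric off-diagonal leakage (volume-conduction stand-in).

    With positions given, leakage falls off with inter-electrode angle;
    otherwise it is uniform.
    """
    if positions is not None:
        cos = np.clip(positions @ positions.T, -1, 1)
        off = gain * np.exp(-2.0 * np.arccos(cos))
    else:
        off = np.full((n, n), gain)
    M = np.eye(n) + off
    np.fill_diagonal(M, 1.0)
    return M


def _band_noise(n: int, fs: float, band: tuple[float, float],
                rng: np.random.Generator) -> np.ndarray:
    lo, hi = band
    sos = signal.butter(4, [lo, min(hi, fs / 2 * 0.99)], btype="bandpass",
                        fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def simulate_coupled_eeg(spec: CouplingSpec, seed: int,
                         ) -> tuple[EEGRecording, list[dict]]:
    """Simulate a recording with the given directed lagged couplings.

    Returns the mixed recording and the ground-truth edge list (one dict per
    coupling with sender, receiver, lag and strength).
    """
    mont = spec.resolved_montage()
    rng = np.random.default_rng(seed)
    n_samp = int(round(spec.duration * spec.fs))
    n_ch = len(mont)
    nper = int(round(spec.fs / 0.5))
    if n_samp < 10 * nper // 2:
        raise ValueError("duration too short for stable spectral estimation "
                         "(need >= 10 half-overlapped segments)")
    max_lag = 0
    for c in spec.couplings:
        if c.sender not in mont.channels or c.receiver not in mont.channels:
            raise ValueError(f"coupling channel not in montage: {c}")
        max_lag = max(max_lag, int(round(c.lag_ms / 1000.0 * spec.fs)))
    if max_lag >= nper:
        raise ValueError("coupling lag is not shorter than a spectral segment")
    pad = max_lag
    total = n_samp + pad
    # broadband background noise, independent per channel
    data = np.stack([
        _band_noise(total, spec.fs, (0.5, 48.0), rng) for _ in range(n_ch)
    ]) * spec.noise_sd
    truth = []
    for c in spec.couplings:
        lag = int(round(c.lag_ms / 1000.0 * spec.fs))
        src = _band_noise(total, spec.fs, DEFAULT_BANDS[c.band], rng) * spec.noise_sd
        i, j = mont.index(c.sender), mont.index(c.receiver)
        data[i] += src
        if c.strength > 0:
            delayed = np.roll(src, lag)
            data[j] += c.strength * delayed
        truth.append({"sender": c.sender, "receiver": c.receiver,
                      "lag_ms": c.lag_ms, "strength": c.strength,
                      "band": c.band})
    data = data[:, pad:]
    if spec.mixing is not None:
        M = np.asarray(spec.mixing, dtype=float)
        if M.shape != (n_ch, n_ch):
            raise ValueError("mixing matrix shape mismatch")
        if np.linalg.matrix_rank(M) < n_ch:
            raise ValueError("mixing matrix is singular")
        data = M @ data
    rec = EEGRecording(data, fs=spec.fs, labels=mont.channels)
    return rec, truth


def blink_waveform(fs: float, width_s: float = 0.4) -> np.ndarray:
    """Stereotyped blink transient: a raised-cosine pulse."""
    n = int(round(width_s * fs))
    return 0.5 * (1 - np.cos(2 * np.pi * np.arange(n) / n))


def frontal_topography(montage: Montage) -> np.ndarray:
    """Per-channel blink gains decaying from the front of the scalp."""
    pos = montage.position_array()
    front = pos[:, 1]  # +y is the front midline
    g = np.clip(front, 0, None) ** 2
    return g / g.max() if g.max() > 0 else g


def inject_blinks(rec: EEGRecording, rate: float, topography: np.ndarray,
                  amplitude: float, seed: int,
                  ) -> tuple[EEGRecording, np.ndarray]:
    """Add blink transients at Poisson times; returns the contaminated
    recording and the ground-truth event times (seconds).

    ``rate`` is in events per minute; ``amplitude`` is the peak deflection in
    uV at the maximally exposed channel.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    topography = np.asarray(topography, dtype=float)
    if topography.shape != (rec.n_channels,):
        raise ValueError("topography length must equal channel count")
    rng = np.random.default_rng(seed)
    if rate == 0:
        return rec, np.array([])
    wave = blink_waveform(rec.fs) * amplitude
    n_wave = len(wave)
    t = 0.0
    times = []
    while True:
        t += rng.exponential(60.0 / rate)
        if t * rec.fs + n_wave >= rec.n_samples:
            break
        times.append(t)
    data = rec.data.copy()
    for t in times:
        s = int(round(t * rec.fs))
        data[:, s:s + n_wave] += topography[:, None] * wave[None, :]
    return rec.copy_with(data), np.array(times)


# ---------------------------------------------------------------------------
# cohort-level simulation


@dataclass
class GroupEffects:
    """Group-structured generator parameters.

    SAM change means come from the published pre/post group means (valence
    5.14 -> 7.71 and arousal 4.64 -> 6.43 for warm-colored illustrations,
    valence 5.07 -> 7.43 for cool-colored); the s.d. of the within-subject
    change (1.34) is back-derived from the reported paired t statistic at
    n = 14.  Behavioral means are free parameters chosen to give effect
    sizes of the same order as the published F statistics.  Coupling
    strengths during learning are stronger for the colored groups, with
    anterior -> posterior theta/alpha topology.
    """

    # post-minus-pre SAM change means per group, (V, A, D)
    sam_delta: dict[str, tuple[float, float, float]] = field(default_factory=lambda: {
        "GB&W": (0.0, 0.0, 0.0),
        "CCI": (2.36, 0.9, 0.0),
        "WCI": (2.57, 1.79, 0.0),
    })
    sam_delta_sd: float = 1.34
    sam_baseline_mean: float = 5.0
    sam_baseline_sd: float = 1.2
    # behavioral (RT ms, ACC %) means per group: RT1, ACC1, RT2, ACC2
    rt1_mean: dict[str, float] = field(default_factory=lambda: {
        "GB&W": 3000.0, "CCI": 3100.0, "WCI": 2400.0})
    rt2_mean: dict[str, float] = field(default_factory=lambda: {
        "GB&W": 3200.0, "CCI": 3400.0, "WCI": 2700.0})
    acc1_mean: dict[str, float] = field(default_factory=lambda: {
        "GB&W": 70.0, "CCI": 78.0, "WCI": 72.0})
    acc2_mean: dict[str, float] = field(default_factory=lambda: {
        "GB&W": 55.0, "CCI": 67.0, "WCI": 55.0})
    rt_sd: float = 550.0
    acc_sd: float = 10.0
    # anterior -> posterior coupling strength during learning, per group
    coupling_strength: dict[str, float] = field(default_factory=lambda: {
        "GB&W": 0.25, "CCI": 0.5, "WCI": 0.65})
    eo_strength: float = 0.15
    # per-z-unit modulation of learning coupling strength by the subject's
    # arousal change (injects a metric-outcome dependence of known sign)
    arousal_coupling_slope: float = 0.12

    def scaled(self, factor: float) -> "GroupEffects":
        """All group effects multiplied by ``factor`` (0 = null cohort)."""
        eff = GroupEffects(
            sam_delta={g: tuple(factor * x for x in v)
                       for g, v in self.sam_delta.items()},
            sam_delta_sd=self.sam_delta_sd,
            sam_baseline_mean=self.sam_baseline_mean,
            sam_baseline_sd=self.sam_baseline_sd,
            rt_sd=self.rt_sd, acc_sd=self.acc_sd,
            eo_strength=self.eo_strength,
            arousal_coupling_slope=factor * self.arousal_coupling_slope,
        )
        for attr in ("rt1_mean", "rt2_mean", "acc1_mean", "acc2_mean",
                     "coupling_strength"):
            base = getattr(self, attr)
            ref = float(np.mean(list(base.values())))
            setattr(eff, attr,
                    {g: ref + factor * (v - ref) for g, v in base.items()})
        return eff


#: learning-task coupling topology: (sender, receiver, band, lag_ms)
LEARNING_COUPLINGS = (
    ("F3", "P3", "theta", 25.0),
    ("F4", "P4", "theta", 25.0),
    ("Fp1", "P3", "alpha", 30.0),
    ("Fp2", "P4", "alpha", 30.0),
)


@dataclass
class Subject:
    id: str
    group: str
    pre_sam: tuple[int, int, int]
    post_sam: tuple[int, int, int]
    rt1: float
    acc1: float
    rt2: float
    acc2: float
    eo: EEGRecording | None = None
    learning: EEGRecording | None = None

    def sam_change(self) -> tuple[int, int, int]:
        return tuple(int(b) - int(a) for a, b in zip(self.pre_sam, self.post_sam))


@dataclass
class CohortDataset:
    subjects: list[Subject]
    effects: GroupEffects
    ground_truth: dict

    def group(self, name: str) -> list[Subject]:
        return [s for s in self.subjects if s.group == name]

    def __len__(self) -> int:
        return len(self.subjects)


def _sam_score(rng: np.random.Generator, mean: float, sd: float) -> int:
    return int(np.clip(np.round(rng.normal(mean, sd)), 1, 9))


def simulate_cohort(effects: GroupEffects | None = None, n_per_group: int = 14,
                    seed: int = 0, with_eeg: bool | tuple = True,
                    duration: float = 30.0, fs: float = 256.0,
                    mixing_gain: float = 0.1,
                    ) -> CohortDataset:
    """Generate a balanced three-group cohort with ground truth attached.

    Each subject carries pre/post SAM ratings, recall reaction times and
    accuracies for both tests, and (optionally) eyes-open and learning
    recordings whose anterior -> posterior theta/alpha couplings follow the
    group- and arousal-dependent strengths in ``effects``.  ``with_eeg``
    may also be an iterable of group names to generate recordings for a
    subset only; the behavioral draws are identical either way.
    """
    if n_per_group < 2:
        raise ValueError("need n_per_group >= 2")
    eff = effects or GroupEffects()
    rng = np.random.default_rng(seed)
    mont = default_montage()
    mix = leakage_mixing(len(mont), mixing_gain, mont.position_array())
    subjects = []
    strengths: dict[str, float] = {}
    for g in GROUPS:
        for k in range(n_per_group):
            sid = f"{g}-{k + 1:02d}"
            pre = tuple(_sam_score(rng, eff.sam_baseline_mean, eff.sam_baseline_sd)
                        for _ in range(3))
            delta = eff.sam_delta[g]
            post = tuple(
                int(np.clip(np.round(p + rng.normal(d, eff.sam_delta_sd)), 1, 9))
                for p, d in zip(pre, delta))
            rt1 = max(200.0, rng.normal(eff.rt1_mean[g], eff.rt_sd))
            rt2 = max(200.0, rng.normal(eff.rt2_mean[g], eff.rt_sd))
            acc1 = float(np.clip(rng.normal(eff.acc1_mean[g], eff.acc_sd), 0, 100))
            acc2 = float(np.clip(rng.normal(eff.acc2_mean[g], eff.acc_sd), 0, 100))
            da = post[1] - pre[1]
            z = (da - eff.sam_delta[g][1]) / max(eff.sam_delta_sd, 1e-9)
            s_learn = float(np.clip(
                eff.coupling_strength[g] + eff.arousal_coupling_slope * z,
                0.0, 1.0))
            strengths[sid] = s_learn
            eo = learn = None
            sub_seed = int(rng.integers(0, 2 ** 31 - 1))
            want_eeg = (with_eeg is True
                        or (not isinstance(with_eeg, bool) and g in with_eeg))
            if want_eeg:
                eo_spec = CouplingSpec(
                    couplings=[Coupling(s, r, lag, eff.eo_strength, band)
                               for s, r, band, lag in LEARNING_COUPLINGS],
                    duration=duration, fs=fs, mixing=mix, montage=mont)
                eo, _ = simulate_coupled_eeg(eo_spec, sub_seed)
                eo.condition = "EO"
                l_spec = CouplingSpec(
                    couplings=[Coupling(s, r, lag, s_learn, band)
                               for s, r, band, lag in LEARNING_COUPLINGS],
                    duration=duration, fs=fs, mixing=mix, montage=mont)
                learn, _ = simulate_coupled_eeg(l_spec, sub_seed + 1)
                learn.condition = "L"
            subjects.append(Subject(sid, g, pre, post, rt1, acc1, rt2, acc2,
                                    eo, learn))
    truth = {
        "effects": _effects_dict(eff),
        "couplings": [{"sender": s, "receiver": r, "band": b, "lag_ms": lag}
                      for s, r, b, lag in LEARNING_COUPLINGS],
        "subject_strengths": strengths,
        # sign of the injected dependence between receiver in-strength and
        # the arousal change, per the positive arousal_coupling_slope
        "expected_corr_sign": 1.0 if eff.arousal_coupling_slope > 0 else
        (-1.0 if eff.arousal_coupling_slope < 0 else 0.0),
    }
    return CohortDataset(subjects=subjects, effects=eff, ground_truth=truth)


def _effects_dict(eff: GroupEffects) -> dict:
    d = asdict(eff)
    return d
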