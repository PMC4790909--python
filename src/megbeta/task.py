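"""Synthetic relevance-modulation (RM) task and signal generators.

The RM task is a visual target-detection paradigm in which task relevance is
manipulated independently of the stimulus: butterfly and ladybird images
alternate within each block, and the block instruction makes one type
relevant and the other irrelevant.  Eight blocks follow the fixed pattern
B-L-L-B-L-B-B-L, each with 40 stimuli (20 + 20, alternating), target
probability 0.05 on relevant trials, 800 ms stimulus duration,
onset-to-onset intervals drawn from Normal(1930, 40) ms, and a 30 s rest
period after every block.

Everything downstream of real MEG recordings can be exercised on the
synthetic signals produced here, with the injected ground truth stored
alongside, so the whole pipeline is testable without any data download:

* trial-averaged beta-band envelope series built from known dual-Weibull
  components plus AR(1) noise (:func:`simulate_envelope_dataset`);
* continuous amplitude-modulated band-limited carriers for the spectrogram
  stage (:func:`simulate_oscillatory_trials`);
* single-dipole magnetometer-array recordings for the beamformer
  (:func:`simulate_sensor_data`);
* gamma-band envelopes correlated at a chosen level with an integrative
  beta curve (:func:`simulate_coupled_gamma`).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .weibull import FS, N_SAMPLES, sample_times_ms, weibull_pdf, weibull_peak

__all__ = [
    "Trial",
    "EventSchedule",
    "generate_schedule",
    "GroundTruthParams",
    "EnvelopeDataset",
    "simulate_envelope_dataset",
    "simulate_oscillatory_trials",
    "SensorScenario",
    "simulate_sensor_data",
    "simulate_coupled_gamma",
    "helmet_sensors",
    "default_study_params",
    "null_study_params",
]

BLOCK_PATTERN = "BLLBLBBL"
BLOCK_TYPES = {"B": "butterflies-relevant", "L": "ladybirds-relevant"}
STIM_OF_BLOCK = {"B": "butterfly", "L": "ladybird"}
N_STIM_PER_BLOCK = 40
TARGET_P = 0.05
ISI_MEAN_MS = 1930.0
ISI_SD_MS = 40.0
STIM_DURATION_MS = 800.0
REST_MS = 30_000.0
INSTRUCTION_MS = 2_000.0

GROUPS = ("control", "patient")
NETWORKS = ("insula", "motor")
CONDITIONS = ("relevant", "irrelevant")


@dataclass(frozen=True)
class Trial:
    onset_ms: float
    block_index: int  # 1..8
    block_type: str
    stimulus_type: str
    is_relevant: bool
    is_target: bool


@dataclass(frozen=True)
class EventSchedule:
    """One session's trial list and rest windows."""

    trials: tuple[Trial, ...]
    rest_windows: tuple[tuple[float, float], ...]
    stimulus_duration_ms: float = STIM_DURATION_MS
    seed: int | None = None

    def onsets_ms(self, condition: str | None = None,
                  include_targets: bool = False) -> np.ndarray:
        """Onsets in ms, optionally restricted to one relevance condition.

        Target trials are excluded by default (they carry button presses
        and are dropped from the MEG analysis).
        """
        sel = []
        for tr in self.trials:
            if not include_targets and tr.is_target:
                continue
            if condition == "relevant" and not tr.is_relevant:
                continue
            if condition == "irrelevant" and tr.is_relevant:
                continue
            sel.append(tr.onset_ms)
        return np.asarray(sel, dtype=float)

    @property
    def duration_ms(self) -> float:
        return self.rest_windows[-1][1]


def generate_schedule(seed: int) -> EventSchedule:
    """Generate one RM-task session; deterministic for a fixed seed.

    Targets are drawn i.i.d. with probability 0.05 on relevant trials only
    (the task logic never makes an ignored stimulus a target).
    """
    if not (isinstance(seed, (int, np.integer)) and seed >= 0):
        raise ValueError("seed must be a nonnegative integer")
    rng = np.random.default_rng(seed)
    trials: list[Trial] = []
    rest: list[tuple[float, float]] = []
    t = 0.0
    for block_index, code in enumerate(BLOCK_PATTERN, start=1):
        block_type = BLOCK_TYPES[code]
        relevant_stim = STIM_OF_BLOCK[code]
        t += INSTRUCTION_MS
        isis = rng.normal(ISI_MEAN_MS, ISI_SD_MS, size=N_STIM_PER_BLOCK - 1)
        onset = t
        for j in range(N_STIM_PER_BLOCK):
            stim = "butterfly" if j % 2 == 0 else "ladybird"
            is_rel = stim == relevant_stim
            is_target = bool(is_rel and rng.random() < TARGET_P)
            trials.append(
                Trial(float(onset), block_index, block_type, stim, is_rel,
                      is_target)
            )
            if j < N_STIM_PER_BLOCK - 1:
                onset += isis[j]
        end_of_block = onset + ISI_MEAN_MS
        rest.append((end_of_block, end_of_block + REST_MS))
        t = end_of_block + REST_MS
    return EventSchedule(tuple(trials), tuple(rest), seed=seed)


@dataclass(frozen=True)
class GroundTruthParams:
    """Ground-truth dual-Weibull parameters for one simulated condition.

    Amplitudes are expressed as the *peak deflection* of the component in
    envelope units (the linear coefficient is amplitude divided by the
    unit-curve peak value), so they are directly comparable with
    ``noise_sd``, the stationary standard deviation of the additive AR(1)
    envelope noise.
    """

    local_scale_ms: float = 350.0
    local_shape: float = 3.0
    local_amplitude: float = -1.0
    integrative_scale_ms: float = 900.0
    integrative_shape: float = 3.0
    integrative_amplitude: float = 1.0
    noise_sd: float = 0.3
    ar1_coefficient: float = 0.9
    sampling_rate_hz: float = FS

    def __post_init__(self):
        if self.local_amplitude >= 0:
            raise ValueError("local amplitude must be strictly negative")
        if not (283.0 <= self.local_scale_ms <= 450.0):
            raise ValueError("local scale must lie in [283, 450] ms")
        if not (500.0 <= self.integrative_scale_ms <= 1700.0):
            raise ValueError("integrative scale must lie in [500, 1700] ms")
        if not (2.0 <= self.integrative_shape <= 4.0):
            raise ValueError("integrative shape must lie in [2, 4]")
        if not (0.0 <= self.ar1_coefficient < 1.0):
            raise ValueError("AR(1) coefficient must lie in [0, 1)")
        p_loc = weibull_peak(self.local_scale_ms, self.local_shape)
        p_int = weibull_peak(self.integrative_scale_ms, self.integrative_shape)
        if p_int <= p_loc:
            raise ValueError("integrative peak must be later than local peak")


def _unit_peak_value(a: float, b: float) -> float:
    """Peak value of the unit Weibull density (1/ms)."""
    return float(weibull_pdf(weibull_peak(a, b), a, b))


def ground_truth_series(params: GroundTruthParams,
                        n_samples: int = N_SAMPLES) -> np.ndarray:
    """Noise-free envelope deflection implied by ``params``."""
    t = sample_times_ms(n_samples, params.sampling_rate_hz)
    loc = params.local_amplitude / _unit_peak_value(
        params.local_scale_ms, params.local_shape
    ) * weibull_pdf(t, params.local_scale_ms, params.local_shape)
    integ = params.integrative_amplitude / _unit_peak_value(
        params.integrative_scale_ms, params.integrative_shape
    ) * weibull_pdf(t, params.integrative_scale_ms, params.integrative_shape)
    return loc + integ


def ar1_noise(rng: np.random.Generator, n: int, sd: float, phi: float) -> np.ndarray:
    """AR(1) envelope noise with stationary standard deviation ``sd``."""
    if sd == 0:
        return np.zeros(n)
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    eps = rng.normal(0.0, innov_sd, size=n)
    out = np.empty(n)
    x = rng.normal(0.0, sd)  # stationary start
    for k in range(n):
        x = phi * x + eps[k]
        out[k] = x
    return out


@dataclass
class EnvelopeDataset:
    """Simulated per-subject trial-averaged beta envelopes + ground truth.

    ``data[(group, subject, network, condition)]`` is a 900-sample series;
    ``truth`` holds the per-subject realized :class:`GroundTruthParams`.
    """

    data: dict[tuple[str, str, str, str], np.ndarray]
    truth: dict[tuple[str, str, str, str], GroundTruthParams]
    subjects: dict[str, tuple[str, ...]]  # group -> subject ids
    seed: int

    def keys(self):
        return self.data.keys()


def simulate_envelope_dataset(
    n_per_group: int | dict[str, int],
    params: dict[tuple[str, str, str], GroundTruthParams],
    seed: int,
    amplitude_sigma: float = 0.2,
    scale_jitter_ms: float = 30.0,
    shape_jitter: float = 0.3,
    n_samples: int = N_SAMPLES,
) -> EnvelopeDataset:
    """Simulate trial-averaged beta envelopes for a two-group study.

    Parameters
    ----------
    n_per_group : int or mapping
        Subjects per group (e.g. ``{"control": 12, "patient": 10}``).
    params : mapping
        ``(group, network, condition) -> GroundTruthParams`` defining the
        condition means; per-subject jitter is applied on top (set the
        jitter arguments to 0 to disable).  Within one subject the same
        jitter multipliers/offsets are shared across networks and
        conditions, so condition contrasts are driven by the condition
        means, not by jitter.
    """
    if isinstance(n_per_group, int):
        if n_per_group < 2:
            raise ValueError("need at least 2 subjects per group")
        n_per_group = {g: n_per_group for g in GROUPS}
    rng = np.random.default_rng(seed)
    data: dict = {}
    truth: dict = {}
    subjects: dict[str, tuple[str, ...]] = {}
    networks = sorted({k[1] for k in params})
    conditions = sorted({k[2] for k in params})
    for group, n_subj in n_per_group.items():
        ids = tuple(f"{group[0]}{i + 1:02d}" for i in range(n_subj))
        subjects[group] = ids
        for sid in ids:
            amp_mult = rng.lognormal(0.0, amplitude_sigma) if amplitude_sigma else 1.0
            d_aloc = rng.uniform(-scale_jitter_ms, scale_jitter_ms) if scale_jitter_ms else 0.0
            d_aint = rng.uniform(-3 * scale_jitter_ms, 3 * scale_jitter_ms) if scale_jitter_ms else 0.0
            d_bint = rng.uniform(-shape_jitter, shape_jitter) if shape_jitter else 0.0
            for network in networks:
                for condition in conditions:
                    base = params[(group, network, condition)]
                    def clip(x, lo, hi):
                        return float(min(max(x, lo), hi))
                    subj = replace(
                        base,
                        local_scale_ms=clip(base.local_scale_ms + d_aloc, 283.0, 450.0),
                        integrative_scale_ms=clip(
                            base.integrative_scale_ms + d_aint, 500.0, 1700.0
                        ),
                        integrative_shape=clip(base.integrative_shape + d_bint, 2.0, 4.0),
                        local_amplitude=base.local_amplitude * amp_mult,
                        integrative_amplitude=base.integrative_amplitude * amp_mult,
                    )
                    series = ground_truth_series(subj, n_samples) + ar1_noise(
                        rng, n_samples, subj.noise_sd, subj.ar1_coefficient
                    )
                    key = (group, sid, network, condition)
                    data[key] = series
                    truth[key] = subj
    return EnvelopeDataset(data, truth, subjects, seed)


def default_study_params(
    noise_sd: float = 0.3, ar1: float = 0.9
) -> dict[tuple[str, str, str], GroundTruthParams]:
    """Condition means emulating the qualitative study pattern.

    In the insula, controls show a larger integrative (ERS) component for
    relevant than irrelevant stimuli while patients show the reverse; in
    the motor network both groups show the same modest relevance effect.
    The early local (ERD) component is identical everywhere.
    """
    base = dict(local_scale_ms=350.0, local_amplitude=-1.0,
                integrative_scale_ms=900.0, integrative_shape=3.0,
                noise_sd=noise_sd, ar1_coefficient=ar1)
    amp = {
        ("control", "insula", "relevant"): 2.0,
        ("control", "insula", "irrelevant"): 1.0,
        ("patient", "insula", "relevant"): 1.0,
        ("patient", "insula", "irrelevant"): 2.0,
        ("control", "motor", "relevant"): 1.8,
        ("control", "motor", "irrelevant"): 1.2,
        ("patient", "motor", "relevant"): 1.8,
        ("patient", "motor", "irrelevant"): 1.2,
    }
    return {
        key: GroundTruthParams(integrative_amplitude=a, **base)
        for key, a in amp.items()
    }


def null_study_params(
    noise_sd: float = 0.3, ar1: float = 0.9
) -> dict[tuple[str, str, str], GroundTruthParams]:
    """Same mean curve in every group/network/condition (no effects)."""
    p = GroundTruthParams(noise_sd=noise_sd, ar1_coefficient=ar1,
                          integrative_amplitude=1.5)
    return {
        (g, n, c): p for g in GROUPS for n in NETWORKS for c in CONDITIONS
    }


def simulate_oscillatory_trials(
    schedule: EventSchedule,
    carrier_hz: float,
    envelope_fn,
    seed: int,
    baseline_amplitude: float = 1.0,
    noise_sd: float = 0.0,
    epoch_ms: float = 1500.0,
    fs: float = FS,
) -> np.ndarray:
    """Continuous raw signal: amplitude-modulated carrier plus noise.

    ``envelope_fn(t_ms)`` gives the amplitude *deflection* from baseline at
    time ``t_ms`` after each stimulus onset (evaluated over [0, epoch_ms));
    rest periods and inter-trial gaps carry the baseline-amplitude carrier.
    Carrier phase is continuous across the whole recording.
    """
    if not (0.0 < carrier_hz < 150.0):
        raise ValueError("carrier must lie strictly inside (0, 150) Hz")
    rng = np.random.default_rng(seed)
    n = int(np.ceil(schedule.duration_ms / 1000.0 * fs)) + 1
    t_s = np.arange(n) / fs
    amplitude = np.full(n, float(baseline_amplitude))
    n_epoch = int(round(epoch_ms / 1000.0 * fs))
    t_epoch_ms = np.arange(n_epoch) / fs * 1000.0
    deflection = np.asarray(envelope_fn(t_epoch_ms), dtype=float)
    for tr in schedule.trials:
        k0 = int(round(tr.onset_ms / 1000.0 * fs))
        k1 = min(k0 + n_epoch, n)
        amplitude[k0:k1] += deflection[: k1 - k0]
    signal = amplitude * np.sin(2.0 * np.pi * carrier_hz * t_s)
    if noise_sd:
        signal = signal + rng.normal(0.0, noise_sd, size=n)
    return signal


@dataclass(frozen=True)
class SensorScenario:
    """A single dipole in a spherical conductor seen by a magnetometer array."""

    sensor_positions: np.ndarray  # (n, 3) metres
    sensor_orientations: np.ndarray  # (n, 3) unit vectors
    sphere_center: np.ndarray  # (3,)
    dipole_position: np.ndarray  # (3,)
    dipole_orientation: np.ndarray  # (3,) unit vector
    dipole_signal: np.ndarray  # (n_times,)
    noise_sd: float = 0.0

    def __post_init__(self):
        r0 = np.asarray(self.dipole_position) - np.asarray(self.sphere_center)
        nr0 = np.linalg.norm(r0)
        if nr0 < 1e-12:
            raise ValueError("dipole must not sit at the sphere center")
        ori = np.asarray(self.dipole_orientation, dtype=float)
        tangential = ori - (ori @ r0 / nr0**2) * r0
        if np.linalg.norm(tangential) < 1e-9:
            raise ValueError(
                "purely radial dipole produces no external field in a "
                "spherical conductor; choose a tangential component"
            )


def helmet_sensors(n_sensors: int = 120, radius: float = 0.12,
                   center=(0.0, 0.0, 0.0)) -> tuple[np.ndarray, np.ndarray]:
    """Radial magnetometers on the upper hemisphere of a helmet surface.

    A Fibonacci lattice restricted to z > 0 gives near-uniform coverage;
    orientations point radially outward.
    """
    k = np.arange(2 * n_sensors)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (k + 0.5) / n_sensors  # spans (1, -1); keep the top half
    phi = 2.0 * np.pi * k / golden
    keep = z > 0.05
    z, phi = z[keep][:n_sensors], phi[keep][:n_sensors]
    rho = np.sqrt(1.0 - z**2)
    dirs = np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=1)
    pos = np.asarray(center) + radius * dirs
    return pos, dirs


def simulate_sensor_data(scenario: SensorScenario, seed: int = 0) -> np.ndarray:
    """channels x time array: leadfield(dipole) outer dipole_signal + noise."""
    from .beamformer import sarvas_leadfield

    lf = sarvas_leadfield(
        scenario.dipole_position,
        scenario.dipole_orientation,
        scenario.sensor_positions,
        scenario.sensor_orientations,
        scenario.sphere_center,
    )
    data = np.outer(lf, np.asarray(scenario.dipole_signal, dtype=float))
    if scenario.noise_sd:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, scenario.noise_sd, size=data.shape)
    return data


def simulate_coupled_gamma(
    integrative_curve: np.ndarray,
    target_r: float,
    n_bands: int,
    seed: int,
) -> np.ndarray:
    """Gamma-band envelopes correlated with an integrative beta curve.

    Each band is an independent mixture ``r*z + sqrt(1-r^2)*noise`` of the
    standardized curve and unit white noise, so the population correlation
    with the curve is exactly ``target_r`` and the sample correlation
    converges to it with series length.
    """
    if not (-1.0 <= target_r <= 1.0):
        raise ValueError("target_r must lie in [-1, 1]")
    curve = np.asarray(integrative_curve, dtype=float)
    if curve.size < 2:
        raise ValueError("curve needs at least 2 samples")
    sd = curve.std()
    if sd == 0:
        raise ValueError("constant integrative curve: correlation undefined")
    z = (curve - curve.mean()) / sd
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, 1.0, size=(n_bands, curve.size))
    return target_r * z[None, :] + np.sqrt(1.0 - target_r**2) * noise
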