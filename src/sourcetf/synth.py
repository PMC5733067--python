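"""Synthetic multi-subject EEG with known oscillatory generators.

Generates two-condition, multi-subject sensor epochs from dipolar sources
with controlled event-related power modulation (ERD/ERS) and controlled
inter-trial phase locking, plus pink-noise background dipoles and white
sensor noise.  Because the generators are known, every downstream stage
(inverse, source ERSP/ITC, permutation statistics) can be validated against
ground truth:

* an ERD/ERS source is an ongoing oscillation with per-trial uniform random
  phase whose amplitude steps by a gain ``g`` inside the modulation window —
  band power changes by ``g²`` while inter-trial coherence stays at its
  chance level (the change is non-phase-locked);
* a phase-locking source has its phase redrawn at a reset latency from a
  von Mises distribution with concentration ``kappa`` — the expected
  resultant length (hence ITC) is ``I1(kappa)/I0(kappa)`` while the expected
  power is unchanged.

Default scenario dimensions follow the emulated recording setup: 128
channels, 512 Hz analysis rate, epochs from -1 to 3 s around the cue, two
conditions, 11 subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.special

from .containers import SensorEpochs
from .forward import HeadSphere, LeadField, Montage

__all__ = [
    "SourceSpec",
    "Scenario",
    "SimulationResult",
    "simulate_trials",
    "expected_itc",
    "make_null_dataset",
    "pink_noise",
]


@dataclass
class SourceSpec:
    """One dipolar generator with optional ERD/ERS and phase-reset behaviour.

    Parameters
    ----------
    position
        Dipole location, mm, inside the head sphere.  The generator is
        snapped to the nearest source-space voxel at simulation time so
        ground-truth voxel indices are exact.
    orientation
        Unit 3-vector dipole orientation.
    band_center
        Oscillation frequency, Hz.
    modulation
        ``"none"``, ``"erd"`` or ``"ers"``; for the latter two the amplitude
        is multiplied by ``gain`` inside ``modulation_window``.
    gain
        Post/pre amplitude ratio (band power changes by ``gain**2``).
    modulation_window
        ``(t_lo, t_hi)`` seconds relative to the event.
    phase_lock_kappa
        von Mises concentration of the phase redraw at ``reset_time``;
        0 disables phase locking (uniform phase throughout).
    reset_time
        Phase-reset latency, seconds.
    amplitude
        Oscillation amplitude in nA·m-equivalent units.
    conditions
        Condition labels in which the modulation / phase reset is active;
        elsewhere the source contributes its unmodulated oscillation.
    """

    position: tuple[float, float, float]
    orientation: tuple[float, float, float] = (0.0, 0.0, 1.0)
    band_center: float = 10.0
    modulation: str = "none"
    gain: float = 1.0
    modulation_window: tuple[float, float] = (0.5, 1.5)
    phase_lock_kappa: float = 0.0
    reset_time: float = 0.3
    amplitude: float = 30.0
    conditions: tuple[str, ...] = ("MI",)

    def validate(self, sphere: HeadSphere, epoch_window: tuple[float, float]) -> None:
        if np.linalg.norm(self.position) >= sphere.radius_mm:
            raise ValueError("source position outside the head sphere")
        if abs(np.linalg.norm(self.orientation) - 1.0) > 1e-6:
            raise ValueError("orientation must be unit-norm")
        if self.modulation not in ("none", "erd", "ers"):
            raise ValueError("modulation must be none/erd/ers")
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if self.phase_lock_kappa < 0:
            raise ValueError("kappa must be >= 0")
        margin = 2.0 / self.band_center  # keep edges >= 2 cycles away
        lo, hi = epoch_window
        if self.modulation != "none":
            w0, w1 = self.modulation_window
            if w0 >= w1:
                raise ValueError("modulation window must have t_lo < t_hi")
            if w0 < lo + margin or w1 > hi - margin:
                raise ValueError(
                    "modulation window must stay >= 2 cycles from epoch edges"
                )
        if self.phase_lock_kappa > 0 and not (
            lo + margin <= self.reset_time <= hi - margin
        ):
            raise ValueError("reset_time must stay >= 2 cycles from epoch edges")


@dataclass
class Scenario:
    """A full simulated study: sources, noise, subjects, recording geometry."""

    sources: list[SourceSpec] = field(default_factory=list)
    n_background: int = 30
    background_amplitude: float = 10.0
    sensor_noise_sd: float = 2.0  # µV
    n_subjects: int = 11
    n_trials: int = 90  # per condition
    subject_jitter_sd: float = 0.2  # lognormal sd on gain and kappa
    srate: float = 512.0
    epoch_window: tuple[float, float] = (-1.0, 3.0)
    condition_names: tuple[str, ...] = ("MI", "rest")

    def validate(self, sphere: HeadSphere) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.srate <= 0:
            raise ValueError("srate must be positive")
        for s in self.sources:
            s.validate(sphere, self.epoch_window)


@dataclass
class SimulationResult:
    """Simulated epochs plus the ground truth needed by validation tests."""

    epochs: dict[str, dict[str, SensorEpochs]]  # subject -> condition -> epochs
    true_voxels: list[int]  # per source, index into the lead field's grid
    subject_gains: dict[str, list[float]]
    subject_kappas: dict[str, list[float]]

    @property
    def subjects(self) -> list[str]:
        return list(self.epochs)


def pink_noise(n_samples: int, rng: np.random.Generator, slope: float = 1.0) -> np.ndarray:
    """Unit-variance noise with a 1/f^slope average power spectrum."""
    freqs = np.fft.rfftfreq(n_samples)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-slope / 2.0)
    phases = rng.uniform(0, 2 * np.pi, len(freqs))
    spec = amp * np.exp(1j * phases)
    x = np.fft.irfft(spec, n=n_samples)
    sd = x.std()
    return x / sd if sd > 0 else x


def _source_waveform(
    spec: SourceSpec,
    times: np.ndarray,
    active: bool,
    rng: np.random.Generator,
    gain: float,
    kappa: float,
) -> np.ndarray:
    """One trial of the source's moment magnitude time series."""
    phase0 = rng.uniform(0, 2 * np.pi)
    theta = 2 * np.pi * spec.band_center * times + phase0
    if active and kappa > 0:
        psi = rng.vonmises(0.0, kappa)
        post = times >= spec.reset_time
        theta = np.where(
            post,
            2 * np.pi * spec.band_center * (times - spec.reset_time) + psi,
            theta,
        )
    amp = np.full_like(times, spec.amplitude)
    if active and spec.modulation != "none":
        w0, w1 = spec.modulation_window
        amp = np.where((times >= w0) & (times < w1), spec.amplitude * gain, amp)
    return amp * np.cos(theta)


def simulate_trials(
    scenario: Scenario,
    leadfield: LeadField,
    seed: int,
    sphere: HeadSphere = HeadSphere(),
) -> SimulationResult:
    """Simulate sensor epochs for every subject and condition.

    Sources are snapped to the nearest source-space voxel and projected
    through the lead field; pink-noise background dipoles (fresh positions
    per subject, fresh time series per trial) and white sensor noise are
    added.  Fully reproducible given ``seed``.
    """
    scenario.validate(sphere)
    montage = leadfield.montage
    sfreq = scenario.srate
    lo, hi = scenario.epoch_window
    n_samp = int(round((hi - lo) * sfreq))
    t0_index = int(round(-lo * sfreq))
    times = (np.arange(n_samp) - t0_index) / sfreq

    true_voxels = [
        leadfield.source_space.nearest_voxel(np.asarray(s.position, float))
        for s in scenario.sources
    ]
    # fixed per-source sensor topography (M,) per unit moment magnitude
    topos = [
        leadfield.voxel_block(v) @ np.asarray(s.orientation, float)
        for v, s in zip(true_voxels, scenario.sources)
    ]

    root = np.random.SeedSequence(seed)
    subj_seeds = root.spawn(scenario.n_subjects)
    epochs: dict[str, dict[str, SensorEpochs]] = {}
    subject_gains: dict[str, list[float]] = {}
    subject_kappas: dict[str, list[float]] = {}
    V = leadfield.n_voxels

    for si, sseq in enumerate(subj_seeds):
        rng = np.random.default_rng(sseq)
        subject = f"S{si + 1:02d}"
        gains = [
            s.gain * np.exp(rng.normal(0.0, scenario.subject_jitter_sd))
            if s.modulation != "none"
            else s.gain
            for s in scenario.sources
        ]
        kappas = [
            s.phase_lock_kappa * np.exp(rng.normal(0.0, scenario.subject_jitter_sd))
            if s.phase_lock_kappa > 0
            else 0.0
            for s in scenario.sources
        ]
        subject_gains[subject] = gains
        subject_kappas[subject] = kappas

        # subject-specific background dipole geometry
        if scenario.n_background > 0:
            bg_vox = rng.integers(0, V, scenario.n_background)
            bg_ori = rng.normal(size=(scenario.n_background, 3))
            bg_ori /= np.linalg.norm(bg_ori, axis=1, keepdims=True)
            bg_topos = np.stack(
                [leadfield.voxel_block(v) @ o for v, o in zip(bg_vox, bg_ori)]
            )  # (B, M)
        else:
            bg_topos = np.zeros((0, montage.n_channels))

        epochs[subject] = {}
        for cond in scenario.condition_names:
            data = np.zeros((montage.n_channels, n_samp, scenario.n_trials))
            for trial in range(scenario.n_trials):
                sensors = np.zeros((montage.n_channels, n_samp))
                for k, spec in enumerate(scenario.sources):
                    active = cond in spec.conditions
                    wav = _source_waveform(
                        spec, times, active, rng, gains[k], kappas[k]
                    )
                    sensors += np.outer(topos[k], wav)
                for b in range(bg_topos.shape[0]):
                    wav = scenario.background_amplitude * pink_noise(n_samp, rng)
                    sensors += np.outer(bg_topos[b], wav)
                if scenario.sensor_noise_sd > 0:
                    sensors += rng.normal(
                        0.0, scenario.sensor_noise_sd, sensors.shape
                    )
                data[:, :, trial] = sensors
            epochs[subject][cond] = SensorEpochs(
                data=data,
                srate=sfreq,
                t0_index=t0_index,
                channel_names=list(montage.channel_names),
                montage_ref="simulated-cap",
                condition_labels=[cond] * scenario.n_trials,
                subject_id=subject,
            )
    return SimulationResult(epochs, true_voxels, subject_gains, subject_kappas)


def expected_itc(kappa: float) -> float:
    """Expected resultant length of von Mises phases: ``I1(kappa)/I0(kappa)``.

    This is the ground-truth inter-trial coherence of a simulated
    phase-locked source; 0 for uniform phases, -> 1 as the concentration
    grows.  Uses exponentially scaled Bessel functions so large kappa does
    not overflow.
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if np.isinf(kappa):
        return 1.0
    return float(scipy.special.ive(1, kappa) / scipy.special.ive(0, kappa))


def make_null_dataset(n_subjects: int, n_voxels: int, seed: int) -> np.ndarray:
    """Subject-level difference maps with no true effect.

    Returns an ``(n_subjects, n_voxels)`` array of i.i.d. standard normal
    values — the global-null input for family-wise-error calibration of the
    permutation test.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    rng = np.random.default_rng(seed)
    return rng.standard_normal((n_subjects, n_voxels))
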