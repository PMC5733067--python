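"""Source-space time-frequency measures: per-trial analytic signals, ERSP, ITC.

Each band is analysed by computing the band-limited analytic signal of every
sensor channel on every trial (zero-phase frequency-domain band-pass with
raised-cosine transitions, combined with the Hilbert transform by retaining
positive frequencies only), applying the linear inverse to the complex
signals trial by trial, and reducing over trials:

* ERSP — the trial-averaged standardized source power, with the additive
  baseline model: the average power over the baseline window (default
  -850 to -50 ms) is subtracted per voxel, so event-related
  desynchronization is negative and synchronization positive;
* ITC — per voxel the 3-component complex estimate is collapsed to a scalar
  by an orientation rule, and the modulus of the trial-averaged unit phasor
  is taken, giving a value in [0, 1] (0 = random phase, 1 = perfect
  phase locking).

Window averages over the configured band/window table turn the per-voxel
time courses into scalar maps for the statistics stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft

from .containers import SensorEpochs
from .inverse import InverseOperator, apply_inverse, source_power_map

__all__ = [
    "BandWindow",
    "default_band_windows",
    "AnalyticEpochs",
    "SourceTFTimecourse",
    "analytic_epochs",
    "source_ersp",
    "source_itc",
    "window_average",
]

#: default baseline window, seconds relative to the event
BASELINE_WINDOW = (-0.850, -0.050)


@dataclass(frozen=True)
class BandWindow:
    """A frequency band and post-stimulus window of interest."""

    name: str
    f_lo: float
    f_hi: float
    t_lo_ms: float
    t_hi_ms: float
    measure: str  # "ERSP" | "ITC"

    def __post_init__(self) -> None:
        if not self.f_lo < self.f_hi:
            raise ValueError(f"{self.name}: need f_lo < f_hi")
        if not self.t_lo_ms < self.t_hi_ms:
            raise ValueError(f"{self.name}: need t_lo < t_hi")
        if self.measure not in ("ERSP", "ITC"):
            raise ValueError(f"{self.name}: measure must be ERSP or ITC")

    @property
    def window_s(self) -> tuple[float, float]:
        return (self.t_lo_ms / 1000.0, self.t_hi_ms / 1000.0)


def default_band_windows() -> list[BandWindow]:
    """The six band/window cells of the default analysis table."""
    return [
        BandWindow("theta_ersp", 3.0, 5.0, 750.0, 1150.0, "ERSP"),
        BandWindow("alpha_ersp", 9.0, 13.0, 530.0, 750.0, "ERSP"),
        BandWindow("alphabeta_ersp", 9.0, 17.0, 1000.0, 1350.0, "ERSP"),
        BandWindow("delta_itc", 0.2, 2.0, 225.0, 425.0, "ITC"),
        BandWindow("theta_itc", 4.0, 7.0, 480.0, 520.0, "ITC"),
        BandWindow("alpha_itc", 10.0, 12.0, 480.0, 520.0, "ITC"),
    ]


@dataclass
class AnalyticEpochs:
    """Complex band-limited analytic epochs, channels x samples x trials."""

    data: np.ndarray
    srate: float
    t0_index: int
    band: tuple[float, float]
    channel_names: list[str]
    condition_labels: list[str] | None = None
    subject_id: str = ""

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return (np.arange(self.data.shape[1]) - self.t0_index) / self.srate


@dataclass
class SourceTFTimecourse:
    """Per-voxel time course of a source-space measure."""

    values: np.ndarray  # (V, S)
    srate: float
    t0_index: int
    measure: str
    n_trials: int
    band: tuple[float, float]
    undefined_mask: np.ndarray | None = None  # voxels where ITC is undefined

    @property
    def times(self) -> np.ndarray:
        return (np.arange(self.values.shape[1]) - self.t0_index) / self.srate


def _band_mask(freqs: np.ndarray, f_lo: float, f_hi: float, nyq: float) -> np.ndarray:
    """One-sided analytic band-pass response: 2 in band, 0 for f <= 0."""
    tw_lo = min(f_lo, (f_hi - f_lo) / 2.0, 2.0)
    tw_hi = min((f_hi - f_lo) / 2.0, 2.0, max(nyq - f_hi, 1e-6))
    mask = np.zeros_like(freqs)
    f = freqs
    rising = (f > f_lo - tw_lo) & (f < f_lo)
    mask[rising] = 0.5 * (1 - np.cos(np.pi * (f[rising] - (f_lo - tw_lo)) / tw_lo))
    flat = (f >= f_lo) & (f <= f_hi)
    mask[flat] = 1.0
    falling = (f > f_hi) & (f < f_hi + tw_hi)
    mask[falling] = 0.5 * (1 + np.cos(np.pi * (f[falling] - f_hi) / tw_hi))
    mask[f <= 0] = 0.0
    return 2.0 * mask


def analytic_epochs(epochs: SensorEpochs, band: tuple[float, float]) -> AnalyticEpochs:
    """Band-limited analytic signal of every channel and trial.

    Epochs are reflection-padded to suppress edge ringing, transformed,
    multiplied by a one-sided raised-cosine band response (which implements
    the zero-phase band-pass and the Hilbert transform in one step), and
    trimmed back to the original window.
    """
    f_lo, f_hi = band
    nyq = epochs.srate / 2.0
    if not 0 < f_lo < f_hi < nyq:
        raise ValueError(f"band {band} must lie strictly inside (0, {nyq}) Hz")
    duration = epochs.n_samples / epochs.srate
    if (f_hi - f_lo) * duration < 2.0:
        raise ValueError(
            f"band {band} too narrow for a {duration:.2f}-s epoch "
            "(need bandwidth x duration >= 2 cycles)"
        )
    S = epochs.n_samples
    pad = S - 1
    x = np.pad(epochs.data, ((0, 0), (pad, pad), (0, 0)), mode="reflect")
    L = x.shape[1]
    freqs = np.fft.fftfreq(L, d=1.0 / epochs.srate)
    mask = _band_mask(freqs, f_lo, f_hi, nyq)
    X = scipy.fft.fft(x, axis=1)
    z = scipy.fft.ifft(X * mask[None, :, None], axis=1)
    z = z[:, pad : pad + S, :]
    return AnalyticEpochs(
        data=z,
        srate=epochs.srate,
        t0_index=epochs.t0_index,
        band=(f_lo, f_hi),
        channel_names=list(epochs.channel_names),
        condition_labels=epochs.condition_labels,
        subject_id=epochs.subject_id,
    )


def source_ersp(
    analytic: AnalyticEpochs,
    op: InverseOperator,
    baseline_window: tuple[float, float] = BASELINE_WINDOW,
    trial_chunk: int = 16,
) -> SourceTFTimecourse:
    """Trial-averaged standardized source power with additive baseline.

    For trial ``n`` and voxel ``v`` the instantaneous power is the
    standardized power of the inverse estimate of the analytic signal; the
    returned value is the trial average minus its own mean over the baseline
    window, so it is ~0 pre-stimulus by construction and directly signed for
    ERD (negative) / ERS (positive).
    """
    n = analytic.n_trials
    if n == 0:
        raise ValueError("no trials")
    S = analytic.data.shape[1]
    acc = np.zeros((op.n_voxels, S))
    for start in range(0, n, trial_chunk):
        chunk = analytic.data[:, :, start : start + trial_chunk]
        J = apply_inverse(op, chunk)  # (3V, S, c)
        acc += source_power_map(op, J).sum(axis=2)
    mean_p = acc / n
    times = (np.arange(S) - analytic.t0_index) / analytic.srate
    bmask = (times >= baseline_window[0]) & (times < baseline_window[1])
    if not bmask.any():
        raise ValueError("baseline window lies outside the epoch")
    ersp = mean_p - mean_p[:, bmask].mean(axis=1, keepdims=True)
    return SourceTFTimecourse(
        values=ersp,
        srate=analytic.srate,
        t0_index=analytic.t0_index,
        measure="ERSP",
        n_trials=n,
        band=analytic.band,
    )


def _orientations(
    analytic: AnalyticEpochs,
    op: InverseOperator,
    rule: str,
    window: tuple[float, float] | None,
    trial_chunk: int,
) -> np.ndarray:
    """Per-voxel complex unit 3-vector collapsing moments to a scalar."""
    S = analytic.data.shape[1]
    times = (np.arange(S) - analytic.t0_index) / analytic.srate
    if window is None:
        tmask = np.ones(S, bool)
    else:
        tmask = (times >= window[0]) & (times < window[1])
        if not tmask.any():
            raise ValueError("orientation window lies outside the epoch")
    V = op.n_voxels
    C = np.zeros((V, 3, 3), complex)
    n = analytic.n_trials
    for start in range(0, n, trial_chunk):
        chunk = analytic.data[:, tmask, :][:, :, start : start + trial_chunk]
        J = apply_inverse(op, chunk).reshape(V, 3, -1)
        C += np.einsum("vit,vjt->vij", J, np.conj(J))
    if rule == "dominant-svd":
        w, U = np.linalg.eigh(C)
        u = U[:, :, -1]  # eigenvector of the largest eigenvalue
    elif rule == "max-power-component":
        idx = np.argmax(np.einsum("vii->vi", C).real, axis=1)
        u = np.zeros((V, 3), complex)
        u[np.arange(V), idx] = 1.0
    else:
        raise ValueError("orientation_rule must be dominant-svd or max-power-component")
    return u


def source_itc(
    analytic: AnalyticEpochs,
    op: InverseOperator,
    orientation_rule: str = "dominant-svd",
    orientation_window: tuple[float, float] | None = None,
    trial_chunk: int = 16,
) -> SourceTFTimecourse:
    """Inter-trial coherence of the source estimates, per voxel and sample.

    The 3-component complex estimate is collapsed to a scalar per voxel —
    by default the projection onto the dominant eigenvector of the voxel's
    trial-stacked cross-spectral matrix (fixed per voxel and band) — and the
    ITC is the modulus of the trial-averaged unit phasor of that scalar.
    Samples with zero amplitude are excluded with count adjustment; voxels
    with no valid samples anywhere are flagged as undefined (NaN).
    """
    n = analytic.n_trials
    if n == 0:
        raise ValueError("no trials")
    u = _orientations(analytic, op, orientation_rule, orientation_window, trial_chunk)
    V = op.n_voxels
    S = analytic.data.shape[1]
    phasor_sum = np.zeros((V, S), complex)
    counts = np.zeros((V, S))
    for start in range(0, n, trial_chunk):
        chunk = analytic.data[:, :, start : start + trial_chunk]
        J = apply_inverse(op, chunk).reshape(V, 3, S, -1)
        h = np.einsum("vi,vist->vst", np.conj(u), J)
        mag = np.abs(h)
        valid = mag > 0
        unit = np.where(valid, h / np.where(valid, mag, 1.0), 0.0)
        phasor_sum += unit.sum(axis=2)
        counts += valid.sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        itc = np.abs(phasor_sum) / counts
    undefined = counts == 0
    itc[undefined] = np.nan
    return SourceTFTimecourse(
        values=itc,
        srate=analytic.srate,
        t0_index=analytic.t0_index,
        measure="ITC",
        n_trials=n,
        band=analytic.band,
        undefined_mask=undefined.all(axis=1),
    )


def window_average(
    timecourse: SourceTFTimecourse, window_s: tuple[float, float]
) -> np.ndarray:
    """Per-voxel time mean over the half-open window ``[t_lo, t_hi)`` s."""
    t = timecourse.times
    mask = (t >= window_s[0]) & (t < window_s[1])
    if not mask.any():
        raise ValueError(f"window {window_s} s contains no samples")
    return timecourse.values[:, mask].mean(axis=1)
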