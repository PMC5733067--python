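"""Independent oracle implementations used only by the tests.

These deliberately use different algorithms from the package: Legendre
series instead of the closed-form sphere potential, literal per-trial /
per-voxel loops instead of the vectorized source ERSP/ITC, brute-force
enumeration instead of grid construction, dense matrix products instead of
block-wise standardization.
"""

from __future__ import annotations

import numpy as np
from scipy.special import eval_legendre


def monopole_potential_series(
    source_mm, electrode_mm, radius_mm, conductivity, n_terms=300
) -> float:
    """Surface potential of a unit current monopole in a homogeneous sphere,
    by direct Legendre-series summation (volts per ampere)."""
    R = radius_mm * 1e-3
    r0 = np.asarray(source_mm, float) * 1e-3
    r = np.asarray(electrode_mm, float) * 1e-3
    r = r * (R / np.linalg.norm(r))
    b = np.linalg.norm(r0)
    cosg = 1.0 if b == 0 else float(r0 @ r / (b * R))
    x = b / R
    total = sum(
        (2 * n + 1) / n * x**n * eval_legendre(n, cosg) for n in range(1, n_terms)
    )
    return total / (4 * np.pi * conductivity * R)


def dipole_potential_series(
    source_mm, moment_nAm, electrode_mm, radius_mm, conductivity, h_mm=1e-4
) -> float:
    """Dipole surface potential (µV per the given nA·m moment) as the
    central-difference limit of two monopole series."""
    m = np.asarray(moment_nAm, float)
    norm = np.linalg.norm(m)
    if norm == 0:
        return 0.0
    mh = m / norm
    vp = monopole_potential_series(
        np.asarray(source_mm) + 0.5 * h_mm * mh, electrode_mm, radius_mm, conductivity
    )
    vm = monopole_potential_series(
        np.asarray(source_mm) - 0.5 * h_mm * mh, electrode_mm, radius_mm, conductivity
    )
    # d/ds in 1/m, moment nA·m -> A·m, volts -> µV
    return (vp - vm) / (h_mm * 1e-3) * norm * 1e-9 * 1e6


def sphere_grid_count_bruteforce(radius_mm: float, spacing_mm: float) -> int:
    """Triple-loop count of origin-aligned grid nodes strictly inside."""
    k = int(np.floor(radius_mm / spacing_mm)) + 1
    count = 0
    for iz in range(-k, k + 1):
        for iy in range(-k, k + 1):
            for ix in range(-k, k + 1):
                p = np.array([ix, iy, iz]) * spacing_mm
                if np.linalg.norm(p) < radius_mm:
                    count += 1
    return count


def naive_source_ersp(analytic_data, transfer, s_blocks, times, baseline_window):
    """Literal transcription of trial-averaged standardized source power
    with additive baseline: explicit loops over trials, voxels, samples."""
    n_ch, n_samp, n_trials = analytic_data.shape
    V = s_blocks.shape[0]
    p = np.zeros((V, n_samp))
    for n in range(n_trials):
        x = analytic_data[:, :, n]
        x = x - x.mean(axis=0, keepdims=True)
        for t in range(n_samp):
            j = transfer @ x[:, t]
            for v in range(V):
                jv = j[3 * v : 3 * v + 3]
                pinv = np.linalg.pinv(s_blocks[v], rcond=1e-12, hermitian=True)
                p[v, t] += np.real(np.conj(jv) @ pinv @ jv)
    p /= n_trials
    bmask = (times >= baseline_window[0]) & (times < baseline_window[1])
    out = np.zeros_like(p)
    for v in range(V):
        out[v] = p[v] - p[v, bmask].mean()
    return out


def naive_source_itc(analytic_data, transfer, orientations):
    """Literal transcription of inter-trial coherence: per voxel, collapse
    the estimate onto the given orientation, average unit phasors over
    trials, take the modulus."""
    n_ch, n_samp, n_trials = analytic_data.shape
    V = orientations.shape[0]
    itc = np.zeros((V, n_samp))
    for v in range(V):
        u = orientations[v]
        for t in range(n_samp):
            acc = 0.0 + 0.0j
            count = 0
            for n in range(n_trials):
                x = analytic_data[:, t, n]
                x = x - x.mean()
                j = transfer[3 * v : 3 * v + 3] @ x
                h = np.conj(u) @ j
                if np.abs(h) > 0:
                    acc += h / np.abs(h)
                    count += 1
            itc[v, t] = np.abs(acc) / count if count else np.nan
    return itc


def write_minimal_edf(path, data_uv, srate, ch_names, phys_range=200.0):
    """Write a minimal 16-bit EDF file (synthetic fixture generator).

    Returns the quantization step in µV.  One-second data records; the tail
    is zero-padded, so callers should use whole-second signals.
    """
    data = np.asarray(data_uv, float)
    n_ch, n_samp = data.shape
    spr = int(round(srate))
    n_rec = int(np.ceil(n_samp / spr))
    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, :n_samp] = data
    dig_min, dig_max = -32768, 32767
    step = 2 * phys_range / (dig_max - dig_min)

    def f(x, width):
        s = str(x)[:width]
        return s.ljust(width).encode("ascii")

    header = b"".join(
        [
            f("0", 8),
            f("X", 80),
            f("X", 80),
            f("01.01.01", 8),
            f("00.00.00", 8),
            f(256 * (1 + n_ch), 8),
            f("", 44),
            f(n_rec, 8),
            f("1", 8),
            f(n_ch, 4),
        ]
    )
    header += b"".join(f(name, 16) for name in ch_names)
    header += b"".join(f("", 80) for _ in ch_names)
    header += b"".join(f("uV", 8) for _ in ch_names)
    header += b"".join(f(-phys_range, 8) for _ in ch_names)
    header += b"".join(f(phys_range, 8) for _ in ch_names)
    header += b"".join(f(dig_min, 8) for _ in ch_names)
    header += b"".join(f(dig_max, 8) for _ in ch_names)
    header += b"".join(f("", 80) for _ in ch_names)
    header += b"".join(f(spr, 8) for _ in ch_names)
    header += b"".join(f("", 32) for _ in ch_names)

    scaled = np.clip(
        np.round((padded + phys_range) / step + dig_min), dig_min, dig_max
    ).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        for rec in range(n_rec):
            for ch in range(n_ch):
                fh.write(scaled[ch, rec * spr : (rec + 1) * spr].tobytes())
    return step
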