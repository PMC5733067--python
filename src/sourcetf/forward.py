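"""Spherical-head forward model: source grids, dipole potentials, lead fields.

The head is modelled as a homogeneous conducting sphere with an insulating
exterior.  For a current dipole at ``r0`` inside a sphere of radius ``R`` and
conductivity ``sigma``, the surface potential has the classical closed form

    V(r) = (1 / 4·pi·sigma·R) · m · [ 2R·(r - r0)/d^3 + (r + R·(r - r0)/d) / F ]

with ``d = |r - r0|`` and ``F = R^2 - r0·r + R·d``, obtained by summing the
Legendre series of the Neumann Green's function.  Electrodes are projected
radially onto the sphere surface.  Realistic (BEM/FEM) gain matrices computed
elsewhere can be used through :func:`load_leadfield`.

Coordinates are millimetres in a right-handed frame centred on the sphere
centre; gains are µV per nA·m of dipole moment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import h5py
import numpy as np

__all__ = [
    "HeadSphere",
    "Montage",
    "SourceSpace",
    "LeadField",
    "make_cap_montage",
    "build_source_grid",
    "dipole_potential",
    "build_leadfield",
    "save_leadfield",
    "load_leadfield",
]


@dataclass(frozen=True)
class HeadSphere:
    """Homogeneous conducting sphere; radius in mm, conductivity in S/m."""

    radius_mm: float = 90.0
    conductivity: float = 0.33


@dataclass
class Montage:
    """Electrode names and 3-D positions (mm, head frame)."""

    channel_names: list[str]
    positions: np.ndarray  # (M, 3) mm

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (len(self.channel_names), 3):
            raise ValueError("positions must be (n_channels, 3)")
        if not np.isfinite(self.positions).all():
            raise ValueError("electrode positions must be finite")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)


@dataclass
class SourceSpace:
    """Regular voxel grid (V x 3 positions in mm) with its spacing."""

    positions: np.ndarray
    spacing: float
    mask_description: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (n_voxels, 3)")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")

    @property
    def n_voxels(self) -> int:
        return self.positions.shape[0]

    def nearest_voxel(self, point: np.ndarray) -> int:
        """Index of the grid voxel closest to ``point`` (mm)."""
        d = np.linalg.norm(self.positions - np.asarray(point, float), axis=1)
        return int(np.argmin(d))


@dataclass
class LeadField:
    """Gain matrix, channels x (3·V); column triplet v holds voxel v's x/y/z
    unit-moment topographies."""

    gain: np.ndarray
    montage: Montage
    source_space: SourceSpace

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float)
        expected = (self.montage.n_channels, 3 * self.source_space.n_voxels)
        if self.gain.shape != expected:
            raise ValueError(
                f"gain shape {self.gain.shape} does not match montage/source "
                f"space (expected {expected})"
            )
        if not np.isfinite(self.gain).all():
            bad = np.argwhere(~np.isfinite(self.gain))
            raise ValueError(f"non-finite gain entries at (row, col) {bad[:5].tolist()}")

    @property
    def n_channels(self) -> int:
        return self.gain.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.gain.shape[1] // 3

    def voxel_block(self, v: int) -> np.ndarray:
        """The (channels x 3) gain block of voxel ``v``."""
        return self.gain[:, 3 * v : 3 * v + 3]


def make_cap_montage(
    n_channels: int = 128,
    sphere: HeadSphere = HeadSphere(),
    max_polar_deg: float = 120.0,
    prefix: str = "E",
) -> Montage:
    """Deterministic synthetic electrode cap on the upper sphere.

    Channels are laid out on a Fibonacci lattice covering polar angles from
    the vertex down to ``max_polar_deg`` (a 120° cap reaches below the
    equator, like a high-density EEG net).  This stands in for a measured
    montage; measured positions can be supplied directly as a
    :class:`Montage`.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    i = np.arange(n_channels)
    # uniform-area spacing in cos(theta) over the cap
    cmin = np.cos(np.deg2rad(max_polar_deg))
    costheta = 1.0 - (1.0 - cmin) * (i + 0.5) / n_channels
    theta = np.arccos(costheta)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = i * golden
    R = sphere.radius_mm
    pos = np.stack(
        [
            R * np.sin(theta) * np.cos(phi),
            R * np.sin(theta) * np.sin(phi),
            R * np.cos(theta),
        ],
        axis=1,
    )
    names = [f"{prefix}{k + 1:03d}" for k in range(n_channels)]
    return Montage(names, pos)


def _mask_predicate(mask) -> tuple[Callable[[np.ndarray], np.ndarray], np.ndarray, str]:
    """Normalize a mask spec into (predicate, bounding box, description)."""
    if callable(mask):
        raise TypeError(
            "callable masks need explicit bounds; pass ('sphere', r), "
            "('box', lo, hi) or ('ellipsoid', semiaxes)"
        )
    kind = mask[0]
    if kind == "sphere":
        r = float(mask[1])
        bounds = np.array([[-r, r]] * 3)
        return (lambda p: np.linalg.norm(p, axis=1) < r), bounds, f"sphere r={r}mm"
    if kind == "box":
        lo = np.asarray(mask[1], float)
        hi = np.asarray(mask[2], float)
        bounds = np.stack([lo, hi], axis=1)
        return (
            lambda p: np.all((p >= lo) & (p <= hi), axis=1),
            bounds,
            f"box {lo.tolist()}..{hi.tolist()}mm",
        )
    if kind == "ellipsoid":
        ax = np.asarray(mask[1], float)
        bounds = np.stack([-ax, ax], axis=1)
        return (
            lambda p: np.sum((p / ax) ** 2, axis=1) < 1.0,
            bounds,
            f"ellipsoid {ax.tolist()}mm",
        )
    raise ValueError(f"unknown mask kind {kind!r}")


def build_source_grid(mask, spacing: float) -> SourceSpace:
    """Regular grid of voxels at ``spacing`` mm where the mask holds.

    Grid nodes are integer multiples of the spacing (origin-aligned);
    ordering is deterministic with x varying fastest.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    predicate, bounds, desc = _mask_predicate(mask)
    axes = []
    for lo, hi in bounds:
        k_lo = int(np.ceil(lo / spacing - 1e-9))
        k_hi = int(np.floor(hi / spacing + 1e-9))
        axes.append(np.arange(k_lo, k_hi + 1) * spacing)
    zz, yy, xx = np.meshgrid(axes[2], axes[1], axes[0], indexing="ij")
    pts = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)
    keep = predicate(pts)
    if not keep.any():
        raise ValueError("mask selects no grid voxels at this spacing")
    return SourceSpace(pts[keep], spacing, desc)


def _dipole_coeff(
    dipole_pos: np.ndarray, electrode_pos: np.ndarray, sphere: HeadSphere
) -> np.ndarray:
    """Vector c (µV per nA·m) such that V = c · m.

    Broadcasts over leading axes of both position arrays.
    """
    R = sphere.radius_mm * 1e-3
    r0 = np.asarray(dipole_pos, float) * 1e-3
    r = np.asarray(electrode_pos, float) * 1e-3
    # project electrodes radially onto the surface
    rn = np.linalg.norm(r, axis=-1, keepdims=True)
    if np.any(rn == 0):
        raise ValueError("electrode at sphere centre cannot be projected")
    r = r * (R / rn)
    b = np.linalg.norm(r0, axis=-1)
    if np.any(b >= R):
        raise ValueError("dipole on or outside the sphere surface")
    dvec = r - r0
    d = np.linalg.norm(dvec, axis=-1, keepdims=True)
    F = (R**2 - np.sum(r0 * r, axis=-1, keepdims=True)) + R * d
    coeff = 2.0 * R * dvec / d**3 + (r + R * dvec / d) / F
    coeff /= 4.0 * np.pi * sphere.conductivity * R
    # volts per A·m -> µV per nA·m: 1e6 * 1e-9
    return coeff * 1e-3


def dipole_potential(
    dipole_pos,
    moment,
    electrode_pos,
    sphere: HeadSphere = HeadSphere(),
) -> float | np.ndarray:
    """Surface potential (µV) of a dipole inside the homogeneous sphere.

    Parameters
    ----------
    dipole_pos
        Dipole location, mm, strictly inside the sphere.
    moment
        Dipole moment vector, nA·m.
    electrode_pos
        Electrode location(s), mm; projected radially to the surface.
    sphere
        Head model geometry and conductivity.

    The potential is linear in ``moment`` and referenced to the
    infinite-homogeneous-medium zero; any montage referencing (e.g. average
    reference) is applied downstream.
    """
    coeff = _dipole_coeff(dipole_pos, electrode_pos, sphere)
    out = coeff @ np.asarray(moment, float)
    return out


def build_leadfield(
    montage: Montage, source_space: SourceSpace, sphere: HeadSphere = HeadSphere()
) -> LeadField:
    """Assemble the channels x (3·V) gain matrix for unit dipole moments."""
    r = np.linalg.norm(source_space.positions, axis=1)
    if np.any(r >= sphere.radius_mm):
        raise ValueError("source space contains voxels on/outside the sphere")
    # (M, V, 3) coefficients -> (M, 3V)
    coeff = _dipole_coeff(
        source_space.positions[None, :, :],
        montage.positions[:, None, :],
        sphere,
    )
    gain = coeff.reshape(montage.n_channels, 3 * source_space.n_voxels)
    return LeadField(gain, montage, source_space)


def save_leadfield(leadfield: LeadField, path: str | Path) -> None:
    with h5py.File(Path(path), "w") as f:
        f.create_dataset("gain", data=leadfield.gain)
        f.attrs["n_channels"] = leadfield.n_channels
        f.attrs["n_voxels"] = leadfield.n_voxels


def load_leadfield(
    path: str | Path, montage: Montage, source_space: SourceSpace
) -> LeadField:
    """Load an externally computed gain matrix and validate it.

    Rejects dimension mismatches (including transposed matrices) and
    non-finite entries, reporting the first offending locations.
    """
    with h5py.File(Path(path), "r") as f:
        gain = f["gain"][()]
    expected = (montage.n_channels, 3 * source_space.n_voxels)
    if gain.shape != expected:
        raise ValueError(
            f"lead field shape {gain.shape} does not match expected {expected}"
        )
    return LeadField(gain, montage, source_space)
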