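"""Double golden-angle 3D radial trajectory generation.

A free-running 3D radial acquisition samples one full-diameter spoke through
the k-space center per repetition time.  The spoke orientation advances by two
irrational (golden-mean) increments so that any contiguous subset of spokes
covers the sphere near-uniformly: the polar angle is ``beta = arccos(frac(m *
phi1))`` and the azimuth ``alpha = 2*pi*frac(m * phi2)`` for spoke number
``m``, where ``frac`` is the modulo-one operation.

Two golden-mean pairs are supported.  The conventional pair ``(0.4656,
0.6823)`` yields a mean angle of ~92 degrees between consecutively acquired
spokes; the small-increment pair ``(0.0102, 0.0219)`` reduces this to ~7
degrees, which suppresses eddy-current image artifacts caused by large
spoke-to-spoke gradient jumps.  In both pairs the *smaller* golden mean drives
the polar angle -- a convention validated here by reproducing the published
consecutive-angle statistics of both trajectories (see
:func:`consecutive_angle_stats`).

A superior-inferior (SI) navigator spoke, fixed along +z, may be interleaved
as every ``si_every``-th acquired spoke to track diaphragm motion.  The golden
index ``m`` advances only over imaging spokes, so the imaging trajectory is
identical with and without the navigator.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Conventional double golden-angle means (polar, azimuthal).
GOLDEN_MEANS_CONVENTIONAL = (0.4656, 0.6823)
#: Small golden-angle means (polar, azimuthal) minimizing consecutive-spoke angles.
GOLDEN_MEANS_MODIFIED = (0.0102, 0.0219)


@dataclass(frozen=True)
class TrajectoryConfig:
    """Acquisition-design parameters for a double golden-angle scan.

    Parameters
    ----------
    phi1, phi2
        Golden means driving the polar and azimuthal angles respectively
        (dimensionless, in (0, 1)).  Defaults are the small-increment pair.
    n_spokes_total
        Total number of acquired spokes, navigators included.
    si_every
        Every ``si_every``-th acquired spoke is a superior-inferior navigator
        (0 disables the navigator; otherwise must be >= 2).
    tr
        Repetition time in seconds; one spoke is acquired per TR.
    matrix
        Isotropic reconstruction grid size in voxels.
    n_readout
        Samples per spoke along the full k-space diameter.  Defaults to
        ``matrix``, which critically samples the diameter.
    voxel_mm
        Isotropic voxel size in mm (sets the k-space unit scale).
    """

    phi1: float = GOLDEN_MEANS_MODIFIED[0]
    phi2: float = GOLDEN_MEANS_MODIFIED[1]
    n_spokes_total: int = 250_000
    si_every: int = 25
    tr: float = 0.0025
    matrix: int = 176
    n_readout: int | None = None
    voxel_mm: float = 2.0

    def __post_init__(self) -> None:
        if not (0.0 < self.phi1 < 1.0 and 0.0 < self.phi2 < 1.0):
            raise ValueError("golden means must lie strictly in (0, 1)")
        if self.si_every != 0 and self.si_every < 2:
            raise ValueError("si_every must be 0 (no navigator) or >= 2")
        if self.n_spokes_total < 1:
            raise ValueError("n_spokes_total must be >= 1")
        if self.tr <= 0 or self.matrix < 1 or self.voxel_mm <= 0:
            raise ValueError("tr, matrix and voxel_mm must be positive")
        if self.n_readout is None:
            object.__setattr__(self, "n_readout", int(self.matrix))
        if self.n_readout < 2:
            raise ValueError("n_readout must be >= 2")

    @property
    def fov_mm(self) -> float:
        """Reconstructed field of view in mm."""
        return self.matrix * self.voxel_mm

    def asdict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SpokeTable:
    """Per-spoke geometry and timing of one acquisition.

    ``directions`` are unit vectors; SI navigator spokes point exactly along
    ``(0, 0, 1)``.  ``timestamps`` are ``index * tr`` and strictly increasing.
    """

    index: np.ndarray            # (N,) int, acquisition order
    azimuth: np.ndarray          # (N,) rad
    polar: np.ndarray            # (N,) rad
    directions: np.ndarray       # (N, 3) unit vectors
    timestamps: np.ndarray       # (N,) s
    is_si: np.ndarray            # (N,) bool
    config: TrajectoryConfig | None = field(default=None, repr=False)

    @property
    def n_spokes(self) -> int:
        return len(self.index)

    @property
    def n_si(self) -> int:
        return int(self.is_si.sum())

    @property
    def imaging(self) -> np.ndarray:
        """Boolean mask selecting imaging (non-navigator) spokes."""
        return ~self.is_si


def _frac(m: np.ndarray, phi: float) -> np.ndarray:
    """frac(m * phi) without large-m rounding loss.

    A golden mean quoted as a short decimal (0.4656, 0.0219, ...) is treated
    as that exact rational, so e.g. frac(1e6 * 0.0219) is exactly 0 rather
    than 1 - 7e-13 as naive float64 multiplication would give.  Golden means
    without a short decimal form fall back to 80-bit extended precision,
    which keeps the error below ~1e-13 for m up to a few 1e6.
    """
    from fractions import Fraction

    m_arr = np.asarray(m, dtype=np.int64)
    rat = Fraction(str(phi))
    p, q = rat.numerator, rat.denominator
    if q <= 10**9 and (m_arr.max(initial=0) + 1) * p < 2**62:
        return ((m_arr * p) % q) / q
    m_ld = m_arr.astype(np.longdouble)
    return np.mod(m_ld * np.longdouble(phi), np.longdouble(1.0)).astype(np.float64)


def golden_direction(
    m: int | np.ndarray, phi1: float, phi2: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Spoke angles and unit direction for golden index ``m``.

    Returns ``(alpha, beta, direction)`` with ``alpha = 2 pi frac(m phi2)``
    (azimuth), ``beta = arccos(frac(m phi1))`` (polar) and ``direction =
    (sin b cos a, sin b sin a, cos b)``.  Accepts scalars or arrays of ``m``.
    """
    scalar = np.isscalar(m)
    m_arr = np.atleast_1d(np.asarray(m))
    if np.any(m_arr < 0):
        raise ValueError("spoke number m must be >= 0")
    cos_beta = _frac(m_arr, phi1)
    beta = np.arccos(cos_beta)
    alpha = 2.0 * np.pi * _frac(m_arr, phi2)
    sin_beta = np.sin(beta)
    direction = np.stack(
        [sin_beta * np.cos(alpha), sin_beta * np.sin(alpha), cos_beta], axis=-1
    )
    if scalar:
        return float(alpha[0]), float(beta[0]), direction[0]
    return alpha, beta, direction


def build_spoke_table(config: TrajectoryConfig) -> SpokeTable:
    """Build the acquisition-ordered spoke table for ``config``.

    With ``si_every = s`` the acquired positions ``s-1, 2s-1, ...`` (0-based)
    carry the SI navigator along ``(0, 0, 1)``; the golden index advances only
    over imaging spokes.
    """
    n = config.n_spokes_total
    idx = np.arange(n)
    if config.si_every:
        is_si = (idx % config.si_every) == (config.si_every - 1)
    else:
        is_si = np.zeros(n, dtype=bool)
    n_img = int((~is_si).sum())

    azimuth = np.zeros(n)
    polar = np.zeros(n)
    directions = np.zeros((n, 3))
    directions[is_si] = (0.0, 0.0, 1.0)
    if n_img:
        a, b, d = golden_direction(np.arange(n_img), config.phi1, config.phi2)
        azimuth[~is_si] = a
        polar[~is_si] = b
        directions[~is_si] = d

    return SpokeTable(
        index=idx,
        azimuth=azimuth,
        polar=polar,
        directions=directions,
        timestamps=idx * config.tr,
        is_si=is_si,
        config=config,
    )


def consecutive_angle_stats(
    table: SpokeTable, include_si: bool = True
) -> tuple[float, float]:
    """Mean and population SD (degrees) of consecutively acquired spoke angles.

    The angle between directed rays ``arccos(u_i . u_{i+1})`` is used, so
    values may exceed 90 degrees; this convention (rather than undirected
    lines, which cap at 90) reproduces the published ~92 degree mean of the
    conventional trajectory.  With ``include_si=False`` navigator spokes are
    dropped before pairing; with ``include_si=True`` the interleaved
    acquisition order is kept, navigator transitions included.
    """
    d = table.directions if include_si else table.directions[table.imaging]
    if len(d) < 2:
        raise ValueError("need at least 2 spokes to form consecutive pairs")
    cosang = np.clip(np.einsum("ij,ij->i", d[:-1], d[1:]), -1.0, 1.0)
    ang = np.degrees(np.arccos(cosang))
    return float(ang.mean()), float(ang.std())


def nyquist_spoke_count(matrix: int) -> int:
    """Fully sampled spoke count ``round(pi/2 * matrix**2)``.

    Full-diameter 3D radial Nyquist criterion: the sphere surface at maximum
    radius is critically sampled when the number of (diameter) spokes reaches
    ``pi/2 N^2`` for an isotropic matrix of size ``N``.
    """
    if matrix < 1:
        raise ValueError("matrix must be >= 1")
    return int(round(np.pi / 2.0 * matrix**2))


def acceleration_factor(n_full: int, n_bin: int) -> float:
    """Undersampling factor ``n_full / n_bin``, reported to one decimal."""
    if n_bin <= 0:
        raise ZeroDivisionError("n_bin must be positive")
    return round(n_full / n_bin, 1)


def readout_radii(n_readout: int) -> np.ndarray:
    """Normalized sample radii along a spoke (cycles/voxel).

    ``n_readout`` points evenly spaced with step ``1/n_readout`` such that the
    sample at index ``n_readout // 2`` lies exactly at k = 0; for even counts
    the radii span ``[-0.5, 0.5)``.
    """
    if n_readout < 2:
        raise ValueError("n_readout must be >= 2")
    return (np.arange(n_readout) - n_readout // 2) / n_readout


def sample_locations(
    direction: np.ndarray, n_readout: int, matrix: int | None = None
) -> np.ndarray:
    """k-space sample coordinates along a spoke, in cycles/voxel.

    The spoke spans the full diameter from -k_max to +k_max (k_max = 0.5
    cycles/voxel), with exactly one sample at k = 0.  ``matrix`` is accepted
    for interface symmetry; the normalized convention does not depend on it.
    """
    direction = np.asarray(direction, dtype=float)
    return readout_radii(n_readout)[:, None] * direction[None, :]
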