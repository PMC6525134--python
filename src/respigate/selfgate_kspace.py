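"""k-space-center respiratory self-gating (phase-only reference method).

Every imaging spoke passes through k = 0, and the complex center sample per
coil varies with global signal changes over the respiratory cycle.  A 1D
series is formed as the real part of the conjugate inner product between a
reference center-sample vector (one spoke, all coils) and every other spoke's
vector, then band-pass filtered to respiratory frequencies.

The resulting signal carries respiratory *phase* information only: its
amplitude reflects global signal modulation, not motion amplitude, so
``amplitude_valid = False`` and downstream anchoring must place
mid-inspiration/mid-expiration at fixed cycle fractions (28% / 88%).  The
pass band is deliberately fixed per run; a respiratory rate drifting relative
to the band center degrades the cycle division -- the known fragility of this
method in patients.
"""

from __future__ import annotations

import logging

import numpy as np
from dataclasses import dataclass
from scipy import signal as sps

from .phantom_sim import AcquisitionData
from .selfgate_projection import RespiratorySignal

logger = logging.getLogger(__name__)

DEFAULT_BAND_HZ = (0.1, 0.5)
GATE_FS_HZ = 16.0  # uniform resampling rate of the gating series


@dataclass
class CenterSampleMatrix:
    """k = 0 sample of every imaging spoke for all coils."""

    values: np.ndarray  # (n_imaging, n_coils) complex
    t: np.ndarray       # (n_imaging,) s


def center_sample_matrix(acq: AcquisitionData) -> CenterSampleMatrix:
    """Extract the exact k = 0 readout sample per imaging spoke and coil."""
    imaging = acq.spoke_table.imaging
    if not imaging.any():
        raise ValueError("acquisition contains no imaging spokes")
    values = acq.samples[imaging][:, :, acq.center_index]
    return CenterSampleMatrix(values=np.asarray(values, dtype=complex),
                              t=acq.spoke_table.timestamps[imaging])


def reference_combine(
    matrix: CenterSampleMatrix, ref_spoke: int = 0, use_magnitude: bool = False
) -> np.ndarray:
    """Coil combination against one reference spoke.

    ``s(t) = Re <v_ref, v(t)>`` with the conjugate-linear inner product over
    coils (``use_magnitude=True`` takes ``|<v_ref, v(t)>|`` instead).  At the
    reference spoke the value is the squared norm of the reference vector.
    """
    n = len(matrix.values)
    if not (0 <= ref_spoke < n):
        raise IndexError(f"ref_spoke {ref_spoke} outside [0, {n})")
    inner = matrix.values @ np.conj(matrix.values[ref_spoke])
    return np.abs(inner) if use_magnitude else np.real(inner)


def bandpass_respiratory(
    series: np.ndarray,
    fs: float,
    f_lo: float = DEFAULT_BAND_HZ[0],
    f_hi: float = DEFAULT_BAND_HZ[1],
) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass on a uniform series."""
    y = np.asarray(series, dtype=float)
    if len(y) / fs <= 2.0 / f_lo:
        raise ValueError(
            f"series duration {len(y) / fs:.1f}s too short for f_lo={f_lo} Hz"
        )
    sos = sps.butter(4, [f_lo, f_hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, y - y.mean())


def extract_kspace_selfgating(
    acq: AcquisitionData,
    band: tuple[float, float] = DEFAULT_BAND_HZ,
    ref_spoke: int = 0,
    use_magnitude: bool = False,
    fs: float = GATE_FS_HZ,
) -> RespiratorySignal:
    """k-space-center gating signal on a uniform time base.

    The spoke-rate series (non-uniform where navigators interrupt the imaging
    stream) is linearly resampled to ``fs`` before filtering.
    """
    matrix = center_sample_matrix(acq)
    raw = reference_combine(matrix, ref_spoke=ref_spoke, use_magnitude=use_magnitude)
    t_u = np.arange(matrix.t[0], matrix.t[-1], 1.0 / fs)
    resampled = np.interp(t_u, matrix.t, raw)
    filtered = bandpass_respiratory(resampled, fs=fs, f_lo=band[0], f_hi=band[1])
    return RespiratorySignal(t=t_u, value=filtered, amplitude_valid=False,
                             method="kspace")
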