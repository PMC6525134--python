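"""Respiratory cycle division, anchoring and cardiac x respiratory binning.

Respiratory cycles are delimited at the 2*pi wrapping points of the
instantaneous phase of the gating signal's analytic (Hilbert) extension;
the wraps correspond to end-expiration.  Within each cycle a mid-inspiration
and a mid-expiration anchor are placed by one of two strategies:

* **amplitude anchoring** (projection gating): mid-inspiration is the first
  time on the rising limb where the signal crosses halfway between the
  cycle-start minimum and the cycle maximum; mid-expiration the first falling
  crossing of halfway between the maximum and the cycle-end minimum.  Window
  widths adapt per cycle.
* **phase anchoring** (k-space gating, which has no amplitude information):
  anchors at fixed cycle fractions, 28% (mid-inspiration) and 88%
  (mid-expiration) of the cycle relative to end-expiration.

Each spoke is then labelled with a respiratory bin (a window of 15% of that
cycle's duration centered on each anchor) and a cardiac bin (end-diastole:
70%-82.5% of the enclosing RR interval); only spokes carrying both labels are
reconstructed, and navigator spokes are always excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import hilbert

from .phantom_sim import AcquisitionData
from .selfgate_projection import RespiratorySignal

logger = logging.getLogger(__name__)

RESP_LABELS = {0: "none", 1: "mid-inspiration", 2: "mid-expiration"}
MIN_CYCLE_S = 1.0
MAX_CYCLE_S = 15.0


@dataclass
class CycleSet:
    """Respiratory cycle boundaries with optional anchors (all times in s)."""

    start: np.ndarray
    end: np.ndarray
    anchor_mi: np.ndarray | None = None
    anchor_me: np.ndarray | None = None
    t_min_start: np.ndarray | None = None
    t_max: np.ndarray | None = None
    t_min_end: np.ndarray | None = None
    method: str = ""

    def __post_init__(self) -> None:
        if np.any(self.end <= self.start):
            raise ValueError("cycle end must exceed start")
        if np.any(self.start[1:] < self.end[:-1] - 1e-9):
            raise ValueError("cycles must be ordered and non-overlapping")

    @property
    def n_cycles(self) -> int:
        return len(self.start)

    @property
    def durations(self) -> np.ndarray:
        return self.end - self.start


@dataclass
class BinAssignment:
    """Per-spoke respiratory and cardiac labels.

    ``resp_label``: 0 none / 1 mid-inspiration / 2 mid-expiration;
    ``cardiac_label``: True for end-diastole.  ``in_bin`` marks spokes with
    both labels (the only ones reconstructed).
    """

    resp_label: np.ndarray
    cardiac_label: np.ndarray
    is_si: np.ndarray
    counts: dict = field(default_factory=dict)

    @property
    def in_bin(self) -> np.ndarray:
        return (self.resp_label > 0) & self.cardiac_label & ~self.is_si

    def spokes(self, resp: int) -> np.ndarray:
        """Indices of reconstructable spokes in respiratory bin 1 (mi) or 2 (me)."""
        return np.where(self.in_bin & (self.resp_label == resp))[0]


def analytic_signal(signal: RespiratorySignal) -> np.ndarray:
    """Complex analytic extension (signal + i * Hilbert transform)."""
    v = np.asarray(signal.value, dtype=float)
    if len(v) < 8:
        raise ValueError("need at least 8 samples for the analytic signal")
    v = v - v.mean()
    if np.ptp(v) <= 1e-12 * max(1.0, np.abs(v).max()):
        raise ValueError("constant signal has undefined instantaneous phase")
    return hilbert(v)


def cycle_divisions(
    signal: RespiratorySignal,
    analytic: np.ndarray | None = None,
    min_cycle_s: float = MIN_CYCLE_S,
    max_cycle_s: float = MAX_CYCLE_S,
) -> CycleSet:
    """Cycle boundaries at the 2*pi wrapping points of the instantaneous phase.

    Boundaries correspond to end-expiration.  Cycles shorter than
    ``min_cycle_s`` or longer than ``max_cycle_s`` are discarded as gating
    failures (logged).
    """
    if analytic is None:
        analytic = analytic_signal(signal)
    phase = np.angle(analytic)
    t = signal.t
    d = np.diff(phase)
    wrap = np.where(d < -np.pi)[0]
    if len(wrap) == 0:
        logger.warning("no phase wraps found; treating record as a single cycle")
        return CycleSet(start=np.array([t[0]]), end=np.array([t[-1]]))
    # linear interpolation of the +pi crossing time within the wrapping step
    frac = (np.pi - phase[wrap]) / (phase[wrap + 1] + 2.0 * np.pi - phase[wrap])
    bounds = t[wrap] + frac * (t[wrap + 1] - t[wrap])
    starts, ends = bounds[:-1], bounds[1:]
    dur = ends - starts
    keep = (dur >= min_cycle_s) & (dur <= max_cycle_s)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("discarded %d cycles outside [%.1f, %.1f] s",
                       n_dropped, min_cycle_s, max_cycle_s)
    return CycleSet(start=starts[keep], end=ends[keep])


def _first_crossing(
    t: np.ndarray, v: np.ndarray, level: float, rising: bool
) -> float | None:
    """Time of the first linear-interpolated crossing of ``level``."""
    if rising:
        hit = np.where((v[:-1] < level) & (v[1:] >= level))[0]
    else:
        hit = np.where((v[:-1] > level) & (v[1:] <= level))[0]
    if len(hit) == 0:
        return None
    i = hit[0]
    frac = (level - v[i]) / (v[i + 1] - v[i])
    return float(t[i] + frac * (t[i + 1] - t[i]))


def amplitude_anchors(
    signal: RespiratorySignal, cycles: CycleSet, edge_frac: float = 0.25
) -> CycleSet:
    """Per-cycle half-amplitude anchors from an amplitude-bearing signal.

    For each cycle: the minimum over the first ``edge_frac`` of the cycle, the
    cycle maximum, and the minimum over the last ``edge_frac``; mid-inspiration
    is the first rising crossing of (start-min + max)/2 and mid-expiration the
    first falling crossing of (max + end-min)/2, both linearly interpolated.
    Cycles without a crossing (flat) are skipped with a log entry.
    """
    if not signal.amplitude_valid:
        raise ValueError(
            "amplitude anchoring requires an amplitude-valid gating signal; "
            "use phase_anchors for phase-only methods"
        )
    t, v = signal.t, signal.value
    keep, mi_l, me_l, tms_l, tmax_l, tme_l = [], [], [], [], [], []
    for i in range(cycles.n_cycles):
        s, e = cycles.start[i], cycles.end[i]
        dur = e - s
        m = (t >= s) & (t < e)
        if m.sum() < 4:
            logger.warning("cycle %d has too few samples; skipped", i)
            continue
        tc, vc = t[m], v[m]
        early = tc < s + edge_frac * dur
        late = tc >= e - edge_frac * dur
        if not early.any() or not late.any():
            logger.warning("cycle %d lacks edge samples; skipped", i)
            continue
        i_min_start = np.argmin(vc[early])
        i_max = int(np.argmax(vc))
        v_min_start = vc[early][i_min_start]
        v_max = vc[i_max]
        v_min_end = vc[late].min()
        t_min_start = tc[early][i_min_start]
        t_max = tc[i_max]
        t_min_end = tc[late][np.argmin(vc[late])]

        rise = (tc >= t_min_start) & (tc <= t_max)
        fall = tc >= t_max
        a_mi = _first_crossing(tc[rise], vc[rise], 0.5 * (v_min_start + v_max), True)
        a_me = _first_crossing(tc[fall], vc[fall], 0.5 * (v_max + v_min_end), False)
        if a_mi is None or a_me is None:
            logger.warning("cycle %d has no half-amplitude crossing; skipped", i)
            continue
        keep.append(i)
        mi_l.append(a_mi)
        me_l.append(a_me)
        tms_l.append(t_min_start)
        tmax_l.append(t_max)
        tme_l.append(t_min_end)
    return CycleSet(
        start=cycles.start[keep],
        end=cycles.end[keep],
        anchor_mi=np.asarray(mi_l),
        anchor_me=np.asarray(me_l),
        t_min_start=np.asarray(tms_l),
        t_max=np.asarray(tmax_l),
        t_min_end=np.asarray(tme_l),
        method="amplitude",
    )


def phase_anchors(
    cycles: CycleSet, mi_frac: float = 0.28, me_frac: float = 0.88
) -> CycleSet:
    """Fixed-fraction anchors: 28% / 88% of each cycle from end-expiration."""
    dur = cycles.durations
    return replace(
        cycles,
        anchor_mi=cycles.start + mi_frac * dur,
        anchor_me=cycles.start + me_frac * dur,
        method="phase",
    )


def respiratory_membership(
    spoke_times: np.ndarray, cycles: CycleSet, width_frac: float = 0.15
) -> np.ndarray:
    """Respiratory bin labels for each spoke time.

    A spoke belongs to a bin iff ``|t - anchor| <= width_frac/2 * duration``
    of that cycle (closed interval).  Should the two windows overlap, the
    spoke goes to the nearer anchor.
    """
    if cycles.anchor_mi is None or cycles.anchor_me is None:
        raise ValueError("cycles carry no anchors; run an anchoring step first")
    t = np.asarray(spoke_times)
    labels = np.zeros(len(t), dtype=np.int8)
    # closed interval; the epsilon keeps exact boundary spokes in despite
    # float rounding of the half-width product
    half = 0.5 * width_frac * cycles.durations + 1e-9 * cycles.durations
    ci = np.searchsorted(cycles.start, t, side="right") - 1
    inside = (ci >= 0) & (t <= cycles.end[np.clip(ci, 0, None)])
    ci_in = ci[inside]
    d_mi = np.abs(t[inside] - cycles.anchor_mi[ci_in])
    d_me = np.abs(t[inside] - cycles.anchor_me[ci_in])
    in_mi = d_mi <= half[ci_in]
    in_me = d_me <= half[ci_in]
    lab = np.zeros(inside.sum(), dtype=np.int8)
    lab[in_mi] = 1
    lab[in_me] = 2
    both = in_mi & in_me
    lab[both] = np.where(d_mi[both] <= d_me[both], 1, 2)
    labels[inside] = lab
    return labels


def cardiac_membership(
    spoke_times: np.ndarray,
    rpeaks: np.ndarray,
    start_frac: float = 0.70,
    width_frac: float = 0.125,
) -> np.ndarray:
    """End-diastole labels: RR fraction in [start_frac, start_frac + width_frac).

    Spokes before the first or after the last R-peak are excluded.
    """
    rpeaks = np.asarray(rpeaks)
    if len(rpeaks) < 2:
        raise ValueError("need at least 2 R-peaks")
    t = np.asarray(spoke_times)
    i = np.searchsorted(rpeaks, t, side="right") - 1
    ok = (i >= 0) & (i < len(rpeaks) - 1)
    frac = np.zeros(len(t))
    ic = np.clip(i, 0, len(rpeaks) - 2)
    frac = (t - rpeaks[ic]) / (rpeaks[ic + 1] - rpeaks[ic])
    return ok & (frac >= start_frac) & (frac < start_frac + width_frac)


def assign_bins(
    acq: AcquisitionData,
    gating: RespiratorySignal,
    resp_width_frac: float = 0.15,
    cardiac_start_frac: float = 0.70,
    cardiac_width_frac: float = 0.125,
    mi_frac: float = 0.28,
    me_frac: float = 0.88,
    cycles: CycleSet | None = None,
) -> BinAssignment:
    """Label every spoke with a cardiac x respiratory bin.

    The anchoring strategy follows the gating signal: amplitude anchors when
    ``gating.amplitude_valid``, fixed-fraction phase anchors otherwise.
    Precomputed (e.g. ground-truth) ``cycles`` with anchors may be supplied to
    bypass extraction.  Navigator spokes never enter reconstruction bins.
    """
    if cycles is None:
        cycles = cycle_divisions(gating)
        if gating.amplitude_valid:
            cycles = amplitude_anchors(gating, cycles)
        else:
            cycles = phase_anchors(cycles, mi_frac=mi_frac, me_frac=me_frac)
    t = acq.spoke_table.timestamps
    resp = respiratory_membership(t, cycles, width_frac=resp_width_frac)
    cardiac = cardiac_membership(
        t, acq.ecg_rpeaks, start_frac=cardiac_start_frac, width_frac=cardiac_width_frac
    )
    assignment = BinAssignment(
        resp_label=resp, cardiac_label=cardiac, is_si=acq.spoke_table.is_si
    )
    counts = {
        "mid_inspiration": int(len(assignment.spokes(1))),
        "mid_expiration": int(len(assignment.spokes(2))),
        "total_spokes": int(len(t)),
        "n_cycles": int(cycles.n_cycles),
    }
    assignment.counts = counts
    for name in ("mid_inspiration", "mid_expiration"):
        if counts[name] == 0:
            logger.warning("empty reconstruction bin: %s", name)
    return assignment
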