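"""Projection-based respiratory self-gating from superior-inferior navigators.

The SI navigator spoke, repeated every ``si_every`` TRs, is Fourier-transformed
into a 1D head-foot projection whose dominant temporal mode tracks diaphragm
displacement.  The gating signal is extracted in five steps:

1. centered 1D inverse Fourier transform of every navigator readout
   (magnitude retained, per coil);
2. coil-wise principal component analysis of the (time x position) projection
   matrices, keeping the two dominant score series per coil;
3. locally weighted scatterplot smoothing (LOWESS) of each score series with a
   six-point span;
4. spectral clustering of all component series by absolute-correlation
   affinity into a signal and a nuisance cluster; the signal cluster (higher
   internal coherence and respiratory-band power) is sign-aligned and
   averaged;
5. polynomial detrending (order 2-4, selected by BIC unless fixed).

Unlike k-space-center gating, the resulting signal is proportional to the
*amplitude* of the respiratory motion, so per-cycle amplitude anchoring is
meaningful (``amplitude_valid = True``).  The sign convention is fixed so
that inspiration (diaphragm moving footward) is positive, resolved against
the projection centroid track.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import SpectralClustering
from sklearn.decomposition import PCA
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .phantom_sim import AcquisitionData

logger = logging.getLogger(__name__)

RESP_BAND_HZ = (0.1, 0.5)


@dataclass
class ProjectionMatrix:
    """SI-navigator projections: magnitude indexed (time, z position, coil)."""

    values: np.ndarray   # (n_t, n_z, n_coils)
    t: np.ndarray        # (n_t,) s
    z_axis: np.ndarray   # (n_z,) mm

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.t)))


@dataclass
class RespiratorySignal:
    """1D respiratory gating series.

    ``amplitude_valid`` marks whether the values are proportional to motion
    amplitude (projection method) or carry phase information only (k-space
    method); downstream anchoring dispatches on this flag.
    """

    t: np.ndarray
    value: np.ndarray
    amplitude_valid: bool
    method: str = ""

    def __post_init__(self) -> None:
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time base must be strictly increasing")
        if not np.all(np.isfinite(self.value)):
            raise ValueError("gating signal contains non-finite values")


def si_projections(acq: AcquisitionData) -> ProjectionMatrix:
    """Centered 1D inverse FT of every SI navigator readout, per coil.

    Readout samples lie at k = (i - n//2)/n cycles/voxel, so the projection
    pixel size equals the voxel size and the z axis is centered on the FOV.
    """
    si = acq.spoke_table.is_si
    if not si.any():
        raise ValueError("acquisition contains no SI navigator spokes")
    data = acq.samples[si]                       # (n_t, n_coils, n_read)
    spec = np.fft.ifftshift(data, axes=-1)
    proj = np.fft.fftshift(np.fft.ifft(spec, axis=-1), axes=-1)
    values = np.moveaxis(np.abs(proj), 1, 2)     # (n_t, n_z, n_coils)
    nz = values.shape[1]
    z_axis = (np.arange(nz) - nz // 2) * acq.voxel_mm
    return ProjectionMatrix(values=values, t=acq.spoke_table.timestamps[si], z_axis=z_axis)


def coilwise_pca(proj: ProjectionMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two dominant principal-component score series per coil.

    Each coil's (time x position) matrix is mean-removed per position and
    decomposed; scores are ordered by explained variance.  Returns
    ``(scores, explained, valid)`` with ``scores`` of shape (n_coils, 2, n_t);
    degenerate (constant) coils yield zero series and ``valid=False``.
    """
    n_t, _, n_coils = proj.values.shape
    if n_t < 2:
        raise ValueError("need at least 2 navigator frames for PCA")
    scores = np.zeros((n_coils, 2, n_t))
    explained = np.zeros((n_coils, 2))
    valid = np.zeros(n_coils, dtype=bool)
    for c in range(n_coils):
        x = proj.values[:, :, c]
        xc = x - x.mean(axis=0, keepdims=True)
        total_var = float((xc**2).sum())
        if total_var <= 1e-12 * max(1.0, float((x**2).sum())):
            logger.warning("coil %d has constant projections; PCA skipped", c)
            continue
        pca = PCA(n_components=2)
        s = pca.fit_transform(x)
        scores[c, : s.shape[1]] = s.T
        explained[c, : s.shape[1]] = pca.explained_variance_ratio_
        valid[c] = True
    if not valid.any():
        raise ValueError("all coils degenerate; no components extracted")
    return scores, explained, valid


def lowess_smooth(series: np.ndarray, span: int = 6) -> np.ndarray:
    """LOWESS (locally weighted linear regression) with a ``span``-point window."""
    y = np.asarray(series, dtype=float)
    n = len(y)
    if n <= span:
        raise ValueError(f"series length {n} must exceed span {span}")
    x = np.arange(n, dtype=float)
    return _sm_lowess(y, x, frac=span / n, it=0, return_sorted=False)


def cluster_combine(
    scores: np.ndarray,
    valid: np.ndarray,
    fs: float,
    resp_band: tuple[float, float] = RESP_BAND_HZ,
    random_state: int = 0,
) -> np.ndarray:
    """Combine all coils' component pairs into one gating series.

    Components are embedded by pairwise absolute Pearson correlation and
    spectrally clustered into two groups (signal vs nuisance).  The cluster
    scoring higher on within-cluster coherence times respiratory-band
    (0.1-0.5 Hz) power fraction is kept; members are sign-aligned to the
    cluster medoid and averaged after unit-variance scaling.
    """
    comps = scores[valid].reshape(-1, scores.shape[-1])
    # drop zero-variance members (e.g. unused second components)
    sd = comps.std(axis=1)
    comps = comps[sd > 1e-12 * max(1.0, float(np.abs(comps).max()))]
    if len(comps) == 0:
        raise ValueError("no usable components to combine")
    z = (comps - comps.mean(axis=1, keepdims=True)) / comps.std(axis=1, keepdims=True)
    if len(comps) == 1:
        return z[0]
    n_t = comps.shape[1]
    corr = (z @ z.T) / n_t
    affinity = np.abs(corr)

    if len(comps) == 2:
        labels = np.array([0, 1]) if affinity[0, 1] < 0.5 else np.array([0, 0])
    else:
        sc = SpectralClustering(
            n_clusters=2, affinity="precomputed", random_state=random_state,
            assign_labels="discretize",
        )
        labels = sc.fit_predict(affinity)

    # respiratory-band power fraction per component
    spec = np.abs(np.fft.rfft(z, axis=1)) ** 2
    freqs = np.fft.rfftfreq(n_t, d=1.0 / fs)
    in_band = (freqs >= resp_band[0]) & (freqs <= resp_band[1])
    total = spec[:, 1:].sum(axis=1)  # exclude DC
    band_frac = np.where(total > 0, spec[:, in_band].sum(axis=1) / total, 0.0)

    best_score, best = -np.inf, None
    for lab in np.unique(labels):
        members = np.where(labels == lab)[0]
        if len(members) == 1:
            coherence = 1.0
        else:
            sub = affinity[np.ix_(members, members)]
            coherence = (sub.sum() - len(members)) / (len(members) * (len(members) - 1))
        s = coherence * band_frac[members].mean()
        if s > best_score:
            best_score, best = s, members
    medoid = best[np.argmax(affinity[np.ix_(best, best)].sum(axis=1))]
    signs = np.sign(corr[best, medoid])
    signs[signs == 0] = 1.0
    return (signs[:, None] * z[best]).mean(axis=0)


def detrend_poly(series: np.ndarray, order: int | str = "auto") -> np.ndarray:
    """Remove a slowly varying polynomial trend (order 2, 3 or 4).

    ``order='auto'`` picks the order minimizing the Bayesian information
    criterion of the residual, replacing a per-case manual choice.
    """
    y = np.asarray(series, dtype=float)
    n = len(y)
    orders = (2, 3, 4) if order == "auto" else (int(order),)
    if orders[0] not in (2, 3, 4):
        raise ValueError("polynomial order must be 2, 3, 4 or 'auto'")
    if n <= max(orders) + 1:
        raise ValueError("series too short for polynomial detrending")
    x = np.linspace(-1.0, 1.0, n)
    best_bic, best_resid = np.inf, None
    for p in orders:
        fit = np.polynomial.Polynomial.fit(x, y, p)
        resid = y - fit(x)
        rss = float(resid @ resid)
        bic = n * np.log(max(rss, 1e-300) / n) + (p + 1) * np.log(n)
        if bic < best_bic:
            best_bic, best_resid = bic, resid
    return best_resid


def _centroid_track(proj: ProjectionMatrix) -> np.ndarray:
    """Intensity-weighted z centroid of the coil-mean projection per frame.

    Smoothed over ~1 s so that cardiac mass redistribution does not dilute
    the respiratory component used for resolving the sign convention.
    """
    from scipy import ndimage

    w = proj.values.mean(axis=2)  # (n_t, n_z)
    track = (w @ proj.z_axis) / w.sum(axis=1)
    n = max(1, int(round(1.0 / proj.dt)))
    return ndimage.uniform_filter1d(track, n)


def extract_projection_selfgating(
    acq: AcquisitionData,
    span: int = 6,
    detrend_order: int | str = "auto",
    resp_band: tuple[float, float] = RESP_BAND_HZ,
) -> RespiratorySignal:
    """Five-step projection-based respiratory gating signal.

    The output is in arbitrary units proportional to respiratory displacement,
    with inspiration positive (``amplitude_valid = True``).
    """
    proj = si_projections(acq)
    scores, _, valid = coilwise_pca(proj)
    smoothed = np.zeros_like(scores)
    for c in np.where(valid)[0]:
        for k in range(2):
            smoothed[c, k] = lowess_smooth(scores[c, k], span=span)
    fs = 1.0 / proj.dt
    combined = cluster_combine(smoothed, valid, fs=fs, resp_band=resp_band)
    signal = detrend_poly(combined, order=detrend_order)

    # inspiration positive: bright abdominal structures move footward (-z),
    # so the gating signal must anti-correlate with the centroid track
    centroid = _centroid_track(proj)
    c = np.corrcoef(signal, centroid)[0, 1]
    if np.isfinite(c) and c > 0:
        signal = -signal
    return RespiratorySignal(
        t=proj.t, value=signal, amplitude_valid=True, method="projection"
    )
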