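"""Spectral preprocessing chain for dried-plasma Raman line maps.

The chain applied to every raw trace is

    cosmic-ray removal -> Savitzky-Golay smoothing
        -> modified-polynomial (modpoly) baseline subtraction
        -> standard normal variate (SNV) normalization

followed by channel-wise averaging of a sample's traces into one spectrum.
Smoothing precedes baseline estimation because the iterative polynomial clip
is driven by signal-vs-fit comparisons that noise destabilizes.

Parameters default to the published processing settings: SG polynomial order
9 over 27 points, baseline order 11 with convergence threshold 1e-4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .config import RunConfig
from .errors import (
    DespikeError,
    GridMismatchError,
    ParameterError,
    StageError,
    ZeroVarianceError,
)
from .spectrum import Spectrum, check_common_grid

_MAD_TO_SD = 0.6745  # modified z-score scale factor (Iglewicz & Hoaglin)


@dataclass
class SGParams:
    """Savitzky-Golay settings: polynomial order ``order`` over an odd
    ``window``-point sliding window, ``window`` > ``order``."""

    order: int = 9
    window: int = 27

    def __post_init__(self) -> None:
        if self.window % 2 == 0:
            raise ParameterError(f"SG window {self.window} must be odd")
        if self.window <= self.order:
            raise ParameterError(
                f"SG window {self.window} must exceed order {self.order}"
            )


@dataclass
class BaselineFit:
    """Result of the iterative modified-polynomial baseline estimate."""

    order: int
    threshold: float
    n_iter: int
    baseline: np.ndarray
    converged: bool
    wavenumber: np.ndarray
    residual_sd_trace: np.ndarray  # residual SD per iteration, non-increasing


def remove_cosmic_rays(
    s: Spectrum, z_threshold: float = 8.0, neighborhood: int = 5
) -> Spectrum:
    """Remove narrow cosmic-ray spikes.

    Candidate channels are those adjacent to a first-difference whose modified
    z-score exceeds ``z_threshold``; a candidate is confirmed as a spike only
    if it also deviates from the linear interpolation across non-candidate
    channels by more than the same robust threshold.  The confirmation step
    keeps the clean channel just after a spike bit-identical.  Confirmed runs
    longer than 3 channels are not treated as spikes.  Confirmed channels are
    replaced by linear interpolation between the nearest clean neighbors.
    """
    n = len(s)
    if n < 2 * neighborhood:
        raise ParameterError(
            f"trace length {n} < 2 x neighborhood ({2 * neighborhood})"
        )
    y = s.intensity
    d = np.diff(y)
    med = np.median(d)
    mad = np.median(np.abs(d - med))
    if mad == 0.0:
        # (near-)constant differences: fall back to the mean absolute deviation
        mad = np.mean(np.abs(d - med))
        if mad == 0.0:
            return s.with_intensity(y.copy(), despiked=True)
    z = _MAD_TO_SD * (d - med) / mad
    big = np.abs(z) > z_threshold
    candidate = np.zeros(n, dtype=bool)
    candidate[1:] |= big  # large jump into the channel
    candidate[:-1] |= big  # large jump out of the channel
    if not candidate.any():
        return s.with_intensity(y.copy(), despiked=True)

    good = ~candidate
    if good.sum() < 2:
        raise DespikeError("despiking flagged nearly the whole trace")
    interp = np.interp(s.wavenumber, s.wavenumber[good], y[good])
    spike = candidate & (np.abs(y - interp) > z_threshold * mad / _MAD_TO_SD)

    # drop runs longer than 3 channels: too wide to be a cosmic ray
    idx = np.flatnonzero(spike)
    if idx.size:
        breaks = np.flatnonzero(np.diff(idx) > 1)
        for run in np.split(idx, breaks + 1):
            if run.size > 3:
                spike[run] = False

    frac = spike.sum() / n
    if frac > 0.10:
        raise DespikeError(
            f"{spike.sum()}/{n} channels flagged as spikes ({frac:.0%}); "
            "trace likely corrupt"
        )
    if not spike.any():
        return s.with_intensity(y.copy(), despiked=True)
    clean = ~spike
    out = y.copy()
    out[spike] = np.interp(s.wavenumber[spike], s.wavenumber[clean], y[clean])
    return s.with_intensity(out, despiked=True)


def smooth_savitzky_golay(s: Spectrum, params: SGParams | None = None) -> Spectrum:
    """Savitzky-Golay smoothing: the value at each channel is the center of a
    least-squares degree-``order`` polynomial over its ``window``-point
    neighborhood; edges are evaluated from the polynomial fitted to the
    truncated available window."""
    params = params or SGParams()
    if len(s) < params.window:
        raise ParameterError(
            f"trace length {len(s)} < SG window {params.window}"
        )
    sm = savgol_filter(
        s.intensity, window_length=params.window, polyorder=params.order,
        mode="interp",
    )
    return s.with_intensity(sm, smoothed=True)


def fit_baseline_modpoly(
    s: Spectrum,
    order: int = 11,
    threshold: float = 1e-4,
    max_iter: int = 500,
) -> BaselineFit:
    """Iterative modified-polynomial fluorescence baseline (modpoly).

    Each iteration least-squares-fits a degree-``order`` polynomial to the
    working trace and clips the working trace to the fit wherever it exceeds
    it, so peaks are progressively excluded while the smooth background is
    retained.  Iteration stops when the relative change of the residual
    standard deviation falls below ``threshold`` or at ``max_iter`` (then
    ``converged`` is False; no exception is raised).
    """
    n = len(s)
    if n <= order + 1:
        raise ParameterError(f"trace length {n} must exceed order+1 ({order + 1})")
    if threshold <= 0:
        raise ParameterError("threshold must be > 0")
    y_work = s.intensity.astype(float).copy()
    x = s.wavenumber
    # least-squares projection onto degree-`order` polynomials, precomputed
    # once per trace: map the grid to [-1, 1] for conditioning, then QR the
    # Vandermonde basis so each iteration is two thin matrix-vector products
    x_scaled = 2.0 * (x - x[0]) / (x[-1] - x[0]) - 1.0
    q, _ = np.linalg.qr(np.polynomial.polynomial.polyvander(x_scaled, order))
    sd_trace: list[float] = []
    prev_sd = None
    converged = False
    fit = np.zeros_like(y_work)
    n_iter = 0
    # residual SD below fp round-off of the signal scale counts as converged
    # (a degree-<=order polynomial input is an immediate fixed point)
    sd_floor = 1e-12 * max(1.0, float(np.ptp(y_work)))
    for n_iter in range(1, max_iter + 1):
        fit = q @ (q.T @ y_work)
        resid = y_work - fit
        sd = float(resid.std())
        sd_trace.append(sd)
        if sd <= sd_floor:
            converged = True
            break
        if prev_sd is not None and abs(prev_sd - sd) / prev_sd < threshold:
            converged = True
            break
        prev_sd = sd
        y_work = np.minimum(y_work, fit)
    return BaselineFit(
        order=order,
        threshold=threshold,
        n_iter=n_iter,
        baseline=fit,
        converged=converged,
        wavenumber=x.copy(),
        residual_sd_trace=np.asarray(sd_trace),
    )


def subtract_baseline(s: Spectrum, fit: BaselineFit) -> Spectrum:
    """Subtract a fitted baseline computed on the same grid."""
    if fit.wavenumber.size != len(s) or not np.allclose(
        fit.wavenumber, s.wavenumber, rtol=0, atol=1e-9
    ):
        raise GridMismatchError(
            f"baseline fit grid does not match trace ({s.sample_id}, {s.map_id})"
        )
    return s.with_intensity(s.intensity - fit.baseline, baseline_corrected=True)


def normalize_snv(s: Spectrum) -> Spectrum:
    """Standard normal variate: (I - mean) / SD with the sample SD (n-1).

    The output has mean 0 and SD 1 to within floating-point round-off, making
    traces comparable regardless of collection efficiency or film thickness.
    """
    sd = s.intensity.std(ddof=1)
    if sd == 0.0 or not np.isfinite(sd):
        raise ZeroVarianceError(
            f"constant trace ({s.sample_id}, {s.map_id}): SNV undefined"
        )
    out = (s.intensity - s.intensity.mean()) / sd
    return s.with_intensity(out, snv_normalized=True)


def preprocess_spectrum(raw: Spectrum, cfg: RunConfig | None = None) -> Spectrum:
    """Full chain: despike -> SG smooth -> modpoly baseline subtract -> SNV."""
    cfg = cfg or RunConfig()
    stages = (
        ("despike", lambda t: remove_cosmic_rays(
            t, cfg.despike_z_threshold, cfg.despike_neighborhood)),
        ("smooth", lambda t: smooth_savitzky_golay(
            t, SGParams(cfg.sg_order, cfg.sg_window))),
        ("baseline", lambda t: subtract_baseline(
            t, fit_baseline_modpoly(
                t, cfg.baseline_order, cfg.baseline_threshold,
                cfg.baseline_max_iter))),
        ("snv", normalize_snv),
    )
    out = raw
    for name, stage in stages:
        try:
            out = stage(out)
        except Exception as exc:  # attach the stage name for diagnosis
            raise StageError(name, exc) from exc
    return out


def aggregate_sample(spectra) -> Spectrum:
    """Channel-wise mean of one sample's preprocessed traces.

    All traces must share the grid and the same processing state; the output
    records how many traces contributed via ``n_averaged``.
    """
    spectra = list(spectra)
    grid = check_common_grid(spectra)
    states = {s.state for s in spectra}
    if len(states) > 1:
        raise ParameterError(
            f"mixed processing states in sample "
            f"{spectra[0].sample_id!r}: {sorted(states)}"
        )
    mean = np.mean([s.intensity for s in spectra], axis=0)
    first = spectra[0]
    out = first.with_intensity(mean)
    out.map_id = 0
    out.n_averaged = len(spectra)
    return out
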