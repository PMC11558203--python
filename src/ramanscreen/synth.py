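"""Synthetic cohorts with known ground truth.

Emulates the three study inputs so every downstream stage is testable without
patient data:

* **Spectra** — per sample, ``maps_per_sample x spectra_per_map`` traces on
  the 600-1700 cm^-1 grid.  Each trace is a sum of Lorentzian bands (FWHM
  12 cm^-1) at the dictionary positions, plus a broad degree-5 polynomial
  fluorescence baseline, Gaussian detector noise, and occasional narrow
  cosmic-ray spikes.  A sample's band amplitudes (its "biology") are shared
  across all of its traces; only noise, baseline, and spikes vary per trace.
  Disease samples have the nine differential bands (745, 757, 828, 878,
  1002, 1013, 1206, 1657, 1670 cm^-1) scaled up by a configurable ratio
  (default 1.2).
* **Clinical metadata** — per-class Gaussian/Bernoulli draws at the published
  cohort summary parameters (age, BMI, gestational age, gravida, parity,
  pregnancy loss, late blood sugar, comorbidity).
* **Protein panel** — log-normal concentrations for fetuin-A, LECT2, FGF-19
  and FGF-21 normalized to a simulated total protein, with standardized
  log-scale class effects d = 0.9 / 0.0 / 0.5 / 0.2.

All generators are deterministic given (config, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ParameterError
from .features import FeatureTable, load_peak_dictionary
from .spectrum import Spectrum

#: fingerprint-region acquisition grid, 1 cm^-1 steps
DEFAULT_GRID = np.arange(600.0, 1701.0, 1.0)

#: bands scaled up in the disease class by default
DEFAULT_EFFECT_WAVENUMBERS = (745, 757, 828, 878, 1002, 1013, 1206, 1657, 1670)

DEFAULT_FWHM = 12.0  # cm^-1, typical plasma band width


#: bands with a fixed, physically motivated amplitude: the 1448 cm^-1
#: CH-deformation reference is the strongest band in dried plasma, and the
#: 1002 cm^-1 phenylalanine ring-breathing band dominates the aromatic bands
_AMPLITUDE_OVERRIDES = {1448.0: 1.0, 1002.0: 0.9}


def _base_amplitude(wavenumber: float) -> float:
    """Fixed synthetic amplitude profile over the dictionary bands.

    Bands without an explicit override get a deterministic pseudo-varied
    amplitude in [0.3, 0.8] so "most intense band per metabolite" is well
    defined.
    """
    if wavenumber in _AMPLITUDE_OVERRIDES:
        return _AMPLITUDE_OVERRIDES[wavenumber]
    return 0.3 + 0.5 * ((int(wavenumber) * 37) % 97) / 96.0


def default_base_amplitudes() -> dict[float, float]:
    return {p.wavenumber: _base_amplitude(p.wavenumber) for p in load_peak_dictionary()}


#: published per-class clinical distribution parameters
#: (healthy value, disease value)
DEFAULT_CLINICAL = {
    "maternal_age": {"dist": "normal", "mean": (31.8, 31.9), "sd": (4.7, 5.6)},
    "bmi": {"dist": "truncnormal", "mean": (29.5, 31.9), "sd": (10.1, 7.8),
            "lower": 15.0},
    "gestational_age": {"dist": "normal", "mean": (38.5, 38.8), "sd": (1.8, 1.3)},
    "gravida": {"dist": "count", "mean": (2.5, 2.7), "sd": (1.5, 1.7)},
    "parity": {"dist": "count", "mean": (1.1, 1.2), "sd": (0.9, 1.4)},
    "pregnancy_loss": {"dist": "count", "mean": (0.4, 0.5), "sd": (0.7, 0.8)},
    "blood_sugar": {"dist": "normal", "mean": (116.0, 185.4), "sd": (20.1, 29.2)},
    "comorbidity": {"dist": "bernoulli", "p": (0.176, 0.029)},
}

#: standardized log-scale class effects for the protein panel
DEFAULT_PROTEIN_EFFECTS = {
    "fetuin_a": 0.9,
    "lect2": 0.0,
    "fgf_19": 0.5,
    "fgf_21": 0.2,
}


@dataclass
class EffectConfig:
    """Class-difference structure and nuisance levels of a synthetic cohort."""

    #: disease/healthy amplitude ratio per wavenumber; absent bands ratio 1
    amplitude_ratios: dict[float, float] = field(
        default_factory=lambda: {float(w): 1.2 for w in DEFAULT_EFFECT_WAVENUMBERS}
    )
    #: lognormal sigma of per-sample, per-band amplitude variation
    amplitude_sigma: float = 0.1
    #: Gaussian noise SD per channel, in units of the reference amplitude
    noise_sd: float = 0.02
    #: baseline amplitude range, as multiples of the median band amplitude
    baseline_scale: tuple[float, float] = (5.0, 20.0)
    baseline_degree: int = 5
    #: per-trace cosmic-ray probability; spikes are 1-2 channels wide at
    #: 20-100x the largest band amplitude
    spike_prob: float = 0.05
    spike_amplitude: tuple[float, float] = (20.0, 100.0)
    fwhm: float = DEFAULT_FWHM
    clinical: dict = field(default_factory=lambda: dict(DEFAULT_CLINICAL))
    protein_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROTEIN_EFFECTS)
    )
    protein_log_sigma: float = 0.4

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.amplitude_ratios.values()):
            raise ParameterError("amplitude ratios must be > 0")
        if self.amplitude_sigma < 0 or self.noise_sd < 0:
            raise ParameterError("sigmas must be >= 0")
        if not 0 <= self.spike_prob <= 1:
            raise ParameterError("spike_prob must be in [0, 1]")
        if self.protein_log_sigma <= 0:
            raise ParameterError("protein_log_sigma must be > 0")
        for name, spec in self.clinical.items():
            if spec["dist"] == "bernoulli":
                if not all(0 <= p <= 1 for p in spec["p"]):
                    raise ParameterError(f"{name}: Bernoulli p outside [0, 1]")
            elif any(s <= 0 for s in spec["sd"]):
                raise ParameterError(f"{name}: SD must be > 0")


@dataclass
class SpectrumTruth:
    """Ground truth for one sample's traces."""

    amplitudes: dict[float, float]  # band center -> true apex amplitude
    baseline_coeffs: np.ndarray  # polynomial coefficients, low to high degree
    noise_sd: float
    spike_channels: tuple[int, ...] = ()
    spike_height: float = 0.0
    label: int = 0

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.amplitudes.values()):
            raise ParameterError("band amplitudes must be >= 0")
        if self.noise_sd < 0:
            raise ParameterError("noise SD must be >= 0")


def lorentzian(grid: np.ndarray, center: float, amplitude: float,
               fwhm: float = DEFAULT_FWHM) -> np.ndarray:
    """Lorentzian line with apex value ``amplitude`` at ``center``."""
    hwhm = fwhm / 2.0
    return amplitude * hwhm**2 / ((grid - center) ** 2 + hwhm**2)


def generate_spectrum(
    truth: SpectrumTruth,
    grid: np.ndarray = DEFAULT_GRID,
    seed: int | np.random.Generator | None = 0,
    fwhm: float = DEFAULT_FWHM,
    sample_id: str = "",
    map_id: int = 0,
) -> Spectrum:
    """One trace: sum of Lorentzian bands + polynomial baseline + Gaussian
    noise + cosmic-ray spikes; deterministic given the seed."""
    grid = np.asarray(grid, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = np.zeros_like(grid)
    for center, amp in truth.amplitudes.items():
        if not grid[0] <= center <= grid[-1]:
            raise ParameterError(f"band center {center} cm^-1 outside the grid")
        y += lorentzian(grid, center, amp, fwhm)
    if truth.baseline_coeffs.size:
        x01 = (grid - grid[0]) / (grid[-1] - grid[0])
        y += np.polynomial.polynomial.polyval(x01, truth.baseline_coeffs)
    if truth.noise_sd > 0:
        y += rng.normal(0.0, truth.noise_sd, size=grid.size)
    for ch in truth.spike_channels:
        if not 0 <= ch < grid.size:
            raise ParameterError(f"spike channel {ch} outside the grid")
        y[ch] += truth.spike_height
    return Spectrum(grid.copy(), y, sample_id=sample_id, map_id=map_id)


def _sample_truth(
    rng: np.random.Generator,
    effects: EffectConfig,
    label: int,
    base_amplitudes: dict[float, float],
    grid: np.ndarray,
    dictionary_wavenumbers: set[float],
) -> SpectrumTruth:
    """Draw one sample's true amplitudes and nuisance parameters."""
    for w in effects.amplitude_ratios:
        if w not in dictionary_wavenumbers:
            warnings.warn(
                f"effect at {w} cm^-1 is not a dictionary band; simulated anyway",
                stacklevel=3,
            )
    amps = {}
    for w, base in base_amplitudes.items():
        jitter = float(np.exp(rng.normal(0.0, effects.amplitude_sigma)))
        ratio = effects.amplitude_ratios.get(w, 1.0) if label == 1 else 1.0
        amps[w] = base * jitter * ratio
    med = float(np.median(list(base_amplitudes.values())))
    lo, hi = effects.baseline_scale
    target_range = rng.uniform(lo, hi) * med if hi > 0 else 0.0
    if target_range > 0:
        coeffs = rng.normal(0.0, 1.0, size=effects.baseline_degree + 1)
        x01 = np.linspace(0.0, 1.0, grid.size)
        raw = np.polynomial.polynomial.polyval(x01, coeffs)
        span = raw.max() - raw.min()
        scale = target_range / span if span > 0 else 0.0
        coeffs = coeffs * scale
        coeffs[0] -= raw.min() * scale  # keep the baseline non-negative
    else:
        coeffs = np.zeros(0)
    return SpectrumTruth(
        amplitudes=amps,
        baseline_coeffs=np.asarray(coeffs, dtype=float),
        noise_sd=effects.noise_sd,
        label=label,
    )


def generate_cohort_spectra(
    n_per_class: int,
    effects: EffectConfig | None = None,
    seed: int = 0,
    grid: np.ndarray = DEFAULT_GRID,
    maps_per_sample: int = 10,
    spectra_per_map: int = 10,
) -> tuple[dict[str, list[Spectrum]], dict[str, SpectrumTruth]]:
    """A two-class cohort of line-map spectra plus each sample's truth.

    Per sample, ``maps_per_sample x spectra_per_map`` traces (the study
    acquired 10 x 10 = 100) share that sample's true band amplitudes;
    noise, baseline draw and cosmic rays are independent per trace.
    """
    if n_per_class < 2:
        raise ParameterError("n_per_class must be >= 2")
    effects = effects or EffectConfig()
    rng = np.random.default_rng(seed)
    base = default_base_amplitudes()
    dict_wns = set(base)
    max_amp = max(base.values())
    spectra: dict[str, list[Spectrum]] = {}
    truths: dict[str, SpectrumTruth] = {}
    for label, prefix in ((0, "healthy"), (1, "disease")):
        for i in range(n_per_class):
            sid = f"{prefix}_{i:03d}"
            truth = _sample_truth(rng, effects, label, base, grid, dict_wns)
            truths[sid] = truth
            traces = []
            for m in range(maps_per_sample):
                for k in range(spectra_per_map):
                    trace_truth = SpectrumTruth(
                        amplitudes=truth.amplitudes,
                        baseline_coeffs=truth.baseline_coeffs,
                        noise_sd=truth.noise_sd,
                        label=label,
                    )
                    if effects.spike_prob > 0 and rng.random() < effects.spike_prob:
                        width = int(rng.integers(1, 3))
                        start = int(rng.integers(0, grid.size - width))
                        trace_truth.spike_channels = tuple(
                            range(start, start + width)
                        )
                        trace_truth.spike_height = float(
                            rng.uniform(*effects.spike_amplitude) * max_amp
                        )
                    # map_id identifies the trace: line map m, position k
                    traces.append(
                        generate_spectrum(
                            trace_truth, grid, rng,
                            fwhm=effects.fwhm, sample_id=sid,
                            map_id=m * spectra_per_map + k,
                        )
                    )
            spectra[sid] = traces
    return spectra, truths


def cohort_labels(truths: dict[str, SpectrumTruth]) -> dict[str, int]:
    return {sid: t.label for sid, t in truths.items()}


def generate_clinical(
    n_per_class: int, effects: EffectConfig | None = None, seed: int = 0
) -> pd.DataFrame:
    """Clinical metadata table at the published per-class parameters."""
    if n_per_class < 2:
        raise ParameterError("n_per_class must be >= 2")
    effects = effects or EffectConfig()
    rng = np.random.default_rng(seed)
    frames = []
    for label, prefix in ((0, "healthy"), (1, "disease")):
        cols: dict[str, np.ndarray] = {
            "sample_id": np.array(
                [f"{prefix}_{i:03d}" for i in range(n_per_class)]
            ),
            "class": np.full(n_per_class, label),
        }
        for name, spec in effects.clinical.items():
            if spec["dist"] == "bernoulli":
                p = spec["p"][label]
                cols[name] = (rng.random(n_per_class) < p).astype(int)
                continue
            mean, sd = spec["mean"][label], spec["sd"][label]
            if spec["dist"] == "truncnormal":
                a = (spec["lower"] - mean) / sd
                vals = sps.truncnorm.rvs(
                    a, np.inf, loc=mean, scale=sd, size=n_per_class,
                    random_state=rng,
                )
            else:
                vals = rng.normal(mean, sd, size=n_per_class)
            if spec["dist"] == "count":
                vals = np.maximum(np.round(vals), 0.0)
            cols[name] = vals
        frames.append(pd.DataFrame(cols))
    return pd.concat(frames, ignore_index=True)


def generate_proteins(
    n_per_class: int, effects: EffectConfig | None = None, seed: int = 0
) -> FeatureTable:
    """Protein panel: log-normal concentrations normalized to a simulated
    total protein, with log-scale standardized class effects."""
    if n_per_class < 2:
        raise ParameterError("n_per_class must be >= 2")
    effects = effects or EffectConfig()
    rng = np.random.default_rng(seed)
    names = list(effects.protein_effects)
    sigma = effects.protein_log_sigma
    ids, labels, rows = [], [], []
    for label, prefix in ((0, "healthy"), (1, "disease")):
        for i in range(n_per_class):
            total = np.exp(rng.normal(0.0, 0.05))  # simulated total protein
            row = []
            for name in names:
                d = effects.protein_effects[name]
                mu = d * sigma if label == 1 else 0.0
                row.append(np.exp(rng.normal(mu, sigma)) / total)
            ids.append(f"{prefix}_{i:03d}")
            labels.append(label)
            rows.append(row)
    return FeatureTable(ids, np.asarray(labels), names, np.asarray(rows))
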