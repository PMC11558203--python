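"""Ratiometric peak features over the shipped band-assignment dictionary.

Each sample's aggregated spectrum is reduced to one intensity per dictionary
band (the local maximum within +/-5 cm^-1 of the nominal position, tolerant
of small calibration drift) and expressed as a ratio to the 1448 cm^-1
lipid/protein CH-deformation band, which varies little between plasma
samples.  Because SNV normalization produces negative values, each aggregated
spectrum is first re-offset by its minimum over the fingerprint window so
every band intensity is non-negative and the reference strictly positive;
ratios are invariant to any per-trace multiplicative gain either way.

Redundant bands (one metabolite assigned at several wavenumbers) are then
collapsed to the single most intense band per metabolite, dropping the
reference, which takes the shipped 39-entry dictionary to 30 features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .errors import FormatError, GridMismatchError, ParameterError
from .spectrum import Spectrum, check_common_grid

log = logging.getLogger(__name__)

REFERENCE_WAVENUMBER = 1448.0


@dataclass(frozen=True)
class PeakAssignment:
    """One dictionary row: nominal band position, metabolite, mode."""

    wavenumber: float
    metabolite: str
    mode: str
    is_reference: bool = False

    @property
    def feature_name(self) -> str:
        return f"{self.wavenumber:g}_{self.metabolite}"


def load_peak_dictionary() -> list[PeakAssignment]:
    """The shipped 39-band dictionary (unique positions, one reference)."""
    with resources.files("ramanscreen.data").joinpath(
        "peak_assignments.csv"
    ).open() as fh:
        df = pd.read_csv(fh)
    peaks = [
        PeakAssignment(
            wavenumber=float(r.wavenumber),
            metabolite=str(r.metabolite),
            mode=str(r.mode),
            is_reference=bool(r.is_reference),
        )
        for r in df.itertuples()
    ]
    _validate_dictionary(peaks)
    return peaks


def _validate_dictionary(peaks: list[PeakAssignment]) -> None:
    wns = [p.wavenumber for p in peaks]
    if len(set(wns)) != len(wns):
        raise FormatError("peak dictionary has duplicate wavenumbers")
    n_ref = sum(p.is_reference for p in peaks)
    if n_ref != 1:
        raise FormatError(f"peak dictionary must have exactly 1 reference, got {n_ref}")


@dataclass
class FeatureTable:
    """Samples x named numeric features with binary class labels."""

    sample_ids: list[str]
    labels: np.ndarray
    feature_names: list[str]
    X: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.size == 0:
            self.X = self.X.reshape(len(self.sample_ids), len(self.feature_names))
        if len(self.feature_names) != len(set(self.feature_names)):
            raise FormatError("feature names must be unique")
        if self.X.shape != (len(self.sample_ids), len(self.feature_names)):
            raise FormatError(
                f"matrix shape {self.X.shape} != "
                f"({len(self.sample_ids)}, {len(self.feature_names)})"
            )
        if self.labels.shape != (len(self.sample_ids),):
            raise FormatError("one class label per sample required")
        if self.labels.size and not np.isin(self.labels, (0, 1)).all():
            raise FormatError("class labels must be binary 0/1")
        if not np.all(np.isfinite(self.X)):
            raise FormatError("feature matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def column(self, name: str) -> np.ndarray:
        return self.X[:, self.feature_names.index(name)]

    def select(self, names: list[str]) -> "FeatureTable":
        idx = [self.feature_names.index(n) for n in names]
        return FeatureTable(
            list(self.sample_ids), self.labels.copy(), list(names),
            self.X[:, idx].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df.insert(0, "class", self.labels)
        df.insert(0, "sample_id", self.sample_ids)
        return df


def extract_peak_intensity(
    s: Spectrum, peak: PeakAssignment | float, half_width: float = 5.0
) -> float:
    """Maximum intensity within ``half_width`` cm^-1 of the nominal position;
    ties resolve to the channel nearest the nominal center."""
    nominal = peak.wavenumber if isinstance(peak, PeakAssignment) else float(peak)
    if half_width <= 0:
        raise ParameterError("half_width must be > 0")
    lo, hi = nominal - half_width, nominal + half_width
    if lo < s.wavenumber[0] or hi > s.wavenumber[-1]:
        raise ParameterError(
            f"window [{lo}, {hi}] cm^-1 outside grid "
            f"[{s.wavenumber[0]}, {s.wavenumber[-1]}]"
        )
    mask = (s.wavenumber >= lo) & (s.wavenumber <= hi)
    vals = s.intensity[mask]
    wns = s.wavenumber[mask]
    best = vals.max()
    ties = np.flatnonzero(vals == best)
    pick = ties[np.argmin(np.abs(wns[ties] - nominal))]
    return float(vals[pick])


def _offset_nonnegative(s: Spectrum) -> Spectrum:
    """Shift an (SNV-normalized) spectrum by its minimum so band intensities
    are non-negative before ratio formation."""
    return s.with_intensity(s.intensity - s.intensity.min())


def build_feature_table(
    samples,
    labels,
    dictionary: list[PeakAssignment] | None = None,
    reference: float = REFERENCE_WAVENUMBER,
    half_width: float = 5.0,
) -> FeatureTable:
    """Ratiometric feature table: band intensity / reference intensity.

    ``samples`` is a sequence of aggregated per-sample spectra and ``labels``
    their binary classes.  The reference feature equals 1 for every sample
    (self-ratio) and is retained until :func:`select_nonredundant`.  Samples
    whose reference intensity is not strictly positive after the minimum
    offset are excluded with a log entry.
    """
    dictionary = dictionary or load_peak_dictionary()
    _validate_dictionary(dictionary)
    samples = list(samples)
    labels = np.asarray(labels, dtype=int)
    if labels.shape != (len(samples),):
        raise ParameterError("one label per sample required")
    names = [p.feature_name for p in dictionary]
    rows, kept_ids, kept_labels = [], [], []
    for s, lab in zip(samples, labels):
        off = _offset_nonnegative(s)
        ref = extract_peak_intensity(off, reference, half_width)
        if ref <= 0:
            log.warning(
                "sample %r excluded: reference %g cm^-1 intensity %g <= 0",
                s.sample_id, reference, ref,
            )
            continue
        rows.append(
            [extract_peak_intensity(off, p, half_width) / ref for p in dictionary]
        )
        kept_ids.append(s.sample_id)
        kept_labels.append(lab)
    return FeatureTable(
        kept_ids,
        np.asarray(kept_labels, dtype=int),
        names,
        np.asarray(rows, dtype=float).reshape(len(kept_ids), len(names)),
    )


def select_nonredundant(
    table: FeatureTable, dictionary: list[PeakAssignment] | None = None
) -> FeatureTable:
    """Collapse each multiply-assigned metabolite to its most intense band.

    "Most intense" is resolved on the cohort mean (both classes pooled) of
    the extracted feature, so the retained band is common to all samples.
    The reference band is dropped.  On the shipped dictionary 39 features
    reduce to exactly 30.
    """
    dictionary = dictionary or load_peak_dictionary()
    by_name = {p.feature_name: p for p in dictionary}
    missing = [n for n in table.feature_names if n not in by_name]
    if missing:
        raise ParameterError(f"features not in dictionary: {missing}")
    groups: dict[str, list[str]] = {}
    for name in table.feature_names:
        p = by_name[name]
        if p.is_reference:
            continue
        groups.setdefault(p.metabolite, []).append(name)
    kept: list[str] = []
    for names in groups.values():
        means = {n: float(table.column(n).mean()) for n in names}
        best = max(means.values())
        # deterministic tie-break: lowest wavenumber among the maxima
        winners = sorted(
            (n for n in names if means[n] == best),
            key=lambda n: by_name[n].wavenumber,
        )
        kept.append(winners[0])
    kept.sort(key=lambda n: by_name[n].wavenumber)
    return table.select(kept)


def difference_spectrum(group_a, group_b) -> Spectrum:
    """mean(group_a) - mean(group_b) on the common grid.

    With ``group_a`` the disease cohort and ``group_b`` the healthy cohort,
    positive values mark bands more abundant in disease.
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ParameterError("both groups must be nonempty")
    grid = check_common_grid(group_a + group_b)
    mean_a = np.mean([s.intensity for s in group_a], axis=0)
    mean_b = np.mean([s.intensity for s in group_b], axis=0)
    return Spectrum(grid.copy(), mean_a - mean_b, sample_id="difference")
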