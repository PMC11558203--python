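"""Run configuration.

A single YAML file drives every stage of the pipeline.  Unset fields take the
published processing parameters as defaults: Savitzky-Golay order 9 with a
27-point window, an 11th-order modified-polynomial baseline with convergence
threshold 1e-4, the 1448 cm^-1 lipid/protein reference band, t-SNE perplexity
30 with early exaggeration 3, and 30 permutation-importance repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass
class RunConfig:
    # spectral preprocessing
    sg_order: int = 9
    sg_window: int = 27
    baseline_order: int = 11
    baseline_threshold: float = 1e-4
    baseline_max_iter: int = 500
    despike_z_threshold: float = 8.0
    despike_neighborhood: int = 5
    # feature extraction
    peak_half_width: float = 5.0
    reference_wavenumber: float = 1448.0
    # model evaluation
    cv_scheme: str = "kfold5"
    cv_shuffle: bool = True
    kernels: tuple = ("linear", "poly", "rbf")
    c_grid: tuple = (0.01, 0.1, 1.0, 10.0, 100.0)
    degree_grid: tuple = (2, 3, 4)
    tsne_perplexity: float = 30.0
    tsne_exaggeration: float = 3.0
    permutation_repeats: int = 30
    # synthetic cohort
    n_per_class: int = 34
    maps_per_sample: int = 10
    spectra_per_map: int = 10
    # randomness: required whenever any stochastic stage runs
    seed: int | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        errs = []
        if self.sg_window % 2 == 0:
            errs.append(f"sg_window={self.sg_window}: must be odd")
        if self.sg_window <= self.sg_order:
            errs.append(
                f"sg_window={self.sg_window}: must exceed sg_order={self.sg_order}"
            )
        if self.sg_order < 1:
            errs.append(f"sg_order={self.sg_order}: must be >= 1")
        if self.baseline_threshold <= 0:
            errs.append(f"baseline_threshold={self.baseline_threshold}: must be > 0")
        if self.baseline_order < 1:
            errs.append(f"baseline_order={self.baseline_order}: must be >= 1")
        if self.baseline_max_iter < 1:
            errs.append(f"baseline_max_iter={self.baseline_max_iter}: must be >= 1")
        if self.peak_half_width <= 0:
            errs.append(f"peak_half_width={self.peak_half_width}: must be > 0")
        if self.despike_z_threshold <= 0:
            errs.append(
                f"despike_z_threshold={self.despike_z_threshold}: must be > 0"
            )
        if self.cv_scheme not in ("kfold5", "loo"):
            errs.append(f"cv_scheme={self.cv_scheme!r}: must be 'kfold5' or 'loo'")
        for k in self.kernels:
            if k not in ("linear", "poly", "rbf"):
                errs.append(f"kernels contains {k!r}: must be linear/poly/rbf")
        if self.tsne_perplexity <= 0:
            errs.append(f"tsne_perplexity={self.tsne_perplexity}: must be > 0")
        if self.permutation_repeats < 1:
            errs.append(f"permutation_repeats={self.permutation_repeats}: must be >= 1")
        if self.n_per_class < 2:
            errs.append(f"n_per_class={self.n_per_class}: must be >= 2")
        if self.maps_per_sample < 1 or self.spectra_per_map < 1:
            errs.append("maps_per_sample and spectra_per_map must be >= 1")
        if errs:
            raise ConfigError("; ".join(errs))

    def require_seed(self) -> int:
        """Seed for a stochastic stage; absence is a configuration error."""
        if self.seed is None:
            raise ConfigError("a seed is required for stochastic stages")
        return int(self.seed)

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML config; unset fields take the published defaults.

    An empty or absent file yields the full default :class:`RunConfig`.
    Unknown keys and out-of-range values raise :class:`ConfigError` naming the
    field and the violated bound.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        data = loaded
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for key in ("kernels", "c_grid", "degree_grid"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    return RunConfig(**data)
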