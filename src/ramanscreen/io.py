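"""Readers and writers for the pipeline's plain-text formats.

Spectra travel either as two-column whitespace-delimited text (one trace per
file: wavenumber, intensity) or as the canonical long-format CSV
(``sample_id, map_id, wavenumber, intensity``) that mirrors line-map
acquisition.  All traces must share one wavenumber grid after loading; there
is no implicit resampling.  Feature tables are CSV with a ``sample_id`` and
``class`` column and round-trip losslessly at 12 significant digits.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, GridMismatchError
from .features import FeatureTable
from .spectrum import Spectrum, check_common_grid

_FLOAT_FMT = "%.12g"


def read_spectra(path: str | Path, format: str = "long") -> dict[str, list[Spectrum]]:
    """Load spectra grouped by sample, verifying one common ascending grid.

    ``format='two_column'``: whitespace-delimited wavenumber/intensity; the
    sample id is the file stem and the map id 0.  ``format='long'``: CSV with
    columns sample_id, map_id, wavenumber, intensity.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format == "two_column":
        try:
            arr = np.loadtxt(path, dtype=float, ndmin=2)
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
        if arr.shape[1] != 2:
            raise FormatError(f"{path}: expected 2 columns, got {arr.shape[1]}")
        spectra = {path.stem: [_make_trace(arr[:, 0], arr[:, 1], path.stem, 0)]}
    elif format == "long":
        try:
            df = pd.read_csv(path)
        except Exception as exc:
            raise FormatError(f"{path}: {exc}") from exc
        required = {"sample_id", "map_id", "wavenumber", "intensity"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"{path}: missing columns {sorted(missing)}")
        spectra = {}
        for (sid, mid), grp in df.groupby(["sample_id", "map_id"], sort=True):
            spectra.setdefault(str(sid), []).append(
                _make_trace(
                    grp["wavenumber"].to_numpy(dtype=float),
                    grp["intensity"].to_numpy(dtype=float),
                    str(sid), int(mid),
                )
            )
    else:
        raise FormatError(f"unknown spectra format {format!r}")
    check_common_grid([t for traces in spectra.values() for t in traces])
    return spectra


def _make_trace(wn, inten, sid, mid) -> Spectrum:
    if wn.size and np.any(np.diff(wn) <= 0):
        raise FormatError(
            f"non-monotone wavenumber grid in trace ({sid}, {mid})"
        )
    return Spectrum(wn, inten, sample_id=sid, map_id=mid)


def write_spectra_long(spectra, path: str | Path) -> None:
    """Write spectra (a {sample_id: [Spectrum]} mapping or an iterable of
    Spectrum) as the canonical long-format CSV."""
    if isinstance(spectra, dict):
        traces = [t for ts in spectra.values() for t in ts]
    else:
        traces = list(spectra)
    frames = [
        pd.DataFrame(
            {
                "sample_id": t.sample_id,
                "map_id": t.map_id,
                "wavenumber": t.wavenumber,
                "intensity": t.intensity,
            }
        )
        for t in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """CSV with header (sample_id, class, features...); 12 significant
    digits, lossless through :func:`read_feature_table`."""
    table.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_feature_table(path: str | Path) -> FeatureTable:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path)
    for col in ("sample_id", "class"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    names = [c for c in df.columns if c not in ("sample_id", "class")]
    return FeatureTable(
        df["sample_id"].astype(str).tolist(),
        df["class"].to_numpy(dtype=int),
        names,
        df[names].to_numpy(dtype=float).reshape(len(df), len(names)),
    )


def write_truth_table(truths, path: str | Path) -> None:
    """Ground-truth amplitudes of a synthetic cohort:
    (sample_id, wavenumber, amplitude, class) CSV."""
    rows = [
        {"sample_id": sid, "wavenumber": w, "amplitude": a, "class": t.label}
        for sid, t in truths.items()
        for w, a in sorted(t.amplitudes.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)
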