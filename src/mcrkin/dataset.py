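"""Spectral dataset container, delimited-text I/O and preprocessing.

A :class:`SpectralDataset` couples a wavenumber grid (cm^-1, stored
ascending), an absorbance matrix (samples x wavenumbers) and a per-sample
metadata table.  The on-disk layout is a single wide delimited table: the
leading columns are metadata (``sample_id``, ``material_kind``,
``age_months``, optionally ``batch`` and ``replicate``), the remaining
column headers are wavenumbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SpectralDataset",
    "SpectralDataError",
    "read_spectra",
    "write_spectra",
    "select_range",
    "average_replicates",
    "baseline_correct",
    "interpolate_to_grid",
]

#: Metadata columns recognised in the wide file layout, in canonical order.
METADATA_COLUMNS = ("sample_id", "material_kind", "age_months", "batch", "replicate")
REQUIRED_METADATA = ("sample_id", "material_kind", "age_months")
MATERIAL_KINDS = ("tablet", "substance", "pure_component")

BASELINE_METHODS = ("offset", "linear", "none")


class SpectralDataError(ValueError):
    """Raised for malformed spectral files or inconsistent datasets."""


@dataclass
class SpectralDataset:
    """NIR spectra on a common wavenumber grid plus per-sample metadata.

    Parameters
    ----------
    wavenumbers : ndarray, shape (J,)
        Strictly monotone grid in cm^-1.  Descending input is accepted and
        stored ascending, with absorbance columns permuted consistently.
    absorbance : ndarray, shape (I, J)
        Absorbance (arbitrary units); must be finite.
    samples : DataFrame, length I
        Must contain ``sample_id``, ``material_kind`` and ``age_months``.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    samples: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        ab = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        if wn.ndim != 1:
            raise SpectralDataError("wavenumbers must be one-dimensional")
        d = np.diff(wn)
        if len(wn) > 1 and np.all(d < 0):  # instrument convention: flip
            wn = wn[::-1]
            ab = ab[:, ::-1]
        elif len(wn) > 1 and not np.all(d > 0):
            raise SpectralDataError("wavenumbers must be strictly monotone")
        samples = self.samples.reset_index(drop=True)
        for col in REQUIRED_METADATA:
            if col not in samples.columns:
                raise SpectralDataError(f"metadata missing required column {col!r}")
        if ab.shape != (len(samples), len(wn)):
            raise SpectralDataError(
                f"absorbance shape {ab.shape} does not match "
                f"{len(samples)} samples x {len(wn)} wavenumbers"
            )
        if not np.all(np.isfinite(ab)):
            raise SpectralDataError("absorbance contains missing/non-finite values")
        bad = set(samples["material_kind"]) - set(MATERIAL_KINDS)
        if bad:
            raise SpectralDataError(f"unknown material_kind values: {sorted(bad)}")
        if (samples["age_months"].astype(float) < 0).any():
            raise SpectralDataError("age_months must be >= 0")
        self.wavenumbers = wn
        self.absorbance = ab
        self.samples = samples

    # -- convenience -----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavenumbers(self) -> int:
        return self.absorbance.shape[1]

    def ages(self) -> np.ndarray:
        """Nominal sample ages in months, as a float array."""
        return self.samples["age_months"].to_numpy(dtype=float)

    def subset(self, mask: np.ndarray) -> "SpectralDataset":
        """Row subset by boolean mask or integer index array."""
        mask = np.asarray(mask)
        return SpectralDataset(
            self.wavenumbers.copy(),
            self.absorbance[mask],
            self.samples.iloc[np.flatnonzero(mask) if mask.dtype == bool else mask],
        )

    def copy(self) -> "SpectralDataset":
        return SpectralDataset(
            self.wavenumbers.copy(), self.absorbance.copy(), self.samples.copy()
        )

    def to_frame(self) -> pd.DataFrame:
        """Wide table: metadata columns followed by one column per wavenumber."""
        meta = [c for c in METADATA_COLUMNS if c in self.samples.columns]
        extra = [c for c in self.samples.columns if c not in meta]
        spec = pd.DataFrame(
            self.absorbance, columns=[format(w, "g") for w in self.wavenumbers]
        )
        return pd.concat(
            [self.samples[meta + extra].reset_index(drop=True), spec], axis=1
        )


def _sep_for(path: Path, dialect: str | None) -> str:
    if dialect in ("csv", "tsv"):
        return "," if dialect == "csv" else "\t"
    if dialect is not None:
        raise SpectralDataError(f"unknown dialect {dialect!r}")
    return "\t" if path.suffix.lower() in (".tsv", ".txt") else ","


def read_spectra(path: str | Path, dialect: str | None = None) -> SpectralDataset:
    """Read a wide delimited spectral table (CSV/TSV autodetected by extension).

    Wavenumber columns may appear in descending (instrument) order; they are
    re-sorted ascending with absorbance columns permuted consistently.
    """
    path = Path(path)
    sep = _sep_for(path, dialect)
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.ParserError as exc:
        raise SpectralDataError(f"cannot parse {path.name}: {exc}") from exc
    meta_cols = [c for c in df.columns if c in METADATA_COLUMNS]
    spec_cols = [c for c in df.columns if c not in METADATA_COLUMNS]
    try:
        wn = np.array([float(c) for c in spec_cols])
    except ValueError as exc:
        raise SpectralDataError(
            f"malformed header in {path.name}: non-numeric wavenumber column ({exc})"
        ) from exc
    if len(spec_cols) == 0:
        raise SpectralDataError(f"{path.name} has no wavenumber columns")
    ab = df[spec_cols].to_numpy(dtype=float)
    if np.isnan(ab).any():
        rows = np.flatnonzero(np.isnan(ab).any(axis=1)) + 2  # 1-based + header
        raise SpectralDataError(
            f"{path.name}: missing absorbance values (file line(s) {rows.tolist()})"
        )
    return SpectralDataset(wn, ab, df[meta_cols])


def write_spectra(ds: SpectralDataset, path: str | Path, dialect: str | None = None) -> None:
    """Write the wide delimited layout read back by :func:`read_spectra`."""
    path = Path(path)
    ds.to_frame().to_csv(path, sep=_sep_for(path, dialect), index=False)


def select_range(ds: SpectralDataset, lo: float, hi: float) -> SpectralDataset:
    """Keep wavenumber columns in the closed interval [lo, hi] (cm^-1)."""
    if not lo < hi:
        raise ValueError(f"require lo < hi, got [{lo}, {hi}]")
    keep = (ds.wavenumbers >= lo) & (ds.wavenumbers <= hi)
    if not keep.any():
        raise SpectralDataError(f"no wavenumbers in [{lo}, {hi}]")
    return SpectralDataset(ds.wavenumbers[keep], ds.absorbance[:, keep], ds.samples)


def average_replicates(ds: SpectralDataset) -> SpectralDataset:
    """Average replicate spectra per ``sample_id`` (arithmetic mean).

    Replicate groups must agree on all other metadata; conflicting
    ``age_months``/``material_kind``/``batch`` within a group is an error.
    The replicate index column is dropped.
    """
    keys = [c for c in ("material_kind", "age_months", "batch") if c in ds.samples.columns]
    rows, metas = [], []
    for sid, grp in ds.samples.groupby("sample_id", sort=False):
        for col in keys:
            if grp[col].nunique() > 1:
                raise SpectralDataError(
                    f"replicates of sample {sid!r} disagree on {col!r}: "
                    f"{sorted(grp[col].unique())}"
                )
        rows.append(ds.absorbance[grp.index.to_numpy()].mean(axis=0))
        metas.append(grp.iloc[0].drop(labels=["replicate"], errors="ignore"))
    return SpectralDataset(
        ds.wavenumbers, np.vstack(rows), pd.DataFrame(metas).reset_index(drop=True)
    )


def baseline_correct(
    ds: SpectralDataset, method: str = "offset", window: int = 15
) -> SpectralDataset:
    """Baseline-correct each spectrum over the retained range.

    ``offset`` subtracts each spectrum's minimum, estimated on a moving
    average of ``window`` grid points so the estimate does not chase the
    deepest noise excursion (``window=1`` is the plain minimum); ``linear``
    subtracts the straight line through the values at the two range
    endpoints; ``none`` returns the input unchanged.
    """
    if method not in BASELINE_METHODS:
        raise ValueError(f"method must be one of {BASELINE_METHODS}, got {method!r}")
    if method == "none":
        return ds
    X = ds.absorbance
    if method == "offset":
        w = max(1, min(int(window), X.shape[1]))
        if w == 1:
            m = X.min(axis=1, keepdims=True)
        else:
            kernel = np.ones(w) / w
            smoothed = np.apply_along_axis(
                lambda r: np.convolve(r, kernel, mode="valid"), 1, X
            )
            m = smoothed.min(axis=1, keepdims=True)
        Xc = X - m
    else:  # linear through the two endpoints
        wn = ds.wavenumbers
        frac = (wn - wn[0]) / (wn[-1] - wn[0])
        left, right = X[:, :1], X[:, -1:]
        Xc = X - (left + (right - left) * frac[None, :])
    return SpectralDataset(ds.wavenumbers, Xc, ds.samples)


def interpolate_to_grid(
    wavenumbers: np.ndarray, spectra: np.ndarray, target_grid: np.ndarray
) -> np.ndarray:
    """Linearly interpolate spectra (rows) onto a target wavenumber grid.

    Used when pure-component spectra were acquired on a different grid than
    the mixture dataset; the bilinear model requires a shared grid.
    """
    wavenumbers = np.asarray(wavenumbers, dtype=float)
    spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
    order = np.argsort(wavenumbers)
    wavenumbers, spectra = wavenumbers[order], spectra[:, order]
    tg = np.asarray(target_grid, dtype=float)
    if tg.min() < wavenumbers.min() - 1e-9 or tg.max() > wavenumbers.max() + 1e-9:
        raise SpectralDataError("target grid extends beyond the source grid")
    return np.vstack([np.interp(tg, wavenumbers, row) for row in spectra])
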