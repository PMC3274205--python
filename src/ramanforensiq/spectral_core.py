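"""Core data model, file I/O and preprocessing for Raman spectra.

A :class:`Spectrum` is a single Raman trace (wavenumber axis in cm^-1,
intensity in arbitrary detector counts, provenance metadata).  A
:class:`SpectralDataset` holds many spectra aligned on one shared axis
together with their class / donor / spot labels; it is the exchange object
between the generator, the signature model and the classifiers.

Preprocessing covers cosmic-ray despiking, resampling onto a common grid,
vector / area normalization, per-sample (donor) averaging and per-class
difference spectra.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WORKING_GRID",
    "FLUIDS",
    "Spectrum",
    "SpectralDataset",
    "FitQuality",
    "read_spectrum",
    "write_spectrum",
    "load_dataset",
    "despike",
    "resample_to_grid",
    "normalize",
    "average_per_sample",
    "difference_spectra",
]

#: Wavenumber grid used throughout: 300-1800 cm^-1 in 2 cm^-1 steps
#: (751 points).  Every component band of the three fluids falls inside it
#: (smallest band 323 cm^-1, largest 1744 cm^-1).
WORKING_GRID: np.ndarray = np.arange(300.0, 1802.0, 2.0)

#: Canonical class labels, in the fixed tie-break order used everywhere.
FLUIDS: tuple[str, ...] = ("blood", "saliva", "semen")

_VALID_LABELS = set(FLUIDS) | {"unknown"}


@dataclass(frozen=True)
class Spectrum:
    """One Raman trace on a strictly increasing wavenumber axis."""

    wavenumbers: np.ndarray
    intensities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if w.ndim != 1 or y.ndim != 1:
            raise ValueError("wavenumbers and intensities must be 1-D")
        if w.size != y.size:
            raise ValueError(
                f"axis length {w.size} != intensity length {y.size}"
            )
        if w.size < 2:
            raise ValueError("a spectrum needs at least 2 points")
        if np.any(np.diff(w) <= 0):
            raise ValueError("wavenumber axis must be strictly increasing")
        object.__setattr__(self, "wavenumbers", w)
        object.__setattr__(self, "intensities", y)

    def __len__(self) -> int:
        return int(self.wavenumbers.size)

    def with_intensities(self, y: np.ndarray) -> "Spectrum":
        return replace(self, intensities=np.asarray(y, dtype=float))


@dataclass(frozen=True)
class FitQuality:
    """Goodness-of-fit of a linear model to one spectrum.

    ``r_square`` is 1 - SSE / (total sum of squares about the mean); it can
    go negative for fits worse than the mean and is deliberately not
    clipped.  ``rmse = sqrt(sse / n_points)`` exactly.
    """

    sse: float
    r_square: float
    rmse: float

    @classmethod
    def from_residual(cls, y: np.ndarray, residual: np.ndarray) -> "FitQuality":
        y = np.asarray(y, dtype=float)
        residual = np.asarray(residual, dtype=float)
        sse = float(np.sum(residual**2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - sse / ss_tot if ss_tot > 0 else (1.0 if sse == 0 else -np.inf)
        return cls(sse=sse, r_square=r2, rmse=float(np.sqrt(sse / y.size)))


class SpectralDataset:
    """Spectrum matrix on one shared axis plus fluid / donor / spot labels."""

    def __init__(
        self,
        wavenumbers: np.ndarray,
        matrix: np.ndarray,
        labels: Sequence[str],
        donors: Sequence[str] | None = None,
        spots: Sequence[str] | None = None,
    ) -> None:
        self.wavenumbers = np.asarray(wavenumbers, dtype=float)
        self.matrix = np.asarray(matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (n_spectra x n_points)")
        n = self.matrix.shape[0]
        if self.matrix.shape[1] != self.wavenumbers.size:
            raise ValueError("matrix columns must match axis length")
        labels = list(labels)
        if len(labels) != n:
            raise ValueError(f"{len(labels)} labels for {n} spectra")
        bad = set(labels) - _VALID_LABELS
        if bad:
            raise ValueError(
                f"unknown fluid label(s) {sorted(bad)}; "
                f"allowed: {sorted(_VALID_LABELS)}"
            )
        self.labels = np.asarray(labels, dtype=object)
        self.donors = np.asarray(
            list(donors) if donors is not None else [""] * n, dtype=object
        )
        self.spots = np.asarray(
            list(spots) if spots is not None else [str(i) for i in range(n)],
            dtype=object,
        )
        if self.donors.size != n or self.spots.size != n:
            raise ValueError("donors and spots must have one entry per row")

    @property
    def n_spectra(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_points(self) -> int:
        return self.matrix.shape[1]

    @property
    def classes(self) -> list[str]:
        """Distinct fluid labels present, in canonical order."""
        present = set(self.labels)
        ordered = [f for f in FLUIDS if f in present]
        ordered += sorted(present - set(FLUIDS))
        return ordered

    def spectrum(self, i: int) -> Spectrum:
        return Spectrum(
            self.wavenumbers,
            self.matrix[i],
            meta={
                "fluid_label": self.labels[i],
                "donor_id": self.donors[i],
                "spot_id": self.spots[i],
            },
        )

    def subset(self, idx: Iterable[int] | np.ndarray) -> "SpectralDataset":
        idx = np.asarray(list(idx) if not isinstance(idx, np.ndarray) else idx)
        return SpectralDataset(
            self.wavenumbers,
            self.matrix[idx],
            self.labels[idx],
            self.donors[idx],
            self.spots[idx],
        )

    def select(self, fluid: str) -> "SpectralDataset":
        return self.subset(np.flatnonzero(self.labels == fluid))

    def copy(self) -> "SpectralDataset":
        return SpectralDataset(
            self.wavenumbers.copy(),
            self.matrix.copy(),
            self.labels.copy(),
            self.donors.copy(),
            self.spots.copy(),
        )

    def map_rows(self, fn) -> "SpectralDataset":
        """Apply a Spectrum -> Spectrum function to every row."""
        rows = [fn(self.spectrum(i)).intensities for i in range(self.n_spectra)]
        return SpectralDataset(
            self.wavenumbers, np.vstack(rows), self.labels, self.donors, self.spots
        )


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_spectrum(path: str | os.PathLike, meta: Mapping | None = None) -> Spectrum:
    """Read a two-column CSV (wavenumber, intensity) into a Spectrum.

    Lines starting with ``#`` are comments.  A descending axis is reversed
    (intensities co-reversed) so the returned axis is always ascending.
    """
    rows: list[tuple[float, float]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            parts = [p for p in text.replace(",", " ").split() if p]
            try:
                w, y = float(parts[0]), float(parts[1])
            except (ValueError, IndexError) as exc:
                raise ValueError(
                    f"{path}: non-numeric row at line {lineno}: {text!r}"
                ) from exc
            rows.append((w, y))
    if len(rows) < 2:
        raise ValueError(f"{path}: need at least 2 data rows, got {len(rows)}")
    arr = np.asarray(rows, dtype=float)
    if arr[0, 0] > arr[-1, 0]:
        arr = arr[::-1]
    m = dict(meta) if meta else {}
    m.setdefault("source_file", str(path))
    m.setdefault("fluid_label", "unknown")
    return Spectrum(arr[:, 0], arr[:, 1], meta=m)


def write_spectrum(s: Spectrum, path: str | os.PathLike) -> None:
    """Write a spectrum as two-column CSV, 6-decimal precision."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# wavenumber_cm-1,intensity_counts\n")
        for w, y in zip(s.wavenumbers, s.intensities):
            fh.write(f"{w:.6f},{y:.6f}\n")


def load_dataset(manifest: str | os.PathLike) -> SpectralDataset:
    """Load spectra listed in a manifest CSV (columns file,fluid,donor,spot).

    Relative file paths resolve against the manifest's directory.  All
    spectra are interpolated onto the intersection of their axes (the axis
    of the first file, cropped to the common support).
    """
    table = pd.read_csv(manifest, comment="#")
    required = {"file", "fluid", "donor", "spot"}
    missing_cols = required - set(table.columns)
    if missing_cols:
        raise ValueError(f"manifest missing column(s): {sorted(missing_cols)}")
    base = os.path.dirname(os.fspath(manifest))
    paths = [
        p if os.path.isabs(p) else os.path.join(base, p) for p in table["file"]
    ]
    absent = [
        f"row {i}: {p}" for i, p in enumerate(paths) if not os.path.exists(p)
    ]
    if absent:
        raise FileNotFoundError(
            "manifest references missing file(s): " + "; ".join(absent)
        )
    bad = sorted(set(table["fluid"].astype(str)) - _VALID_LABELS)
    if bad:
        raise ValueError(
            f"manifest contains unknown fluid token(s) {bad}; "
            f"allowed: {sorted(_VALID_LABELS)}"
        )
    spectra = [read_spectrum(p) for p in paths]
    lo = max(s.wavenumbers[0] for s in spectra)
    hi = min(s.wavenumbers[-1] for s in spectra)
    if lo > hi:
        raise ValueError("spectra have empty wavenumber-axis intersection")
    ref = spectra[0].wavenumbers
    grid = ref[(ref >= lo) & (ref <= hi)]
    if grid.size < 2:
        raise ValueError("axis intersection too small (< 2 points)")
    rows = [resample_to_grid(s, grid).intensities for s in spectra]
    return SpectralDataset(
        grid,
        np.vstack(rows),
        table["fluid"].astype(str).tolist(),
        table["donor"].astype(str).tolist(),
        table["spot"].astype(str).tolist(),
    )


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def despike(s: Spectrum, window: int = 11, z_thresh: float = 8.0) -> Spectrum:
    """Remove cosmic-ray spikes by a rolling modified-z test on first differences.

    A point is flagged when the modified z-score (0.6745 * |dev| / MAD) of
    its first difference, computed within the centred rolling window,
    exceeds ``z_thresh``; flagged points are replaced by the window median
    of the intensities.  Genuine Raman bands (widths of several channels)
    produce smooth differences and survive; one- or two-channel spikes do
    not.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    y = s.intensities
    n = y.size
    if window >= n:
        raise ValueError(f"window {window} must be smaller than spectrum length {n}")
    # First differences, padded so diff[i] pairs with point i.
    d = np.empty(n)
    d[1:] = np.diff(y)
    d[0] = d[1]
    half = window // 2
    flagged = np.zeros(n, dtype=bool)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        win = d[lo:hi]
        med = np.median(win)
        mad = np.median(np.abs(win - med))
        dev = abs(d[i] - med)
        if mad > 0:
            z = 0.6745 * dev / mad
        else:
            z = np.inf if dev > 0 else 0.0
        if z > z_thresh:
            flagged[i] = True
    if not flagged.any():
        return s
    out = y.copy()
    for i in np.flatnonzero(flagged):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        keep = ~flagged[lo:hi]
        vals = y[lo:hi][keep] if keep.any() else y[lo:hi]
        out[i] = np.median(vals)
    return s.with_intensities(out)


def resample_to_grid(s: Spectrum, grid: np.ndarray) -> Spectrum:
    """Linearly interpolate a spectrum onto ``grid`` (no extrapolation)."""
    grid = np.asarray(grid, dtype=float)
    if grid[0] < s.wavenumbers[0] or grid[-1] > s.wavenumbers[-1]:
        raise ValueError(
            f"target grid [{grid[0]}, {grid[-1]}] outside spectrum support "
            f"[{s.wavenumbers[0]}, {s.wavenumbers[-1]}]"
        )
    y = np.interp(grid, s.wavenumbers, s.intensities)
    return Spectrum(grid, y, meta=dict(s.meta))


def normalize(s: Spectrum, mode: str = "vector") -> Spectrum:
    """Scale a spectrum to unit Euclidean norm or unit trapezoidal area."""
    y = s.intensities
    if not np.any(y):
        raise ValueError("cannot normalize an all-zero spectrum")
    if mode == "vector":
        scale = np.linalg.norm(y)
    elif mode == "area":
        scale = np.trapezoid(y, s.wavenumbers)
        if scale == 0:
            raise ValueError("zero-area spectrum cannot be area-normalized")
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return s.with_intensities(y / scale)


def normalize_dataset(d: SpectralDataset, mode: str = "vector") -> SpectralDataset:
    """Row-wise :func:`normalize` over a whole dataset."""
    return d.map_rows(lambda s: normalize(s, mode))


def average_per_sample(d: SpectralDataset) -> SpectralDataset:
    """Average the spot spectra of each (fluid, donor) sample.

    Returns one row per sample: the pointwise mean over that donor's spots,
    with the fluid and donor labels preserved.  This is the averaging step
    that turns per-spot heterogeneity of a dry trace into one stable
    per-sample spectrum.
    """
    keys: list[tuple[str, str]] = []
    seen = set()
    for f, dn in zip(d.labels, d.donors):
        if (f, dn) not in seen:
            seen.add((f, dn))
            keys.append((f, dn))
    rows, labels, donors = [], [], []
    for f, dn in keys:
        mask = (d.labels == f) & (d.donors == dn)
        rows.append(d.matrix[mask].mean(axis=0))
        labels.append(f)
        donors.append(dn)
    return SpectralDataset(
        d.wavenumbers,
        np.vstack(rows),
        labels,
        donors,
        spots=["mean"] * len(rows),
    )


def difference_spectra(
    d: SpectralDataset,
) -> tuple[Spectrum, dict[str, Spectrum]]:
    """Grand-mean spectrum and per-class (class mean - grand mean) traces.

    The grand mean is the row mean over all spectra, so the per-class
    differences weighted by class sizes sum to zero.
    """
    classes = d.classes
    if len(classes) < 2:
        raise ValueError("difference spectra need at least 2 classes")
    grand = d.matrix.mean(axis=0)
    grand_s = Spectrum(d.wavenumbers, grand, meta={"fluid_label": "unknown"})
    diffs = {}
    for c in classes:
        cm = d.matrix[d.labels == c].mean(axis=0)
        diffs[c] = Spectrum(d.wavenumbers, cm - grand, meta={"fluid_label": c})
    return grand_s, diffs
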