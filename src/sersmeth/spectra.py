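"""Spectrum container, text I/O, and the preprocessing chain.

A :class:`Spectrum` is a wavenumber grid (cm^-1, strictly increasing) with
matched intensities (arbitrary units) and free-form metadata.  Preprocessing
follows the conventional Raman order — Savitzky-Golay smoothing, asymmetric
least squares (AsLS) baseline subtraction, normalization — each step
individually switchable.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.signal import savgol_filter
from scipy.sparse.linalg import spsolve

from .errors import ConfigError, SpectrumFormatError

__all__ = [
    "Spectrum",
    "PreprocessConfig",
    "read_spectrum",
    "write_spectrum",
    "read_bundle",
    "write_bundle",
    "resample",
    "preprocess",
    "asls_baseline",
    "default_grid",
]

MIN_POINTS = 16


@dataclass(frozen=True)
class Spectrum:
    """A single spectrum: wavenumbers (cm^-1) and intensities (a.u.)."""

    wavenumbers: np.ndarray
    intensities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "wavenumbers", w)
        object.__setattr__(self, "intensities", y)
        if w.ndim != 1 or y.ndim != 1 or w.shape != y.shape:
            raise SpectrumFormatError("wavenumbers/intensities must be equal-length 1-D")
        if w.size < MIN_POINTS:
            raise SpectrumFormatError(f"spectrum needs >= {MIN_POINTS} points, got {w.size}")
        if not np.all(np.diff(w) > 0):
            raise SpectrumFormatError("wavenumber grid must be strictly increasing")
        if not np.all(np.isfinite(y)):
            raise SpectrumFormatError("non-finite intensity values")

    def __len__(self) -> int:
        return self.wavenumbers.size

    def with_intensities(self, y: np.ndarray, **meta_updates) -> "Spectrum":
        return Spectrum(self.wavenumbers, y, {**self.meta, **meta_updates})


def default_grid(start: float = 600.0, stop: float = 1700.0, step: float = 1.0) -> np.ndarray:
    """Analysis grid covering all assigned bands (644-1636 cm^-1)."""
    return np.arange(start, stop + 0.5 * step, step)


# ---------------------------------------------------------------- file I/O

def _parse_meta_line(line: str, meta: dict) -> None:
    body = line.lstrip("#").strip()
    if "=" in body:
        key, _, value = body.partition("=")
        meta[key.strip()] = value.strip()


def read_spectrum(path_or_handle) -> Spectrum:
    """Read a two-column delimited text spectrum.

    Comment lines start with ``#``; ``#key=value`` lines populate ``meta``.
    Comma or whitespace delimited; an optional non-numeric header row is
    skipped.
    """
    if hasattr(path_or_handle, "read"):
        lines = path_or_handle.read().splitlines()
        name = getattr(path_or_handle, "name", "<stream>")
    else:
        name = str(path_or_handle)
        lines = Path(path_or_handle).read_text().splitlines()

    meta: dict = {}
    w, y = [], []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            _parse_meta_line(line, meta)
            continue
        parts = line.replace(",", " ").split()
        if len(parts) < 2:
            raise SpectrumFormatError(f"{name}:{lineno}: expected two columns")
        try:
            w.append(float(parts[0]))
            y.append(float(parts[1]))
        except ValueError:
            if not w:  # tolerate a header row before any data
                continue
            raise SpectrumFormatError(
                f"{name}:{lineno}: non-numeric row {parts[:2]!r}"
            ) from None
    return Spectrum(np.array(w), np.array(y), meta)


def write_spectrum(spectrum: Spectrum, path) -> None:
    """Write a spectrum as two-column text with ``#key=value`` meta lines."""
    with open(path, "w") as fh:
        for key, value in spectrum.meta.items():
            fh.write(f"#{key}={value}\n")
        for w, y in zip(spectrum.wavenumbers, spectrum.intensities):
            fh.write(f"{w:.6f},{y:.12e}\n")


def write_bundle(spectra: dict[str, Spectrum], path) -> None:
    """Write spectra sharing a grid as a wide table (wavenumber + one
    column per spectrum, header row of ids)."""
    ids = list(spectra)
    grid = spectra[ids[0]].wavenumbers
    for sid in ids[1:]:
        if not np.array_equal(spectra[sid].wavenumbers, grid):
            raise SpectrumFormatError("bundle spectra must share one grid")
    df = pd.DataFrame(
        {"wavenumber": grid, **{sid: spectra[sid].intensities for sid in ids}}
    )
    df.to_csv(path, index=False)


def read_bundle(path) -> dict[str, Spectrum]:
    df = pd.read_csv(path)
    if df.columns[0] != "wavenumber":
        raise SpectrumFormatError("bundle must start with a 'wavenumber' column")
    grid = df["wavenumber"].to_numpy(float)
    return {
        sid: Spectrum(grid, df[sid].to_numpy(float), {"sample": sid})
        for sid in df.columns[1:]
    }


# --------------------------------------------------------------- resample

def resample(spectrum: Spectrum, grid: np.ndarray) -> Spectrum:
    """Linear interpolation onto ``grid``; exact at shared grid points."""
    grid = np.asarray(grid, dtype=float)
    w = spectrum.wavenumbers
    if grid[0] < w[0] or grid[-1] > w[-1]:
        raise SpectrumFormatError(
            f"target grid [{grid[0]}, {grid[-1]}] extends beyond source "
            f"range [{w[0]}, {w[-1]}]; extrapolation not supported"
        )
    y = np.interp(grid, w, spectrum.intensities)
    return Spectrum(grid, y, dict(spectrum.meta))


# ------------------------------------------------------------- preprocess

@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the smoothing/baseline/normalization chain.

    The acquisition protocol names the three steps but not their methods or
    parameters, so every choice here is configurable.  Defaults: SG window
    11 points order 3 (standard for ~1 cm^-1 Raman grids), AsLS lambda 1e10 /
    p 0.01 / 10 iterations, max-normalization.  The stiff default lambda is
    deliberate: on a 1100 cm^-1 window of ~12 cm^-1-wide bands a softer
    baseline creeps into the Lorentzian tail pedestal and eats real signal
    (measurable as band-prominence loss on noiseless baseline-free
    spectra), while low-order drifts — which the second-difference penalty
    barely constrains — are still captured essentially exactly.
    """

    smooth: bool = True
    window_length: int = 11
    polyorder: int = 3
    baseline: bool = True
    lam: float = 1e10
    p: float = 0.01
    niter: int = 10
    normalize: bool = True
    norm_mode: str = "max"  # "max" or "area"

    def __post_init__(self) -> None:
        if self.smooth:
            if self.window_length % 2 == 0:
                raise ConfigError("smoothing window must be odd-sized")
            if self.polyorder >= self.window_length:
                raise ConfigError("polyorder must be < window_length")
        if self.norm_mode not in ("max", "area"):
            raise ConfigError(f"unknown norm_mode {self.norm_mode!r}")


def asls_baseline(
    y: np.ndarray, lam: float = 1e10, p: float = 0.01, niter: int = 10
) -> np.ndarray:
    """Asymmetric least squares baseline (Whittaker smoother with
    asymmetric weights: points above the running baseline are down-weighted
    by ``p``, points below by ``1-p``)."""
    y = np.asarray(y, dtype=float)
    n = y.size
    d = sparse.diags([1.0, -2.0, 1.0], [0, -1, -2], shape=(n, n - 2))
    dtd = lam * (d @ d.T)
    w = np.ones(n)
    z = y
    for _ in range(niter):
        W = sparse.spdiags(w, 0, n, n)
        z = spsolve((W + dtd).tocsc(), w * y)
        w = np.where(y > z, p, 1.0 - p)
    return z


def _normalize(y: np.ndarray, grid: np.ndarray, mode: str) -> np.ndarray:
    if mode == "max":
        peak = np.max(y)
        if peak <= 0:
            raise SpectrumFormatError("cannot max-normalize a non-positive spectrum")
        return y / peak
    area = np.trapezoid(np.abs(y), grid)
    if area <= 0:
        raise SpectrumFormatError("cannot area-normalize a zero spectrum")
    return y / area


def preprocess(spectrum: Spectrum, config: PreprocessConfig | None = None) -> Spectrum:
    """Apply smoothing, baseline subtraction, and normalization in order.

    The wavenumber grid is never altered; ``meta['preprocessing']`` records
    the steps applied.
    """
    config = config or PreprocessConfig()
    y = spectrum.intensities
    steps = []
    if config.smooth:
        if config.window_length > len(spectrum):
            raise ConfigError("smoothing window larger than spectrum")
        y = savgol_filter(y, config.window_length, config.polyorder)
        steps.append(f"savgol(w={config.window_length},o={config.polyorder})")
    if config.baseline:
        y = y - asls_baseline(y, config.lam, config.p, config.niter)
        steps.append(f"asls(lam={config.lam:g},p={config.p:g})")
    if config.normalize:
        y = _normalize(y, spectrum.wavenumbers, config.norm_mode)
        steps.append(f"norm({config.norm_mode})")
    return spectrum.with_intensities(y, preprocessing=";".join(steps) or "none")
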