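"""Synthetic Raman spectrum generator for dry body-fluid traces.

Each fluid class (blood, saliva, semen) is modelled as a non-negative
mixture of 2-3 chemical component spectra built from the band positions
reported for the resolved components of each fluid: tyrosine-, serum-
protein- and spermine-phosphate-like components for semen; hemoglobin- and
fibrin-like components for blood; mucin/protein-, acetate/carbohydrate- and
arginine-like components for saliva.  Component bands are Lorentzian lines
(positions are well established; linewidths are set to a typical
solid-phase value).  On top of the chemical signal each simulated spot
carries a fluorescence baseline (constant plus tilted line) and additive
Gaussian detector noise.

Heterogeneity is modelled at two levels, mirroring how dry traces behave:
a per-sample (donor) abundance vector drawn from a Dirichlet, and a
per-spot multiplicative lognormal jitter around it, since spectra taken at
different spots of the same dry trace differ.  Saliva gets twice the
spot-level jitter of blood and semen, reflecting its higher spot-to-spot
variability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .spectral_core import FLUIDS, WORKING_GRID, SpectralDataset, Spectrum

__all__ = [
    "PeakSpec",
    "ComponentSpec",
    "SimulationConfig",
    "PEAK_TABLE",
    "make_component",
    "component_library",
    "simulate_spot",
    "simulate_dataset",
    "inject_corruption",
    "default_config",
    "campaign_spot_lists",
]


@dataclass(frozen=True)
class PeakSpec:
    """One Lorentzian band: center (cm^-1), FWHM (cm^-1), relative height."""

    center: float
    fwhm: float = 12.0
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.fwhm <= 0 or self.amplitude <= 0:
            raise ValueError("fwhm and amplitude must be positive")


@dataclass(frozen=True)
class ComponentSpec:
    """A named chemical component of one fluid: a list of bands."""

    name: str
    fluid: str
    peaks: tuple[PeakSpec, ...]

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError("a component needs at least one peak")


#: Band positions (cm^-1) of the chemical components of each fluid.
PEAK_TABLE: dict[str, dict[str, tuple[float, ...]]] = {
    "semen": {
        "tyrosine_like": (641, 798, 829, 848, 983, 1179, 1200, 1213, 1265, 1327, 1616),
        "protein_like": (715, 759, 1003, 1240, 1336, 1448, 1668),
        "sph_like": (888, 958, 1011, 1055, 1065, 1125, 1317, 1461, 1494),
    },
    "blood": {
        "hemoglobin_like": (1000, 1368, 1542, 1620),
        "fibrin_like": (967, 1248, 1342),
    },
    "saliva": {
        "mucin_protein_like": (1002, 1444, 1653),
        "acetate_carbohydrate_like": (323, 521, 632, 1295, 1434, 1744),
        "arginine_like": (544, 919, 991),
    },
}

#: Seed that freezes the library's randomly drawn band amplitudes.
LIBRARY_SEED = 20100329

#: Relative overall Raman intensity of each fluid's dry trace (blood is
#: the strongest scatterer of the three, saliva the weakest).
FLUID_TOTAL_INTENSITY = {"blood": 1.2, "saliva": 0.8, "semen": 1.0}

_DEFAULT_FWHM = 12.0


@dataclass
class SimulationConfig:
    """Study-condition parameters of the simulated acquisition campaign.

    Defaults correspond to the default synthetic dataset used throughout:
    17 samples per fluid, 10 mapped spots per sample, peak signal-to-noise
    25, moderate fluorescence background, seed 42.  ``spots_per_sample``
    may be a fixed int, an inclusive (lo, hi) range sampled per donor, or a
    per-fluid mapping to explicit per-sample spot lists (to hit exact
    spectrum totals).
    """

    n_samples_per_fluid: int | dict[str, int] = 17
    spots_per_sample: int | tuple[int, int] | dict[str, Sequence[int]] = 10
    peak_snr: float = 25.0
    donor_variability: float = 50.0
    baseline_strength: float = 0.3
    fwhm: float = _DEFAULT_FWHM
    seed: int = 42

    def __post_init__(self) -> None:
        if self.peak_snr <= 0 or self.donor_variability <= 0:
            raise ValueError("peak_snr and donor_variability must be positive")
        if self.baseline_strength < 0:
            raise ValueError("baseline_strength must be >= 0")
        if isinstance(self.spots_per_sample, tuple):
            lo, hi = self.spots_per_sample
            if not (1 <= lo <= hi <= 100):
                raise ValueError("spots range must lie within [1, 100]")

    def n_samples(self, fluid: str) -> int:
        if isinstance(self.n_samples_per_fluid, dict):
            return int(self.n_samples_per_fluid[fluid])
        return int(self.n_samples_per_fluid)


def default_config(seed: int = 42, **overrides) -> SimulationConfig:
    """The default synthetic study: 17 donors/fluid, 10 spots each."""
    return SimulationConfig(seed=seed, **overrides)


def campaign_spot_lists() -> dict[str, list[int]]:
    """Per-sample spot counts reproducing the 170/252/693 spectrum totals.

    Blood: 17 samples x 10 spots = 170.  Saliva: 17 samples totalling 252
    (fourteen with 15 spots, three with 14).  Semen: 50 samples totalling
    693 (forty-three with 14 spots, seven with 13).
    """
    lists = {
        "blood": [10] * 17,
        "saliva": [15] * 14 + [14] * 3,
        "semen": [14] * 43 + [13] * 7,
    }
    assert sum(lists["blood"]) == 170
    assert sum(lists["saliva"]) == 252
    assert sum(lists["semen"]) == 693
    return lists


# ---------------------------------------------------------------------------
# Component spectra
# ---------------------------------------------------------------------------

def _lorentzian(grid: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    hw = fwhm / 2.0
    return hw**2 / ((grid - center) ** 2 + hw**2)


def make_component(spec: ComponentSpec, grid: np.ndarray = WORKING_GRID) -> Spectrum:
    """Render a component as a sum of Lorentzians, max-normalized to 1."""
    grid = np.asarray(grid, dtype=float)
    y = np.zeros_like(grid)
    for p in spec.peaks:
        if not (grid[0] <= p.center <= grid[-1]):
            raise ValueError(
                f"peak at {p.center} cm^-1 outside grid "
                f"[{grid[0]}, {grid[-1]}] in component {spec.name!r}"
            )
        y += p.amplitude * _lorentzian(grid, p.center, p.fwhm)
    y /= y.max()
    return Spectrum(grid, y, meta={"fluid_label": spec.fluid, "component": spec.name})


def component_library(
    grid: np.ndarray = WORKING_GRID,
    fwhm: float = _DEFAULT_FWHM,
    library_seed: int = LIBRARY_SEED,
) -> dict[str, list[Spectrum]]:
    """The 8 chemical component spectra, keyed by fluid.

    Band amplitudes are drawn log-uniformly in [0.2, 1.0] once under a
    fixed seed and frozen, so the library is a deterministic object.  Each
    component also receives a low-amplitude admixture of the other
    components' bands (10-30 % of their height), reproducing the
    cross-mixing that alternating-least-squares resolution leaves between
    components.  Only a component's intense bands (>= 60 % of its
    strongest band) reappear elsewhere — it is the strong bands that bleed
    across resolved components — and admixed bands closer than 20 cm^-1 to
    one of the receiving component's own bands are skipped so its band
    positions stay put.
    """
    rng = np.random.default_rng(library_seed)
    # Own-band amplitudes, drawn in the deterministic PEAK_TABLE order.
    own_amps: dict[tuple[str, str], np.ndarray] = {}
    for fluid in FLUIDS:
        for name, centers in PEAK_TABLE[fluid].items():
            own_amps[(fluid, name)] = np.exp(
                rng.uniform(math.log(0.2), math.log(1.0), size=len(centers))
            )
    lib: dict[str, list[Spectrum]] = {f: [] for f in FLUIDS}
    for fluid in FLUIDS:
        for name, centers in PEAK_TABLE[fluid].items():
            peaks = [
                PeakSpec(c, fwhm, a)
                for c, a in zip(centers, own_amps[(fluid, name)])
            ]
            # Cross-mixing from every other component in the library.
            for (of, on), amps in own_amps.items():
                if (of, on) == (fluid, name):
                    continue
                mix = rng.uniform(0.1, 0.3)
                for c, a in zip(PEAK_TABLE[of][on], amps):
                    if a < 0.6 * amps.max():
                        continue  # only intense bands bleed across
                    if min(abs(c - oc) for oc in centers) < 20.0:
                        continue
                    peaks.append(PeakSpec(c, fwhm, mix * a))
            spec = ComponentSpec(name=name, fluid=fluid, peaks=tuple(peaks))
            lib[fluid].append(make_component(spec, grid))
    return lib


# ---------------------------------------------------------------------------
# Spot- and dataset-level simulation
# ---------------------------------------------------------------------------

def simulate_spot(
    fluid: str,
    sample_abundance: np.ndarray,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    *,
    components: list[Spectrum] | None = None,
    grid: np.ndarray = WORKING_GRID,
    jitter: bool = True,
    baseline: tuple[float, float] | None = None,
) -> Spectrum:
    """Simulate one mapped spot of a dry trace.

    intensity = sum_i w_i * component_i + b0 + b1 * ramp + noise, clipped
    at zero.  Spot weights ``w`` jitter multiplicatively (lognormal) around
    the sample-level abundances; the noise standard deviation is
    max(chemical signal) / peak_snr; baseline offsets b0, b1 are drawn
    uniformly in [0, baseline_strength * max(chemical signal)] unless fixed
    via ``baseline=(b0, b1)``.
    """
    grid = np.asarray(grid, dtype=float)
    if components is None:
        components = component_library(grid, fwhm=cfg.fwhm)[fluid]
    w = np.asarray(sample_abundance, dtype=float)
    if w.size != len(components):
        raise ValueError(
            f"{w.size} weights for {len(components)} {fluid} components"
        )
    if np.any(w < 0):
        raise ValueError("mixing weights must be non-negative")
    sigma_spot = 1.0 / math.sqrt(cfg.donor_variability)
    if fluid == "saliva":
        sigma_spot *= 2.0  # saliva traces vary more spot-to-spot
    if jitter:
        w = w * rng.lognormal(mean=0.0, sigma=sigma_spot, size=w.size)
    signal = np.zeros_like(grid)
    for wi, comp in zip(w, components):
        signal += wi * comp.intensities
    smax = signal.max() if signal.max() > 0 else 1.0
    ramp = (grid - grid[0]) / (grid[-1] - grid[0])
    if baseline is not None:
        b0, b1 = baseline
    else:
        b0 = rng.uniform(0.0, cfg.baseline_strength * smax)
        b1 = rng.uniform(0.0, cfg.baseline_strength * smax)
    y = signal + b0 + b1 * ramp
    if np.isfinite(cfg.peak_snr):
        y = y + rng.normal(0.0, smax / cfg.peak_snr, size=y.size)
    y = np.clip(y, 0.0, None)
    return Spectrum(grid, y, meta={"fluid_label": fluid})


def _spot_counts(cfg: SimulationConfig, fluid: str, n_samples: int,
                 rng: np.random.Generator) -> list[int]:
    sp = cfg.spots_per_sample
    if isinstance(sp, dict):
        counts = list(sp[fluid])
        if len(counts) != n_samples:
            raise ValueError(
                f"{fluid}: {len(counts)} spot counts for {n_samples} samples"
            )
        return [int(c) for c in counts]
    if isinstance(sp, tuple):
        lo, hi = sp
        return [int(rng.integers(lo, hi + 1)) for _ in range(n_samples)]
    return [int(sp)] * n_samples


def simulate_dataset(cfg: SimulationConfig, grid: np.ndarray = WORKING_GRID) -> SpectralDataset:
    """Simulate a full multi-donor, multi-spot acquisition campaign.

    Per fluid, ``n_samples`` donors; per donor a Dirichlet abundance vector
    over that fluid's components (concentration = donor_variability, so
    larger values mean donors are more alike), scaled by a per-donor total
    intensity; per donor a number of spots, each simulated independently.
    Fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    lib = component_library(grid, fwhm=cfg.fwhm)
    rows, labels, donors, spots = [], [], [], []
    for fluid in FLUIDS:
        comps = lib[fluid]
        k = len(comps)
        n_samples = cfg.n_samples(fluid)
        counts = _spot_counts(cfg, fluid, n_samples, rng)
        for s_idx in range(n_samples):
            donor = f"{fluid[:2]}{s_idx + 1:03d}"
            abundance = rng.dirichlet([cfg.donor_variability] * k)
            # mean weight ~1 per component, scaled by the fluid's overall
            # scattering strength
            abundance = abundance * k * FLUID_TOTAL_INTENSITY[fluid]
            for spot_idx in range(counts[s_idx]):
                s = simulate_spot(
                    fluid, abundance, cfg, rng, components=comps, grid=grid
                )
                rows.append(s.intensities)
                labels.append(fluid)
                donors.append(donor)
                spots.append(str(spot_idx + 1))
    return SpectralDataset(np.asarray(grid, float), np.vstack(rows), labels, donors, spots)


def inject_corruption(
    d: SpectralDataset,
    noise_factor: float = 0.0,
    background_factor: float = 0.0,
    seed: int = 0,
) -> SpectralDataset:
    """Return a corrupted copy: extra noise and a broad fluorescence hump.

    Adds Gaussian noise with standard deviation ``noise_factor`` times the
    per-spectrum maximum, plus a random broad Gaussian hump (center uniform
    on the grid, FWHM uniform in 400-800 cm^-1) scaled by
    ``background_factor`` times the per-spectrum maximum.  The input
    dataset is left untouched.
    """
    if not (np.isfinite(noise_factor) and np.isfinite(background_factor)):
        raise ValueError("corruption factors must be finite")
    if noise_factor < 0 or background_factor < 0:
        raise ValueError("corruption factors must be >= 0")
    out = d.copy()
    if noise_factor == 0 and background_factor == 0:
        return out
    rng = np.random.default_rng(seed)
    grid = out.wavenumbers
    for i in range(out.n_spectra):
        y = out.matrix[i]
        ymax = y.max() if y.max() > 0 else 1.0
        if background_factor > 0:
            center = rng.uniform(grid[0], grid[-1])
            fwhm = rng.uniform(400.0, 800.0)
            sig = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
            hump = np.exp(-0.5 * ((grid - center) / sig) ** 2)
            y = y + background_factor * ymax * hump
        if noise_factor > 0:
            y = y + rng.normal(0.0, noise_factor * ymax, size=y.size)
        out.matrix[i] = y
    return out
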