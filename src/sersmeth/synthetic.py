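"""Synthetic SERS generator: reference dsCG/dsAT spectra, PCR-product
spectra at given CG fractions, the 3-gene x 7-level verification design,
and simulated clinical cohorts.

The generator stands in for the Raman instrument so the whole pipeline is
testable offline.  Its signal model is a sum of Lorentzian bands at the
assigned dsCG/dsAT wavenumbers; band intensities are linear in duplex
composition, so the noiseless spectrum of a PCR product with CG base-pair
fraction ``f`` is ``f * S_CG + (1 - f) * S_AT``.  On top of the signal it
adds the dominant SERS variability modes with few parameters: a low-order
polynomial baseline (fluorescence/substrate background), a per-spectrum
lognormal intensity scale (substrate batch, focus), and additive white
Gaussian noise (shot/CCD noise).

Every stochastic operation is a pure function of (inputs, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .calibration import GeneCalibration, cg_fraction_at_level
from .errors import ConfigError
from .spectra import Spectrum, default_grid

__all__ = [
    "PeakSpec",
    "SimulationConfig",
    "CohortConfig",
    "GroupMixture",
    "DEFAULT_PEAKS",
    "make_reference_spectrum",
    "make_product_spectrum",
    "simulate_verification_set",
    "simulate_cohort",
    "VERIFICATION_LEVELS",
]

#: Methylation levels of the seven reference DNA mixtures.
VERIFICATION_LEVELS = (0.0, 0.01, 0.05, 0.25, 0.50, 0.75, 1.00)


@dataclass(frozen=True)
class PeakSpec:
    """One Raman band: centre and FWHM in cm^-1, plus its response per
    unit CG fraction and per unit AT fraction.  A band belongs to dsCG
    only iff ``amplitude_at == 0``, and vice versa."""

    center: float
    width: float
    amplitude_cg: float
    amplitude_at: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ConfigError(f"peak {self.center}: width must be > 0")
        if self.amplitude_cg < 0 or self.amplitude_at < 0:
            raise ConfigError(f"peak {self.center}: amplitudes must be >= 0")


def _default_peaks() -> tuple[PeakSpec, ...]:
    # Band table of dsCG/dsAT duplexes: (centre, CG amplitude, AT amplitude).
    # CG-only: 644, 1354, 1550; AT-only: 684, 734, 1336, 1575; the rest are
    # shared (incl. 1024 and 1098, treated as shared backbone/phosphate
    # modes).  Heights are plausible relative intensities, not measured
    # values; they cancel in reference-based deconvolution.
    fwhm = 12.0
    table = [
        (644.0, 0.45, 0.0),
        (684.0, 0.0, 0.35),
        (734.0, 0.0, 0.85),
        (788.0, 1.00, 0.55),
        (1024.0, 0.40, 0.30),
        (1098.0, 0.45, 0.60),
        (1188.0, 0.35, 0.30),
        (1240.0, 0.50, 0.45),
        (1270.0, 0.55, 0.40),
        (1336.0, 0.0, 0.90),
        (1354.0, 0.75, 0.0),
        (1378.0, 0.45, 0.70),
        (1484.0, 0.65, 0.60),
        (1550.0, 0.70, 0.0),
        (1575.0, 0.0, 0.75),
        (1636.0, 0.30, 0.25),
    ]
    return tuple(
        PeakSpec(center=c, width=fwhm, amplitude_cg=cg, amplitude_at=at)
        for c, cg, at in table
    )


DEFAULT_PEAKS: tuple[PeakSpec, ...] = _default_peaks()


@dataclass(frozen=True)
class SimulationConfig:
    """Instrument stand-in parameters.

    noise_sd and baseline_amplitude are relative to the maximum noiseless
    peak intensity; intensity_scale_sd is the sigma of a lognormal
    multiplicative factor (median 1).
    """

    grid_start: float = 600.0
    grid_stop: float = 1700.0
    grid_step: float = 1.0
    peaks: tuple[PeakSpec, ...] = DEFAULT_PEAKS
    noise_sd: float = 0.01
    baseline_amplitude: float = 0.05
    intensity_scale_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ConfigError("peak table must not be empty")
        for name in ("noise_sd", "baseline_amplitude", "intensity_scale_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")

    def grid(self) -> np.ndarray:
        return default_grid(self.grid_start, self.grid_stop, self.grid_step)

    def noiseless(self) -> "SimulationConfig":
        return replace(
            self, noise_sd=0.0, baseline_amplitude=0.0, intensity_scale_sd=0.0
        )


def _lorentzian(grid: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    hwhm = fwhm / 2.0
    return hwhm**2 / ((grid - center) ** 2 + hwhm**2)


def _clean_signal(grid: np.ndarray, peaks, kind: str) -> np.ndarray:
    y = np.zeros_like(grid)
    for pk in peaks:
        amp = pk.amplitude_cg if kind == "CG" else pk.amplitude_at
        if amp > 0:
            y += amp * _lorentzian(grid, pk.center, pk.width)
    return y


def _max_peak(config: SimulationConfig) -> float:
    grid = config.grid()
    return max(
        np.max(_clean_signal(grid, config.peaks, "CG")),
        np.max(_clean_signal(grid, config.peaks, "AT")),
    )


def _corrupt(
    y: np.ndarray, grid: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Apply multiplicative scale, baseline, and additive noise."""
    ref = _max_peak(config)
    if config.intensity_scale_sd > 0:
        y = y * rng.lognormal(mean=0.0, sigma=config.intensity_scale_sd)
    if config.baseline_amplitude > 0:
        u = (grid - grid[0]) / (grid[-1] - grid[0])
        coeffs = rng.uniform(-1.0, 1.0, size=3)
        poly = coeffs[0] + coeffs[1] * u + coeffs[2] * u**2
        poly -= poly.min()  # fluorescence background is non-negative
        y = y + config.baseline_amplitude * ref * poly
    if config.noise_sd > 0:
        y = y + rng.normal(0.0, config.noise_sd * ref, size=y.size)
    return y


def make_reference_spectrum(
    kind: str, config: SimulationConfig, rng: np.random.Generator | None = None
) -> Spectrum:
    """Simulated SERS spectrum of a pure dsCG or dsAT duplex."""
    if kind not in ("CG", "AT"):
        raise ConfigError(f"kind must be 'CG' or 'AT', got {kind!r}")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    grid = config.grid()
    y = _corrupt(_clean_signal(grid, config.peaks, kind), grid, config, rng)
    return Spectrum(grid, y, {"kind": kind, "seed": config.seed})


def make_product_spectrum(
    f_cg: float,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> Spectrum:
    """Simulated spectrum of a PCR product with CG base-pair fraction
    ``f_cg``: peak-model composition ``f*S_CG + (1-f)*S_AT`` plus the
    configured corruption."""
    if not (0.0 <= f_cg <= 1.0):
        raise ConfigError(f"f_cg={f_cg} outside [0, 1]")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    grid = config.grid()
    clean = f_cg * _clean_signal(grid, config.peaks, "CG") + (
        1.0 - f_cg
    ) * _clean_signal(grid, config.peaks, "AT")
    y = _corrupt(clean, grid, config, rng)
    return Spectrum(grid, y, {"f_cg": f_cg, "seed": config.seed})


def simulate_verification_set(
    calibs: dict[str, GeneCalibration],
    config: SimulationConfig,
    levels: tuple[float, ...] = VERIFICATION_LEVELS,
    reps: int = 3,
) -> list[Spectrum]:
    """Generate the verification design: one spectrum per gene x
    methylation level x replicate, at the CG fraction the calibration maps
    that level to.  Default: 3 genes x 7 levels x 3 reps = 63 spectra."""
    if reps < 1:
        raise ConfigError("reps must be >= 1")
    rng = np.random.default_rng(config.seed)
    out = []
    for gene, calib in calibs.items():
        for m in levels:
            f = cg_fraction_at_level(calib, m)
            for rep in range(1, reps + 1):
                sp = make_product_spectrum(f, config, rng)
                sp.meta.update(gene=gene, true_m=m, rep=rep)
                out.append(sp)
    return out


# -------------------------------------------------------------- cohorts

@dataclass(frozen=True)
class GroupMixture:
    """Zero-inflated methylation-level distribution of one gene in one
    group: with probability ``p_methylated`` the true level is drawn from a
    normal(level_mean, level_sd) truncated to [0.05, 1]; otherwise it is a
    near-zero background normal(bg_mean, bg_sd) truncated below 0.05
    (negative values allowed, mirroring unclipped estimates)."""

    p_methylated: float
    level_mean: float = 0.15
    level_sd: float = 0.10
    bg_mean: float = 0.005
    bg_sd: float = 0.015

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_methylated <= 1.0):
            raise ConfigError("p_methylated must be in [0, 1]")

    def draw(self, rng: np.random.Generator, shift: float = 0.0) -> float:
        if rng.uniform() < self.p_methylated:
            while True:
                x = rng.normal(self.level_mean + shift, self.level_sd)
                if 0.05 <= x <= 1.0:
                    return x
        while True:
            x = rng.normal(self.bg_mean, self.bg_sd)
            if x < 0.05:
                return x


def _default_categoricals() -> dict:
    # Cohort marginals of the emulated study population (48 NSCLC / 51
    # controls): gender, age band, smoking pack-years band; stage and
    # histology are cancer-only.
    return {
        "gender": {
            "cancer": {"female": 21 / 48, "male": 27 / 48},
            "control": {"female": 27 / 51, "male": 24 / 51},
        },
        "age_band": {
            "cancer": {"1-40": 6 / 48, "41-60": 7 / 48, "61-100": 35 / 48},
            "control": {"1-40": 6 / 51, "41-60": 10 / 51, "61-100": 35 / 51},
        },
        "pack_years_band": {
            "cancer": {"0": 13 / 48, "1-20": 13 / 48, "21-100": 22 / 48},
            "control": {"0": 22 / 51, "1-20": 10 / 51, "21-100": 19 / 51},
        },
        "stage_band": {
            "cancer": {"I-II": 15 / 48, "III-IV": 33 / 48},
            "control": {"NA": 1.0},
        },
        "histology": {
            "cancer": {"adeno": 18 / 48, "large_cell": 6 / 48, "squamous": 24 / 48},
            "control": {"NA": 1.0},
        },
    }


def _default_mixtures() -> dict:
    # Per-gene methylation probability ~0.50 in cancer and ~0.04 in
    # controls gives, under independence across the three genes, any-gene
    # methylation design targets of 87.5% (cancer) and 11.8% (control) and
    # a group mean-level difference of roughly 5 percentage points.
    return {
        gene: {
            "cancer": GroupMixture(p_methylated=0.50),
            "control": GroupMixture(p_methylated=0.041),
        }
        for gene in ("p16", "MGMT", "RASSF1")
    }


@dataclass(frozen=True)
class CohortConfig:
    """Simulated clinical cohort: subject counts, per-gene level mixtures
    per group, clinical-category marginals, and association effects.

    Association effects (cancer group only) emulate the reported clinical
    correlations: p16 levels rise with pack-years smoked and with
    non-adeno histology; RASSF1 methylation is more frequent in stage
    III-IV.
    """

    n_cancer: int = 48
    n_control: int = 51
    mixtures: dict = field(default_factory=_default_mixtures)
    categoricals: dict = field(default_factory=_default_categoricals)
    p16_smoking_shift: float = 0.05   # added to p16 level mean per smoking band step
    p16_histology_shift: float = 0.05  # added for squamous/large-cell vs adeno
    # Multiplies RASSF1 p_methylated in stage III-IV; stage I-II is
    # compensated downward so the gene's cancer-group marginal (and hence
    # the any-gene design target) is unchanged.
    rassf1_stage_odds: float = 1.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cancer < 0 or self.n_control < 0:
            raise ConfigError("subject counts must be >= 0")
        for feature, by_group in self.categoricals.items():
            for group, probs in by_group.items():
                total = sum(probs.values())
                if abs(total - 1.0) > 1e-9:
                    raise ConfigError(
                        f"{feature}/{group}: probabilities sum to {total}, not 1"
                    )

    @property
    def design_target_any_gene(self) -> dict[str, float]:
        """Designed any-gene methylation fraction per group (independence
        across genes)."""
        out = {}
        for group in ("cancer", "control"):
            p_none = 1.0
            for gene in self.mixtures:
                p_none *= 1.0 - self.mixtures[gene][group].p_methylated
            out[group] = 1.0 - p_none
        return out


_SMOKING_STEP = {"0": 0, "1-20": 1, "21-100": 2}


def _stage_split_probs(config: CohortConfig, p: float) -> tuple[float, float]:
    """Stage-conditional RASSF1 methylation probabilities (III-IV, I-II)
    that preserve the marginal ``p`` across the cancer stage mix."""
    stage_probs = config.categoricals["stage_band"]["cancer"]
    w_hi = stage_probs.get("III-IV", 0.0)
    w_lo = stage_probs.get("I-II", 0.0)
    p_hi = min(1.0, p * config.rassf1_stage_odds)
    if w_lo <= 0:
        return p_hi, p
    p_lo = max(0.0, (p - w_hi * p_hi) / w_lo)
    return p_hi, p_lo


def _draw_category(rng: np.random.Generator, probs: dict[str, float]) -> str:
    names = list(probs)
    idx = rng.choice(len(names), p=np.array([probs[n] for n in names]))
    return names[idx]


def simulate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Simulate a cohort as a tidy table: one row per subject with group,
    clinical categories, and per-gene true methylation levels/states."""
    rng = np.random.default_rng(config.seed)
    rows = []
    genes = list(config.mixtures)
    for group, count in (("cancer", config.n_cancer), ("control", config.n_control)):
        for i in range(count):
            rec: dict = {
                "sample_id": f"{group[:3]}{i + 1:03d}",
                "group": group,
            }
            for feature, by_group in config.categoricals.items():
                rec[feature] = _draw_category(rng, by_group[group])
            for gene in genes:
                mix = config.mixtures[gene][group]
                shift = 0.0
                if group == "cancer" and gene == "p16":
                    shift += config.p16_smoking_shift * _SMOKING_STEP.get(
                        rec["pack_years_band"], 0
                    )
                    if rec["histology"] in ("squamous", "large_cell"):
                        shift += config.p16_histology_shift
                if group == "cancer" and gene == "RASSF1":
                    p_hi, p_lo = _stage_split_probs(config, mix.p_methylated)
                    mix = replace(
                        mix,
                        p_methylated=p_hi if rec["stage_band"] == "III-IV" else p_lo,
                    )
                level = mix.draw(rng, shift)
                rec[f"level_{gene}"] = level
                rec[f"state_{gene}"] = level >= 0.05
            rows.append(rec)
    return pd.DataFrame(rows)
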