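"""Whole-spectrum deconvolution into dsCG/dsAT reference components.

A preprocessed product spectrum is regressed, over every grid point, onto
the preprocessed dsCG and dsAT reference spectra by ordinary least squares.
The two fitted coefficients carry the duplex composition: renormalizing
them, ``f = c_CG / (c_CG + c_AT)``, yields a CG base-pair fraction that is
invariant to the overall intensity scale of the target (and hence to the
normalization convention used upstream).  The per-amplicon calibration then
converts ``f`` to a methylation level, which is deliberately left unclipped
— negative estimates are informative noise outcomes; the binary state call
applies the 5% threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import (
    GeneCalibration,
    cg_fraction_at_level,
    methylation_from_cg_fraction,
)
from .errors import ConditioningError, DataError, NonPhysicalFitError
from .spectra import PreprocessConfig, Spectrum, preprocess

__all__ = [
    "ReferenceSet",
    "build_reference_set",
    "DeconvolutionResult",
    "MethylationEstimate",
    "mlr_deconvolve",
    "cg_fraction_from_coefficients",
    "estimate_methylation",
    "call_state",
    "STATE_THRESHOLD",
]

#: Methylation-state cutoff: a gene is called methylated at level >= 5%.
STATE_THRESHOLD = 0.05

#: Condition-number ceiling for the two-column reference design matrix.
MAX_CONDITION = 1e8


@dataclass(frozen=True)
class ReferenceSet:
    """The pair of reference spectra, preprocessed and on a common grid."""

    s_cg: Spectrum
    s_at: Spectrum

    def __post_init__(self) -> None:
        if not np.array_equal(self.s_cg.wavenumbers, self.s_at.wavenumbers):
            raise DataError("reference spectra must share one wavenumber grid")

    def design_matrix(self, with_intercept: bool) -> np.ndarray:
        cols = [self.s_cg.intensities, self.s_at.intensities]
        if with_intercept:
            cols.append(np.ones_like(self.s_cg.intensities))
        return np.column_stack(cols)


@dataclass(frozen=True)
class DeconvolutionResult:
    """OLS fit of a target spectrum on the two references."""

    c_cg: float
    c_at: float
    intercept: float | None
    fitted: Spectrum
    difference: Spectrum  # fitted - target
    r_squared: float


@dataclass(frozen=True)
class MethylationEstimate:
    """Methylation read-out for one sample x gene."""

    gene: str
    cg_fraction: float
    level: float
    state: bool  # True = methylated
    replicate_levels: tuple[float, ...] | None = None


def build_reference_set(
    cg_replicates: list[Spectrum],
    at_replicates: list[Spectrum],
    preprocess_config: PreprocessConfig | None = None,
) -> ReferenceSet:
    """Characterize the dsCG/dsAT reference pair from replicate measurements.

    Each replicate is smoothed and baseline-corrected, replicates are
    averaged per kind, and the averaged pair is then normalized *jointly*
    (divided by their common maximum).  Joint rather than per-spectrum
    normalization is essential: the references are prepared equimolar, so
    their relative intensity scale carries the per-unit-composition
    response that ``c_cg/(c_cg + c_at)`` converts into a CG fraction.
    Normalizing each reference to its own maximum would silently rescale
    one component against the other and bias every downstream estimate.
    """
    if not cg_replicates or not at_replicates:
        raise DataError("need at least one replicate per reference kind")
    cfg = preprocess_config or PreprocessConfig()
    # per-replicate smoothing + baseline only; joint scale handled below
    solo = PreprocessConfig(
        smooth=cfg.smooth,
        window_length=cfg.window_length,
        polyorder=cfg.polyorder,
        baseline=cfg.baseline,
        lam=cfg.lam,
        p=cfg.p,
        niter=cfg.niter,
        normalize=False,
    )

    def average(replicates: list[Spectrum], kind: str) -> Spectrum:
        processed = [preprocess(sp, solo) for sp in replicates]
        grid = processed[0].wavenumbers
        for sp in processed[1:]:
            if not np.array_equal(sp.wavenumbers, grid):
                raise DataError("reference replicates must share one grid")
        y = np.mean([sp.intensities for sp in processed], axis=0)
        return Spectrum(grid, y, {"kind": kind, "n_replicates": len(processed)})

    s_cg = average(cg_replicates, "CG")
    s_at = average(at_replicates, "AT")
    scale = max(np.max(s_cg.intensities), np.max(s_at.intensities))
    if scale <= 0:
        raise DataError("reference spectra are non-positive after preprocessing")
    return ReferenceSet(
        s_cg=s_cg.with_intensities(s_cg.intensities / scale),
        s_at=s_at.with_intensities(s_at.intensities / scale),
    )


def mlr_deconvolve(
    target: Spectrum, refs: ReferenceSet, with_intercept: bool = False
) -> DeconvolutionResult:
    """Ordinary least squares of the target on the dsCG/dsAT references.

    Coefficients are unconstrained; negative values are permitted and
    propagate to (meaningful) negative methylation estimates.
    """
    if not np.array_equal(target.wavenumbers, refs.s_cg.wavenumbers):
        raise DataError(
            "target not on the reference grid; resample before deconvolving"
        )
    X = refs.design_matrix(with_intercept)
    cond = np.linalg.cond(X)
    if not np.isfinite(cond) or cond > MAX_CONDITION:
        raise ConditioningError(
            f"reference design matrix condition number {cond:.3g} exceeds "
            f"{MAX_CONDITION:.0e}; references are near-collinear"
        )
    y = target.intensities
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted_y = X @ beta
    resid = y - fitted_y
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return DeconvolutionResult(
        c_cg=float(beta[0]),
        c_at=float(beta[1]),
        intercept=float(beta[2]) if with_intercept else None,
        fitted=target.with_intensities(fitted_y, role="fitted"),
        difference=target.with_intensities(fitted_y - y, role="difference"),
        r_squared=max(0.0, min(1.0, r2)),
    )


def cg_fraction_from_coefficients(result: DeconvolutionResult) -> float:
    """CG base-pair fraction from fitted coefficients: c_cg/(c_cg+c_at).

    The renormalization makes the fraction invariant to the target's
    overall intensity scale.
    """
    total = result.c_cg + result.c_at
    if total <= 0:
        raise NonPhysicalFitError(
            f"coefficient sum {total:.4g} is non-positive; deconvolution failed"
        )
    return result.c_cg / total


def call_state(level: float, threshold: float = STATE_THRESHOLD) -> bool:
    """True (methylated) iff ``level >= threshold``; negative levels are
    unmethylated."""
    return level >= threshold


def estimate_methylation(
    targets: Spectrum | list[Spectrum],
    refs: ReferenceSet,
    calib: GeneCalibration,
    preprocess_config: PreprocessConfig | None = None,
    with_intercept: bool = False,
    threshold: float = STATE_THRESHOLD,
) -> MethylationEstimate:
    """Composed pipeline: preprocess -> deconvolve -> CG fraction ->
    methylation level -> state.

    ``targets`` may be a single spectrum or replicate spectra of one
    sample; replicate levels are averaged (for this linear pipeline that is
    equivalent to averaging the spectra first).  Pass
    ``preprocess_config=None`` together with an already-preprocessed
    target by using ``PreprocessConfig(smooth=False, baseline=False,
    normalize=False)``.
    """
    if isinstance(targets, Spectrum):
        targets = [targets]
    if not targets:
        raise DataError("no target spectra supplied")
    levels = []
    for sp in targets:
        if preprocess_config is not None:
            sp = preprocess(sp, preprocess_config)
        result = mlr_deconvolve(sp, refs, with_intercept)
        f = cg_fraction_from_coefficients(result)
        levels.append(methylation_from_cg_fraction(calib, f))
    level = float(np.mean(levels))
    return MethylationEstimate(
        gene=calib.gene_name,
        cg_fraction=cg_fraction_at_level(calib, level),
        level=level,
        state=call_state(level, threshold),
        replicate_levels=tuple(levels) if len(levels) > 1 else None,
    )
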