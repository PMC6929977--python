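"""Unmix one simulated PCR-product spectrum into dsCG/dsAT components.

The synthetic generator stands in for the Raman instrument: it composes
Lorentzian bands at the assigned dsCG/dsAT wavenumbers, linear in duplex
composition, then adds baseline drift, a random intensity scale, and shot
noise.  Ordinary least squares against the two reference spectra recovers
the composition; the renormalized coefficient ratio is the CG fraction.
"""

import numpy as np

from sersmeth import STUDY_GENES, SimulationConfig, make_product_spectrum
from sersmeth.deconvolution import estimate_methylation, mlr_deconvolve
from sersmeth.pipeline import characterize_references
from sersmeth.spectra import PreprocessConfig, preprocess
from sersmeth.calibration import cg_fraction_at_level

sim = SimulationConfig(seed=42)
prep = PreprocessConfig()

# Characterize the reference pair (3 replicate measurements each,
# smoothed, baseline-corrected, jointly scaled).
refs = characterize_references(sim, prep)

# One noisy measurement of a p16 product at 50% methylation.
p16 = STUDY_GENES["p16"]
true_m = 0.50
f_true = cg_fraction_at_level(p16, true_m)
rng = np.random.default_rng(sim.seed + 1)
target = make_product_spectrum(f_true, sim, rng)

result = mlr_deconvolve(preprocess(target, prep), refs)
print(f"true CG fraction          : {f_true:.4f}")
print(f"fitted coefficients       : c_CG={result.c_cg:.4f}, c_AT={result.c_at:.4f}")
print(f"fit quality R^2           : {result.r_squared:.5f}")

est = estimate_methylation(target, refs, p16, prep)
print(f"estimated CG fraction     : {est.cg_fraction:.4f}")
print(
    f"estimated methylation     : {est.level:.4f}  (truth {true_m:.2f}; "
    f"state: {'methylated' if est.state else 'unmethylated'})"
)
# The coefficient ratio, not the raw coefficients, carries the answer:
# the spectrum's overall intensity scale cancels in c_CG/(c_CG+c_AT).
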