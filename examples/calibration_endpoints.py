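"""Build per-amplicon calibrations and show the methylation <-> CG map.

A bisulfite-converted amplicon carries N0 C:G base pairs when fully
unmethylated; each methylated CpG retains one more.  The CG base-pair
fraction is therefore linear in methylation level, and its two endpoints
are all the assay needs per gene.
"""

from sersmeth import (
    STUDY_GENES,
    calibration_from_sequence,
    cg_fraction_at_level,
    methylation_from_cg_fraction,
)

# The three study genes, instantiated from published constants
# (amplicon length, CpG count, one printed CG-percentage endpoint).
print("gene      L   nCpG   CG% at m=0   CG% at m=1")
for gene, calib in STUDY_GENES.items():
    print(
        f"{gene:8s} {calib.amplicon_length:3d}   {calib.n_cpg:3d}"
        f"     {100 * calib.f0:6.2f}       {100 * calib.f100:6.2f}"
    )

# From a raw amplicon sequence instead: the constructor simulates the
# unmethylated bisulfite conversion and counts the surviving C/G bases.
toy = calibration_from_sequence("toy", "TACGGATCGA")
print(
    f"\ntoy amplicon TACGGATCGA: L={toy.amplicon_length}, nCpG={toy.n_cpg}, "
    f"CG fraction {toy.f0:.2f} (m=0) -> {toy.f100:.2f} (m=1)"
)

# The map is exactly invertible: a measured CG fraction converts straight
# back to a methylation level (unclipped; noise can push it below 0).
p16 = STUDY_GENES["p16"]
f = cg_fraction_at_level(p16, 0.25)
print(f"\np16 at 25% methylation -> CG fraction {f:.4f}")
print(f"inverting {f:.4f} -> methylation level {methylation_from_cg_fraction(p16, f):.4f}")
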