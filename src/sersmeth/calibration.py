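"""Bisulfite/PCR calibration: the linear map between methylation level and
CG base-pair fraction of an amplicon.

Bisulfite treatment converts every unmethylated cytosine to uracil (read as
thymine after PCR) while methylated cytosines — in mammalian DNA, cytosines
of CpG dinucleotides — are retained.  The PCR product of a fully
unmethylated template therefore carries ``N0`` C:G base pairs out of ``L``,
and each methylated CpG adds exactly one C:G pair back.  The CG base-pair
fraction of the duplex is consequently affine in the population methylation
level ``m``::

    f(m) = (N0 + m * n_cpg) / L,       m = (f - f0) / (f100 - f0)

with endpoints ``f0 = N0/L`` (0 % methylation) and
``f100 = (N0 + n_cpg)/L`` (100 %).  SERS measures bulk base-pair
composition, so ``m`` scales expected retained CpG cytosines linearly; no
per-molecule methylation patterns are enumerated.

Conversion is modelled on the top strand only: methylation-independent
primers select one converted strand, whose duplex amplicon has CG fraction
``(#C + #G in the converted top strand) / L``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .errors import DataError, DegenerateCalibrationError, InvalidAlphabetError

__all__ = [
    "GeneCalibration",
    "bisulfite_convert",
    "find_cpg_positions",
    "calibration_from_sequence",
    "calibration_from_constants",
    "cg_fraction_at_level",
    "methylation_from_cg_fraction",
    "calibrations_from_fasta",
    "calibration_table",
    "STUDY_GENES",
]

_VALID_BASES = frozenset("ACGT")

#: Rounding tolerance (base pairs) when reconstructing the integer CG count
#: at 0% methylation from a percentage printed to two decimals.
ROUNDING_TOL_BP = 0.05


@dataclass(frozen=True)
class GeneCalibration:
    """Per-amplicon constants defining the methylation <-> CG-fraction map.

    Attributes
    ----------
    gene_name : str
        Label of the amplified gene.
    amplicon_length : int
        Duplex length ``L`` in base pairs.
    n_cpg : int
        Number of CpG dinucleotides on the top strand.
    cg_count_at_zero : int
        C:G base pairs ``N0`` in the fully unmethylated converted duplex.
    """

    gene_name: str
    amplicon_length: int
    n_cpg: int
    cg_count_at_zero: int

    def __post_init__(self) -> None:
        L, n, n0 = self.amplicon_length, self.n_cpg, self.cg_count_at_zero
        if n <= 0:
            raise DegenerateCalibrationError(
                f"{self.gene_name}: amplicon has no CpG site; the "
                "methylation-to-CG-fraction map would have zero slope"
            )
        if not (n <= L / 2):
            raise DataError(f"{self.gene_name}: n_cpg={n} exceeds L/2={L / 2}")
        if not (0 <= n0 <= L - n):
            raise DataError(
                f"{self.gene_name}: cg_count_at_zero={n0} outside [0, L-n_cpg]"
            )

    @property
    def f0(self) -> float:
        """CG base-pair fraction at 0% methylation."""
        return self.cg_count_at_zero / self.amplicon_length

    @property
    def f100(self) -> float:
        """CG base-pair fraction at 100% methylation."""
        return (self.cg_count_at_zero + self.n_cpg) / self.amplicon_length


def find_cpg_positions(sequence: str) -> list[int]:
    """Indices of CpG cytosines on the given (top) strand."""
    seq = _validate_sequence(sequence)
    return [i for i in range(len(seq) - 1) if seq[i] == "C" and seq[i + 1] == "G"]


def _validate_sequence(sequence: str) -> str:
    seq = sequence.upper()
    bad = set(seq) - _VALID_BASES
    if bad:
        raise InvalidAlphabetError(
            f"sequence contains non-ACGT characters: {sorted(bad)}"
        )
    return seq


def bisulfite_convert(
    sequence: str, methylated_cpg_flags: Sequence[bool]
) -> str:
    """Apply bisulfite conversion to the top strand of ``sequence``.

    Every cytosine is deaminated to uracil — read as thymine after PCR —
    except CpG cytosines whose flag is True (methylated, protected).

    Parameters
    ----------
    sequence : str
        A/C/G/T string (case-insensitive); returned upper-case.
    methylated_cpg_flags : sequence of bool
        One flag per CpG dinucleotide found on the strand, in 5'->3' order.
    """
    seq = _validate_sequence(sequence)
    cpg_positions = [
        i for i in range(len(seq) - 1) if seq[i] == "C" and seq[i + 1] == "G"
    ]
    if len(methylated_cpg_flags) != len(cpg_positions):
        raise DataError(
            f"expected {len(cpg_positions)} methylation flags "
            f"(one per CpG), got {len(methylated_cpg_flags)}"
        )
    protected = {
        pos
        for pos, flag in zip(cpg_positions, methylated_cpg_flags)
        if flag
    }
    out = [
        base if base != "C" or i in protected else "T"
        for i, base in enumerate(seq)
    ]
    return "".join(out)


def calibration_from_sequence(gene_name: str, amplicon: str) -> GeneCalibration:
    """Derive a :class:`GeneCalibration` from the amplicon top strand.

    ``N0`` is the C+G count of the fully unmethylated converted strand;
    each methylated CpG retains one extra C (hence one extra C:G pair in
    the duplex).
    """
    seq = _validate_sequence(amplicon)
    n_cpg = len(find_cpg_positions(seq))
    if n_cpg == 0:
        raise DegenerateCalibrationError(
            f"{gene_name}: amplicon contains no CpG dinucleotide"
        )
    converted = bisulfite_convert(seq, [False] * n_cpg)
    n0 = sum(1 for b in converted if b in "CG")
    return GeneCalibration(
        gene_name=gene_name,
        amplicon_length=len(seq),
        n_cpg=n_cpg,
        cg_count_at_zero=n0,
    )


def calibration_from_constants(
    gene_name: str,
    amplicon_length: int,
    n_cpg: int,
    *,
    f0: float | None = None,
    f100: float | None = None,
) -> GeneCalibration:
    """Build a calibration from (L, n_cpg) plus one printed CG-fraction
    endpoint, recovering the integer CG count at 0% methylation.

    Exactly one of ``f0``/``f100`` must be given.  The implied
    ``N0 = f0*L`` (or ``f100*L - n_cpg``) must be within
    :data:`ROUNDING_TOL_BP` base pairs of an integer — the slack a
    two-decimal printed percentage allows.
    """
    if (f0 is None) == (f100 is None):
        raise DataError("provide exactly one of f0= or f100=")
    endpoint = f0 if f0 is not None else f100
    if not (0.0 < endpoint <= 1.0):
        raise DataError(f"endpoint fraction {endpoint} outside (0, 1]")
    implied = endpoint * amplicon_length
    if f100 is not None:
        implied -= n_cpg
    n0 = round(implied)
    if abs(implied - n0) > ROUNDING_TOL_BP:
        raise DataError(
            f"{gene_name}: endpoint {endpoint} implies a non-integer CG "
            f"count {implied:.3f} at 0% methylation (tolerance "
            f"{ROUNDING_TOL_BP} bp)"
        )
    return GeneCalibration(
        gene_name=gene_name,
        amplicon_length=amplicon_length,
        n_cpg=n_cpg,
        cg_count_at_zero=n0,
    )


def cg_fraction_at_level(calib: GeneCalibration, m: float) -> float:
    """CG base-pair fraction of the PCR product at methylation level ``m``.

    ``m`` may lie outside [0, 1] for consistency with the (unclipped)
    inverse map.
    """
    return (calib.cg_count_at_zero + m * calib.n_cpg) / calib.amplicon_length


def methylation_from_cg_fraction(calib: GeneCalibration, f: float) -> float:
    """Invert the calibration: methylation level at CG fraction ``f``.

    Returned unclipped — estimates below 0 or above 1 are meaningful
    noise-driven outcomes and the 5% state threshold is applied downstream.
    """
    return (f - calib.f0) / (calib.f100 - calib.f0)


def calibrations_from_fasta(path_or_handle) -> dict[str, GeneCalibration]:
    """Read amplicons from a (multi-)FASTA; record ids become gene names."""
    if isinstance(path_or_handle, (str, bytes)) or hasattr(path_or_handle, "__fspath__"):
        records = list(SeqIO.parse(str(path_or_handle), "fasta"))
    else:
        records = list(SeqIO.parse(path_or_handle, "fasta"))
    if not records:
        raise DataError("no FASTA records found")
    return {
        rec.id: calibration_from_sequence(rec.id, str(rec.seq))
        for rec in records
    }


def calibrations_from_config(entries: Iterable[dict]) -> dict[str, GeneCalibration]:
    """Build calibrations from constants entries, each a mapping with keys
    ``gene``, ``length``, ``n_cpg``, ``endpoint`` (fraction), and
    ``endpoint_kind`` ("f0" or "f100")."""
    out: dict[str, GeneCalibration] = {}
    for entry in entries:
        missing = {"gene", "length", "n_cpg", "endpoint", "endpoint_kind"} - set(entry)
        if missing:
            raise DataError(f"calibration entry missing key(s): {sorted(missing)}")
        kind = entry["endpoint_kind"]
        if kind not in ("f0", "f100"):
            raise DataError(f"endpoint_kind must be 'f0' or 'f100', got {kind!r}")
        out[entry["gene"]] = calibration_from_constants(
            entry["gene"],
            int(entry["length"]),
            int(entry["n_cpg"]),
            **{kind: float(entry["endpoint"])},
        )
    return out


def calibration_table(calibs: Iterable[GeneCalibration]) -> pd.DataFrame:
    """Delimited-table view: gene, L, n_cpg, N0, f0, f100."""
    return pd.DataFrame(
        [
            {
                "gene": c.gene_name,
                "L": c.amplicon_length,
                "n_cpg": c.n_cpg,
                "N0": c.cg_count_at_zero,
                "f0": c.f0,
                "f100": c.f100,
            }
            for c in calibs
        ]
    )


def _study_genes() -> dict[str, GeneCalibration]:
    # Published constants for the three NSCLC marker amplicons: length,
    # CpG count, and the printed CG percentage at one endpoint.
    return {
        "p16": calibration_from_constants("p16", 93, 7, f0=0.5484),
        "MGMT": calibration_from_constants("MGMT", 98, 12, f0=0.3469),
        "RASSF1": calibration_from_constants("RASSF1", 136, 12, f100=0.4632),
    }


#: Calibrations of the three study genes (p16, MGMT, RASSF1), instantiated
#: from their published amplicon constants.
STUDY_GENES: dict[str, GeneCalibration] = _study_genes()
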