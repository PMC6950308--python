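"""Reference data for the two *Actinia tenebrosa* Kunitz inhibitors.

The tryptic-peptide evidence (sequences, observed and calculated precursor
m/z at the reported charges) from the LC-MS/MS sequencing of ATPI-I and
ATPI-II, and the full chains assembled from the overlapping peptides.
These serve as worked inputs for the identification and verification
stages and as ground truth for the synthetic generators.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "PeptideObservation",
    "ATPI_I_PEPTIDES",
    "ATPI_II_PEPTIDES",
    "ATPI_I_CHAIN",
    "ATPI_II_CHAIN",
    "ATPI_I_AVG_MASS",
    "ATPI_II_AVG_MASS",
]


@dataclass(frozen=True)
class PeptideObservation:
    """One sequenced tryptic peptide with its precursor-ion evidence."""

    sequence: str
    start: int  # 1-based inclusive position on the mature chain
    end: int
    charge: int
    observed_mz: float
    reported_calc_mz: float | None = None
    #: True when the reported calculated m/z is internally inconsistent
    #: with the mass-verified chain (a published erratum); such rows are
    #: kept as inputs but excluded from exact m/z reproduction checks.
    erratum: bool = False


ATPI_I_PEPTIDES: tuple[PeptideObservation, ...] = (
    PeptideObservation("DANSFCQLPAVVGK", 1, 14, 2, 753.47, 753.37),
    PeptideObservation("CRGYFPRYYYNTEAGK", 15, 30, 4, 510.32, 509.97, erratum=True),
    PeptideObservation("YYYNTEAGK", 22, 30, 2, 554.97, 554.75),
    PeptideObservation("CQQFIYGGCGGNR", 31, 43, 2, 758.89, 758.82),
    PeptideObservation("CQQFIYGGCGGNRNNFETVEDCR", 31, 53, 3, 928.00, 927.72),
    PeptideObservation("NNFETVEDCR", 44, 53, 2, 642.39, 642.27),
    PeptideObservation("NNFETVEDCRATCHSHA", 44, 60, 4, 513.00, 512.71),
)

# ATPI-II evidence starts at mature position 3; residues 1-2 were not
# resolved by the peptide data.
ATPI_II_PEPTIDES: tuple[PeptideObservation, ...] = (
    PeptideObservation("NSFCNLPAVVGRCKGYFPR", 3, 21, 4, 561.60, 561.28),
    PeptideObservation("NSFCNLPAVVGR", 3, 14, 2, 667.53, 667.34),
    PeptideObservation("CKGYFPR", 15, 21, 2, 464.63, 464.23),
    PeptideObservation("YFYNTEAGKCQR", 22, 33, 3, 513.23, 512.90),
    PeptideObservation("FIYGGCGGNRNNFETVDDCRATCHPRE", 34, 60, 5, 641.54, 641.28),
)

#: 60-residue mature ATPI-I chain assembled from the overlapping peptides.
ATPI_I_CHAIN = (
    "DANSFCQLPAVVGK" "CRGYFPRYYYNTEAGK" "CQQFIYGGCGGNR" "NNFETVEDCRATCHSHA"
)

#: Assembled ATPI-II chain (mature positions 3-60; N-terminal two residues
#: unresolved by the peptide evidence).
ATPI_II_CHAIN = (
    "NSFCNLPAVVGR" "CKGYFPR" "YFYNTEAGKCQR" "FIYGGCGGNRNNFETVDDCRATCHPRE"
)

#: Calculated intact average masses (reduced chain, unmodified Cys), Da.
ATPI_I_AVG_MASS = 6719.43
ATPI_II_AVG_MASS = 6604.39
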