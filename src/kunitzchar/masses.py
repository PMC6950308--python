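"""Amino-acid mass chemistry for peptide and protein ions.

Monoisotopic and average residue masses (IUPAC), fixed modifications,
neutral peptide/protein masses, charged-ion m/z and tryptic digestion.
All coordinates are 1-based and inclusive; internal masses are kept at
full float precision and rounded only for presentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "AminoAcidTable",
    "ModificationSpec",
    "PeptideIon",
    "DigestResult",
    "STANDARD_TABLE",
    "CARBAMIDOMETHYL",
    "PROTON_MASS",
    "peptide_monoisotopic_mass",
    "peptide_average_mass",
    "ion_mz",
    "chain_average_mass",
    "tryptic_digest",
]

#: Proton mass used for charging, Da.  1.00728 (not the H atomic weight
#: 1.00794) is required to reproduce printed 2-decimal m/z values.
PROTON_MASS = 1.00728

# (monoisotopic, average) residue masses, Da
_RESIDUE_MASSES: dict[str, tuple[float, float]] = {
    "G": (57.02146, 57.0519),
    "A": (71.03711, 71.0788),
    "S": (87.03203, 87.0782),
    "P": (97.05276, 97.1167),
    "V": (99.06841, 99.1326),
    "T": (101.04768, 101.1051),
    "C": (103.00919, 103.1388),
    "L": (113.08406, 113.1594),
    "I": (113.08406, 113.1594),
    "N": (114.04293, 114.1038),
    "D": (115.02694, 115.0886),
    "Q": (128.05858, 128.1307),
    "K": (128.09496, 128.1741),
    "E": (129.04259, 129.1155),
    "M": (131.04049, 131.1926),
    "H": (137.05891, 137.1411),
    "F": (147.06841, 147.1766),
    "R": (156.10111, 156.1875),
    "Y": (163.06333, 163.1760),
    "W": (186.07931, 186.2132),
}


@dataclass(frozen=True)
class AminoAcidTable:
    """Residue mass table plus the water and proton constants.

    ``residues`` maps one-letter codes to ``(monoisotopic, average)``
    residue (i.e. dehydrated) masses in Da.
    """

    residues: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_RESIDUE_MASSES)
    )
    water_mono: float = 18.01056
    water_avg: float = 18.0153
    proton: float = PROTON_MASS

    def mono(self, aa: str) -> float:
        try:
            return self.residues[aa][0]
        except KeyError:
            raise ValueError(f"unknown residue code {aa!r}") from None

    def avg(self, aa: str) -> float:
        try:
            return self.residues[aa][1]
        except KeyError:
            raise ValueError(f"unknown residue code {aa!r}") from None

    def validate_sequence(self, seq: str) -> None:
        for aa in seq:
            if aa not in self.residues:
                raise ValueError(f"unknown residue code {aa!r} in sequence")


STANDARD_TABLE = AminoAcidTable()


@dataclass(frozen=True)
class ModificationSpec:
    """A fixed (quantitative) modification applied to every target residue."""

    name: str
    delta_mono: float
    delta_avg: float
    target_residues: frozenset[str]

    def __post_init__(self) -> None:
        if not self.target_residues:
            raise ValueError("target_residues must be non-empty")

    def count_in(self, seq: str) -> int:
        return sum(seq.count(aa) for aa in self.target_residues)


#: Iodoacetamide alkylation of cysteine (+57.02 Da), applied after
#: disulfide reduction in the sequencing workflow.
CARBAMIDOMETHYL = ModificationSpec(
    name="carbamidomethyl",
    delta_mono=57.02146,
    delta_avg=57.0513,
    target_residues=frozenset("C"),
)


@dataclass(frozen=True)
class PeptideIon:
    """A (sub)sequence with fixed modifications and charge.

    ``start_pos``/``end_pos`` are optional 1-based inclusive coordinates
    in the parent chain.
    """

    sequence: str
    fixed_mods: tuple[ModificationSpec, ...] = ()
    charge: int = 1
    start_pos: int | None = None
    end_pos: int | None = None

    def __post_init__(self) -> None:
        STANDARD_TABLE.validate_sequence(self.sequence)
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        if self.start_pos is not None and self.end_pos is not None:
            if self.end_pos - self.start_pos + 1 != len(self.sequence):
                raise ValueError(
                    "end_pos - start_pos + 1 must equal sequence length"
                )

    @property
    def neutral_mass(self) -> float:
        return peptide_monoisotopic_mass(self.sequence, self.fixed_mods)

    @property
    def mz(self) -> float:
        return ion_mz(self.neutral_mass, self.charge)


@dataclass(frozen=True)
class DigestResult:
    """Products of an in-silico digest, with per-peptide missed-cleavage counts."""

    peptides: tuple[PeptideIon, ...]
    missed_cleavages: tuple[int, ...]

    def __iter__(self):
        return iter(zip(self.peptides, self.missed_cleavages))

    def __len__(self) -> int:
        return len(self.peptides)


def _mod_delta(seq: str, mods: Iterable[ModificationSpec], mono: bool) -> float:
    return sum(
        (m.delta_mono if mono else m.delta_avg) * m.count_in(seq) for m in mods
    )


def peptide_monoisotopic_mass(
    seq: str,
    mods: Iterable[ModificationSpec] = (),
    table: AminoAcidTable = STANDARD_TABLE,
) -> float:
    """Neutral monoisotopic mass: residue masses + water + fixed-mod deltas."""
    if not seq:
        raise ValueError("sequence must be non-empty")
    table.validate_sequence(seq)
    return sum(table.mono(aa) for aa in seq) + table.water_mono + _mod_delta(
        seq, mods, mono=True
    )


def peptide_average_mass(
    seq: str,
    mods: Iterable[ModificationSpec] = (),
    table: AminoAcidTable = STANDARD_TABLE,
) -> float:
    """Neutral average (isotope-abundance-weighted) mass."""
    if not seq:
        raise ValueError("sequence must be non-empty")
    table.validate_sequence(seq)
    return sum(table.avg(aa) for aa in seq) + table.water_avg + _mod_delta(
        seq, mods, mono=False
    )


def ion_mz(neutral_mass: float, charge: int, proton: float = PROTON_MASS) -> float:
    """m/z of the [M + zH]^z+ ion."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (neutral_mass + charge * proton) / charge


#: Average mass of one hydrogen atom, Da; each disulfide removes two.
_H_AVG = 1.008


def chain_average_mass(
    seq: str,
    cysteine_state: str | int = "reduced",
    table: AminoAcidTable = STANDARD_TABLE,
) -> float:
    """Average mass of a full chain, optionally oxidised into disulfides.

    ``cysteine_state`` is either ``"reduced"`` (free thiols, the convention
    behind calculated intact masses of the reconstructed inhibitors) or an
    integer number of disulfide bonds, each subtracting 2 H.
    """
    reduced = peptide_average_mass(seq, (), table)
    if cysteine_state == "reduced":
        return reduced
    n = int(cysteine_state)
    if n < 0:
        raise ValueError("number of disulfides must be >= 0")
    if 2 * n > seq.count("C"):
        raise ValueError(
            f"{n} disulfides require {2 * n} Cys; sequence has {seq.count('C')}"
        )
    return reduced - n * 2 * _H_AVG


def cleavage_sites(seq: str) -> list[int]:
    """0-based indices i such that trypsin cuts between seq[i-1] and seq[i].

    Rule: C-terminal to K or R, except when the next residue is P.
    Returned list includes the 0 and len(seq) sentinels.
    """
    sites = [0]
    sites.extend(
        i + 1
        for i in range(len(seq) - 1)
        if seq[i] in "KR" and seq[i + 1] != "P"
    )
    sites.append(len(seq))
    return sites


def tryptic_digest(
    seq: str,
    max_missed: int = 2,
    min_length: int = 1,
    mods: Sequence[ModificationSpec] = (),
) -> DigestResult:
    """In-silico tryptic digest emitting all products with <= max_missed
    internal cleavage sites and length >= min_length.

    Peptides carry 1-based inclusive positions on the parent; the
    zero-missed products partition the parent exactly.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    if not seq:
        return DigestResult((), ())
    STANDARD_TABLE.validate_sequence(seq)
    sites = cleavage_sites(seq)
    peptides: list[PeptideIon] = []
    missed: list[int] = []
    for a in range(len(sites) - 1):
        for b in range(a + 1, min(a + max_missed + 2, len(sites))):
            sub = seq[sites[a] : sites[b]]
            if len(sub) < min_length:
                continue
            peptides.append(
                PeptideIon(
                    sequence=sub,
                    fixed_mods=tuple(mods),
                    charge=1,
                    start_pos=sites[a] + 1,
                    end_pos=sites[b],
                )
            )
            missed.append(b - a - 1)
    return DigestResult(tuple(peptides), tuple(missed))
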