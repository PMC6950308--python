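"""Tag-to-transcriptome matching and mass-verified sequence reconstruction.

Sequence tags read from MS/MS ladders are searched against all six reading
frames of transcriptome contigs; candidate proteins are then verified by
in-silico digestion against the observed precursor ions, and the full
chain is reconstructed from the overlapping matched peptides.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .masses import (
    CARBAMIDOMETHYL,
    ModificationSpec,
    PeptideIon,
    chain_average_mass,
    ion_mz,
    tryptic_digest,
)
from .spectra import SequenceTag

__all__ = [
    "CandidateProtein",
    "TagHit",
    "PrecursorMatch",
    "ReconstructionReport",
    "six_frame_translate",
    "search_tags",
    "verify_candidate",
    "reconstruct_sequence",
]

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _translate_frame(nt: str) -> str:
    out = []
    for i in range(0, len(nt) - 2, 3):
        codon = nt[i : i + 3]
        out.append("X" if "N" in codon else _CODON_TABLE[codon])
    return "".join(out)


def six_frame_translate(nt: str) -> list[str]:
    """Standard-code translation of frames +1..+3 and -1..-3.

    Stops are rendered as '*'; codons containing N translate to 'X'.
    """
    nt = nt.upper()
    bad = set(nt) - set("ACGTN")
    if bad:
        raise ValueError(f"non-IUPAC nucleotide characters: {sorted(bad)}")
    rc = nt.translate(_COMPLEMENT)[::-1]
    return [_translate_frame(s[off:]) for s in (nt, rc) for off in (0, 1, 2)]


@dataclass(frozen=True)
class TagHit:
    """A tag match inside a translated frame."""

    protein_id: str
    offset: int  # 0-based start in the protein string
    tag: SequenceTag
    orientation: str  # "forward" (b-ladder, N->C) | "reverse" (y-ladder)


def _tag_regex(classes: Sequence[frozenset[str]]) -> "re.Pattern[str]":
    # lookahead wrapper makes overlapping matches visible
    body = "".join(
        next(iter(cls)) if len(cls) == 1 else "[" + "".join(sorted(cls)) + "]"
        for cls in classes
    )
    return re.compile(f"(?=({body}))")


def search_tags(
    proteins: Iterable[tuple[str, str]],
    tags: Iterable[SequenceTag],
) -> list[TagHit]:
    """Find every position where a tag's ambiguity classes match a protein.

    Both tag orientations are scanned: read from ascending m/z, a b-ladder
    tag spells the sequence N->C while a y-ladder tag spells it C->N, so
    each tag is also searched reversed. Matching is exact per position
    (each residue must belong to the tag's ambiguity class); overlapping
    matches are all reported.
    """
    hits: list[TagHit] = []
    proteins = list(proteins)
    for tag in tags:
        variants = [("forward", tag.residues)]
        rev = tuple(reversed(tag.residues))
        if rev != tag.residues:
            variants.append(("reverse", rev))
        patterns = [(orient, _tag_regex(cls)) for orient, cls in variants]
        for pid, seq in proteins:
            for orient, pat in patterns:
                for m in pat.finditer(seq):
                    hits.append(TagHit(pid, m.start(), tag, orient))
    return hits


@dataclass(frozen=True)
class PrecursorMatch:
    peptide: PeptideIon
    missed_cleavages: int
    observed_mz: float
    observed_charge: int
    delta_mz: float


@dataclass
class CandidateProtein:
    """A translated candidate with matched-precursor coverage evidence."""

    source_id: str
    sequence: str
    matched: list[PrecursorMatch] = field(default_factory=list)
    coverage: float = 0.0

    @property
    def covered_positions(self) -> set[int]:
        pos: set[int] = set()
        for m in self.matched:
            pos.update(range(m.peptide.start_pos, m.peptide.end_pos + 1))
        return pos


def verify_candidate(
    sequence: str,
    observed_precursors: Sequence[tuple[float, int]],
    tol_mz: float = 0.5,
    mods: Sequence[ModificationSpec] = (CARBAMIDOMETHYL,),
    max_missed: int = 2,
    min_length: int = 1,
    source_id: str = "candidate",
) -> CandidateProtein:
    """Match observed precursor ions to the in-silico digest of a candidate.

    Matching is done in m/z space at the observed charge. Each observed
    precursor is assigned to at most one theoretical peptide within
    ``tol_mz``; ties resolve to smallest |Δm/z|, then fewest missed
    cleavages. Coverage is the fraction of residues under matched spans.
    """
    if tol_mz <= 0:
        raise ValueError("tol_mz must be > 0")
    digest = tryptic_digest(sequence, max_missed=max_missed,
                            min_length=min_length, mods=mods)
    theo = [
        (pep, mc, pep.neutral_mass) for pep, mc in digest
    ]
    cand = CandidateProtein(source_id, sequence)
    for obs_mz, charge in observed_precursors:
        best: PrecursorMatch | None = None
        for pep, mc, mass in theo:
            delta = obs_mz - ion_mz(mass, charge)
            if abs(delta) > tol_mz:
                continue
            if (
                best is None
                or abs(delta) < abs(best.delta_mz)
                or (abs(delta) == abs(best.delta_mz) and mc < best.missed_cleavages)
            ):
                best = PrecursorMatch(pep, mc, obs_mz, charge, delta)
        if best is not None:
            cand.matched.append(best)
    if sequence:
        cand.coverage = len(cand.covered_positions) / len(sequence)
    return cand


@dataclass
class ReconstructionReport:
    """Assembly of a chain from positioned, overlapping peptides."""

    sequence: str  # longest contiguous assembled segment
    segment_start: int  # 1-based position of that segment
    segments: list[tuple[int, int, str]]  # all contiguous (start, end, seq)
    unresolved_positions: list[int]  # gaps within [1, max covered position]
    average_mass: float  # reduced-chain average mass of `sequence`

    @property
    def has_gaps(self) -> bool:
        return bool(self.unresolved_positions)


def reconstruct_sequence(
    peptides: Sequence[PeptideIon],
) -> ReconstructionReport:
    """Assemble the chain covered by overlapping positioned peptides.

    Residue conflicts at a shared position are a hard error naming the
    position. Positions from 1 up to the last covered residue that no
    peptide covers are flagged unresolved; the reported sequence and
    intact average mass (reduced chain, unmodified Cys) belong to the
    longest contiguous segment.
    """
    if not peptides:
        raise ValueError("no peptides to assemble")
    residues: dict[int, str] = {}
    for pep in peptides:
        if pep.start_pos is None or pep.end_pos is None:
            raise ValueError("all peptides must carry positions")
        for k, aa in enumerate(pep.sequence):
            pos = pep.start_pos + k
            prev = residues.get(pos)
            if prev is not None and prev != aa:
                raise ValueError(
                    f"conflicting residues {prev!r} vs {aa!r} at position {pos}"
                )
            residues[pos] = aa
    covered = sorted(residues)
    segments: list[tuple[int, int, str]] = []
    start = covered[0]
    prev = covered[0]
    for pos in covered[1:]:
        if pos != prev + 1:
            segments.append((start, prev, "".join(residues[p] for p in range(start, prev + 1))))
            start = pos
        prev = pos
    segments.append((start, prev, "".join(residues[p] for p in range(start, prev + 1))))
    longest = max(segments, key=lambda s: len(s[2]))
    unresolved = [p for p in range(1, covered[-1] + 1) if p not in residues]
    return ReconstructionReport(
        sequence=longest[2],
        segment_start=longest[0],
        segments=segments,
        unresolved_positions=unresolved,
        average_mass=chain_average_mass(longest[2], "reduced"),
    )
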