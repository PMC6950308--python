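"""Tandem-MS fragment theory, spectrum annotation and sequence-tag deduction.

The identification workflow reads centroided MS/MS spectra (MGF), deduces
short sequence tags from the spacings between adjacent same-series product
ions, and later annotates spectra with theoretical b/y (and a/z) ions of a
candidate peptide.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from pyteomics import mgf as _mgf

from .masses import (
    CARBAMIDOMETHYL,
    PROTON_MASS,
    STANDARD_TABLE,
    ModificationSpec,
    PeptideIon,
)

__all__ = [
    "Spectrum",
    "FragmentIon",
    "SequenceTag",
    "fragment_mz",
    "theoretical_ions",
    "annotate_spectrum",
    "deduce_tags",
    "read_mgf",
    "write_mgf",
]

_CO = 27.99491  # carbonyl loss turning b into a ions
_Z_SHIFT = 16.01872  # y -> z-dot: lose NH3, regain the radical H

# K and Q differ by 0.03638 Da; they merge into one ambiguity class only
# when the fragment tolerance covers that gap.
_KQ_GAP = 0.03638


@dataclass
class Spectrum:
    """A centroided MS/MS spectrum: precursor plus fragment peak list."""

    precursor_mz: float
    precursor_charge: int
    mz: np.ndarray
    intensity: np.ndarray
    title: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have the same shape")
        if self.precursor_charge < 1:
            raise ValueError("precursor_charge must be >= 1")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be >= 0")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    def __len__(self) -> int:
        return self.mz.size


@dataclass(frozen=True)
class FragmentIon:
    """One theoretical product ion of a peptide."""

    series: str  # a | b | y | z
    index: int
    charge: int
    mz: float


@dataclass(frozen=True)
class SequenceTag:
    """A partial sequence read from same-series peak spacings.

    ``residues`` is a tuple of ambiguity classes (frozensets of one-letter
    codes); anchors are the m/z of the first and last peak of the ladder
    segment the tag was read from.
    """

    residues: tuple[frozenset[str], ...]
    anchor_mz_low: float
    anchor_mz_high: float
    direction: str = "unknown"  # b-ladder | y-ladder | unknown

    def __len__(self) -> int:
        return len(self.residues)

    def class_string(self) -> str:
        return "".join(
            r if len(cls) == 1 else "[" + "".join(sorted(cls)) + "]"
            for cls in self.residues
            for r in [min(cls)]
        )


def _prefix_masses(peptide: PeptideIon) -> np.ndarray:
    """Cumulative modified residue masses, length n."""
    seq = peptide.sequence
    masses = np.array([STANDARD_TABLE.mono(aa) for aa in seq])
    for mod in peptide.fixed_mods:
        for i, aa in enumerate(seq):
            if aa in mod.target_residues:
                masses[i] += mod.delta_mono
    return np.cumsum(masses)


def fragment_mz(peptide: PeptideIon, series: str, index: int, charge: int) -> float:
    """m/z of one product ion.

    b_i: N-terminal fragment of i residues; y_i: C-terminal fragment of i
    residues plus water; a = b - CO; z implemented as z-dot = y - 16.01872
    (loss of NH3 with retention of the radical hydrogen).
    """
    n = len(peptide.sequence)
    if not 1 <= index < n:
        raise ValueError(f"fragment index must be in [1, {n - 1}]")
    if charge < 1:
        raise ValueError("charge must be >= 1")
    prefix = _prefix_masses(peptide)
    if series in ("b", "a"):
        neutral = prefix[index - 1]
        mz = (neutral + charge * PROTON_MASS) / charge
        if series == "a":
            mz -= _CO / charge
        return mz
    if series in ("y", "z"):
        neutral = (prefix[-1] - prefix[n - index - 1]) + STANDARD_TABLE.water_mono
        mz = (neutral + charge * PROTON_MASS) / charge
        if series == "z":
            mz -= _Z_SHIFT / charge
        return mz
    raise ValueError(f"unknown ion series {series!r}")


def theoretical_ions(
    peptide: PeptideIon,
    series: Sequence[str] = ("b", "y"),
    charges: Sequence[int] = (1,),
) -> list[FragmentIon]:
    """All product ions of the requested series/charges, sorted by m/z."""
    ions = [
        FragmentIon(s, i, z, fragment_mz(peptide, s, i, z))
        for s in series
        for z in charges
        for i in range(1, len(peptide.sequence))
    ]
    ions.sort(key=lambda f: f.mz)
    return ions


@dataclass
class AnnotationResult:
    matches: list[tuple[int, FragmentIon]]  # (peak index, ion)
    fraction_b: float
    fraction_y: float


def annotate_spectrum(
    spectrum: Spectrum,
    peptide: PeptideIon,
    tol_mz: float = 0.3,
    series: Sequence[str] = ("b", "y"),
    charges: Sequence[int] = (1,),
) -> AnnotationResult:
    """Greedy nearest-first assignment of theoretical ions to peaks.

    Candidate (ion, peak) pairs within ``tol_mz`` are assigned in order of
    increasing |Δm/z|; each peak and each theoretical ion is used at most
    once.
    """
    if tol_mz <= 0:
        raise ValueError("tol_mz must be > 0")
    ions = theoretical_ions(peptide, series, charges)
    pairs: list[tuple[float, int, int]] = []
    for j, ion in enumerate(ions):
        lo = np.searchsorted(spectrum.mz, ion.mz - tol_mz, side="left")
        hi = np.searchsorted(spectrum.mz, ion.mz + tol_mz, side="right")
        for i in range(lo, hi):
            pairs.append((abs(spectrum.mz[i] - ion.mz), i, j))
    pairs.sort()
    used_peaks: set[int] = set()
    used_ions: set[int] = set()
    matches: list[tuple[int, FragmentIon]] = []
    for _, i, j in pairs:
        if i in used_peaks or j in used_ions:
            continue
        used_peaks.add(i)
        used_ions.add(j)
        matches.append((i, ions[j]))
    matches.sort(key=lambda m: m[0])
    n_frag = len(peptide.sequence) - 1

    def _frac(s: str) -> float:
        if s not in series or n_frag == 0:
            return 0.0
        found = {ion.index for _, ion in matches if ion.series == s}
        return len(found) / n_frag

    return AnnotationResult(matches, _frac("b"), _frac("y"))


def _residue_classes(tol_mz: float, mods: Iterable[ModificationSpec]) -> list[tuple[float, frozenset[str]]]:
    """(mass, ambiguity class) entries to interpret peak spacings.

    I/L are always merged; K/Q merge when the tolerance covers their mass
    gap. Fixed modifications add mass-shifted entries for their targets.
    """
    base: dict[str, float] = {
        aa: STANDARD_TABLE.mono(aa) for aa in STANDARD_TABLE.residues
    }
    for mod in mods:
        for aa in mod.target_residues:
            base[aa] = STANDARD_TABLE.mono(aa) + mod.delta_mono
    entries: list[tuple[float, frozenset[str]]] = []
    merged: dict[float, set[str]] = {}
    for aa, m in base.items():
        merged.setdefault(round(m, 6), set()).add(aa)  # fuses I/L
    for m, aas in merged.items():
        entries.append((m, frozenset(aas)))
    if tol_mz >= _KQ_GAP:
        out: list[tuple[float, frozenset[str]]] = []
        kq: list[tuple[float, frozenset[str]]] = []
        for m, cls in entries:
            (kq if cls & {"K", "Q"} else out).append((m, cls))
        if len(kq) == 2:
            mean_m = sum(m for m, _ in kq) / 2
            out.append((mean_m, frozenset().union(*(c for _, c in kq))))
            entries = out
    entries.sort()
    return entries


def deduce_tags(
    spectrum: Spectrum,
    tol_mz: float = 0.3,
    min_tag_len: int = 4,
    mods: Sequence[ModificationSpec] = (CARBAMIDOMETHYL,),
    max_paths: int = 200,
) -> list[SequenceTag]:
    """Read sequence tags from spacings between same-ladder peaks.

    Builds a directed acyclic gap graph over the peak list (edge i->j when
    mz_j - mz_i matches a residue mass, including fixed-mod shifts, within
    ``tol_mz``), then emits every maximal path of length >= ``min_tag_len``
    as a tag of ambiguity classes. Path enumeration is capped at
    ``max_paths`` to bound combinatorics on noisy spectra.
    """
    if tol_mz <= 0:
        raise ValueError("tol_mz must be > 0")
    classes = _residue_classes(tol_mz, mods)
    masses = np.array([m for m, _ in classes])
    mz = spectrum.mz
    n = mz.size
    edges: dict[int, list[tuple[int, frozenset[str]]]] = {i: [] for i in range(n)}
    has_incoming = np.zeros(n, dtype=bool)
    for i in range(n):
        gaps = mz - mz[i]
        lo = np.searchsorted(gaps, masses.min() - tol_mz)
        for j in range(max(lo, i + 1), n):
            gap = gaps[j]
            if gap > masses.max() + tol_mz:
                break
            hit = np.nonzero(np.abs(masses - gap) <= tol_mz)[0]
            if hit.size:
                cls = frozenset().union(*(classes[k][1] for k in hit))
                edges[i].append((j, cls))
                has_incoming[j] = True

    tags: list[SequenceTag] = []
    budget = [max_paths]

    def walk(node: int, path: list[frozenset[str]], start: int) -> None:
        if budget[0] <= 0:
            return
        nexts = edges[node]
        if not nexts:
            if len(path) >= min_tag_len:
                budget[0] -= 1
                tags.append(
                    SequenceTag(tuple(path), float(mz[start]), float(mz[node]))
                )
            return
        for j, cls in nexts:
            path.append(cls)
            walk(j, path, start)
            path.pop()

    for i in range(n):
        if not has_incoming[i] and edges[i]:
            walk(i, [], i)
    return tags


def read_mgf(path) -> list[Spectrum]:
    """Read centroided spectra from a Mascot generic format file."""
    spectra: list[Spectrum] = []
    with _mgf.MGF(str(path)) as reader:
        for entry in reader:
            params = entry["params"]
            charge = int(params.get("charge", [1])[0])
            spectra.append(
                Spectrum(
                    precursor_mz=float(params["pepmass"][0]),
                    precursor_charge=charge,
                    mz=entry["m/z array"],
                    intensity=entry["intensity array"],
                    title=str(params.get("title", "")),
                )
            )
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path) -> None:
    entries = [
        {
            "m/z array": s.mz,
            "intensity array": s.intensity,
            "params": {
                "title": s.title,
                "pepmass": s.precursor_mz,
                "charge": f"{s.precursor_charge}+",
            },
        }
        for s in spectra
    ]
    with open(path, "w") as fh:
        _mgf.write(entries, fh)
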