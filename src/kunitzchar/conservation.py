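"""Physico-chemical conservation scoring and the stability correlation.

Each alignment column is scored 0-11 in the style of AMAS: 11 is reserved
for strict gap-free identity, otherwise the score counts how many of ten
physico-chemical properties (hydrophobic, positive, negative, polar,
charged, small, tiny, aliphatic, aromatic, proline) are uniform across the
column — every residue has the property, or every residue lacks it. Gaps
annihilate conservation (score 0) by default.

Per-residue alanine-scan ΔΔG tables (kcal/mol, ΔG_mut − ΔG_wt) from the
homologs are mapped through the alignment, averaged per column, and
regressed on the conservation score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PropertyTable",
    "TAYLOR_PROPERTIES",
    "MultipleAlignment",
    "ConservationProfile",
    "DEFAULT_BINS",
    "amas_score_column",
    "score_alignment",
    "bin_scores",
    "map_positions_to_columns",
    "mean_ddg_per_column",
    "conservation_stability_regression",
]

GAP = "-"

_STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class PropertyTable:
    """Residue property memberships used for column scoring.

    Exactly ten properties; swappable because published descriptions of the
    scoring scheme name the properties but not their exact memberships.
    """

    properties: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        if len(self.properties) != 10:
            raise ValueError("property table must define exactly 10 properties")

    def items(self):
        return self.properties.items()


# Taylor/Zvelebil-style classification.
TAYLOR_PROPERTIES = PropertyTable(
    {
        "hydrophobic": frozenset("ACFGHIKLMTVWY"),
        "positive": frozenset("HKR"),
        "negative": frozenset("DE"),
        "polar": frozenset("CDEHKNQRSTWY"),
        "charged": frozenset("DEHKR"),
        "small": frozenset("ACDGNPSTV"),
        "tiny": frozenset("AGS"),
        "aliphatic": frozenset("ILV"),
        "aromatic": frozenset("FHWY"),
        "proline": frozenset("P"),
    }
)


@dataclass
class MultipleAlignment:
    """A gapped multiple sequence alignment ('-' gaps, equal-length rows)."""

    records: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise ValueError("alignment needs >= 2 rows")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            raise ValueError("alignment rows must have equal length")

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.records]

    def column(self, j: int) -> list[str]:
        return [seq[j] for _, seq in self.records]

    @classmethod
    def from_fasta(cls, path) -> "MultipleAlignment":
        from Bio import SeqIO

        records = [
            (rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fasta")
        ]
        return cls(records)


def amas_score_column(
    column: Sequence[str],
    table: PropertyTable = TAYLOR_PROPERTIES,
    gap_mode: str = "annihilate",
) -> int:
    """Score one alignment column on the 0-11 scale.

    ``gap_mode``: "annihilate" (default) makes any gap break every property
    so the column scores 0; "exclude" drops gaps before scoring (an
    all-gap column then scores 0).
    """
    if not column:
        raise ValueError("column must be non-empty")
    residues = [aa.upper() for aa in column]
    unknown = set(residues) - _STANDARD_RESIDUES - {GAP}
    if unknown:
        raise ValueError(f"unknown residue(s) in column: {sorted(unknown)}")
    if GAP in residues:
        if gap_mode == "annihilate":
            return 0
        residues = [aa for aa in residues if aa != GAP]
        if not residues:
            return 0
    kinds = set(residues)
    if len(kinds) == 1:
        return 11
    score = 0
    for _, members in table.items():
        flags = {aa in members for aa in kinds}
        if len(flags) == 1:
            score += 1
    return min(score, 10)


DEFAULT_BINS: tuple[tuple[int, int], ...] = ((9, 11), (5, 8), (2, 4), (0, 1))


@dataclass
class ConservationProfile:
    """Per-column conservation scores with the residue content behind them."""

    scores: np.ndarray
    columns: list[tuple[str, ...]]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=int)
        if np.any((self.scores < 0) | (self.scores > 11)):
            raise ValueError("scores must lie in [0, 11]")

    def __len__(self) -> int:
        return self.scores.size

    def histogram(self) -> np.ndarray:
        """Counts of columns at each score 0..11."""
        return np.bincount(self.scores, minlength=12)

    def bin_counts(
        self, bins: Sequence[tuple[int, int]] = DEFAULT_BINS
    ) -> dict[tuple[int, int], int]:
        assignment = bin_scores(self, bins)
        return {b: int(np.sum(assignment == i)) for i, b in enumerate(bins)}


def score_alignment(
    aln: MultipleAlignment,
    table: PropertyTable = TAYLOR_PROPERTIES,
    gap_mode: str = "annihilate",
) -> ConservationProfile:
    cols = [tuple(aln.column(j)) for j in range(aln.length)]
    scores = np.array(
        [amas_score_column(c, table, gap_mode) for c in cols], dtype=int
    )
    return ConservationProfile(scores, cols)


def bin_scores(
    profile: ConservationProfile,
    bins: Sequence[tuple[int, int]] = DEFAULT_BINS,
) -> np.ndarray:
    """Assign every column to exactly one score bin; bins must partition 0-11."""
    covered: list[int] = []
    for lo, hi in bins:
        covered.extend(range(lo, hi + 1))
    if sorted(covered) != list(range(12)):
        raise ValueError("bins must partition the score range 0-11 exactly")
    assignment = np.full(len(profile), -1, dtype=int)
    for i, (lo, hi) in enumerate(bins):
        assignment[(profile.scores >= lo) & (profile.scores <= hi)] = i
    return assignment


def map_positions_to_columns(aligned_seq: str) -> dict[int, int]:
    """1-based ungapped residue position -> 0-based alignment column."""
    mapping: dict[int, int] = {}
    pos = 0
    for j, aa in enumerate(aligned_seq):
        if aa != GAP:
            pos += 1
            mapping[pos] = j
    return mapping


def mean_ddg_per_column(
    ddg: pd.DataFrame,
    aln: MultipleAlignment,
) -> pd.DataFrame:
    """Average alanine-scan ΔΔG per alignment column across homologs.

    ``ddg`` has columns homolog_id, position (1-based on the ungapped
    homolog sequence), ddG_kcal_mol (wt_residue optional). Columns with no
    observation (e.g. Ala/Gly-only positions, where the Ala substitution is
    uninformative) come back with NaN mean and n_obs 0, flagged missing
    rather than zero.
    """
    required = {"homolog_id", "position", "ddG_kcal_mol"}
    missing = required - set(ddg.columns)
    if missing:
        raise ValueError(f"ddG table missing columns: {sorted(missing)}")
    maps = {rid: map_positions_to_columns(seq) for rid, seq in aln.records}
    sums = np.zeros(aln.length)
    counts = np.zeros(aln.length, dtype=int)
    for row in ddg.itertuples(index=False):
        try:
            mapping = maps[row.homolog_id]
        except KeyError:
            raise ValueError(f"homolog {row.homolog_id!r} not in alignment") from None
        pos = int(row.position)
        if pos not in mapping:
            raise ValueError(
                f"position {pos} outside ungapped length of {row.homolog_id!r}"
            )
        j = mapping[pos]
        sums[j] += float(row.ddG_kcal_mol)
        counts[j] += 1
    mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {
            "column": np.arange(aln.length),
            "mean_ddG_kcal_mol": mean,
            "n_obs": counts,
        }
    )


@dataclass(frozen=True)
class RegressionResult:
    r: float
    slope: float
    intercept: float
    n: int
    defined: bool = True


def conservation_stability_regression(
    profile: ConservationProfile,
    mean_ddg: pd.DataFrame,
) -> RegressionResult:
    """OLS of per-column mean ΔΔG on conservation score, with Pearson r.

    Columns lacking a ΔΔG observation are dropped. Zero variance in either
    variable leaves r undefined (NaN, ``defined=False``).
    """
    df = mean_ddg.dropna(subset=["mean_ddG_kcal_mol"])
    cols = df["column"].to_numpy(dtype=int)
    y = df["mean_ddG_kcal_mol"].to_numpy(dtype=float)
    x = profile.scores[cols].astype(float)
    if x.size < 3:
        raise ValueError("need >= 3 columns with both score and ΔΔG")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return RegressionResult(np.nan, np.nan, np.nan, x.size, defined=False)
    fit = stats.linregress(x, y)
    return RegressionResult(
        r=float(fit.rvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n=x.size,
    )
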