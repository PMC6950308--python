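"""Seeded generators for every input the pipeline consumes.

Each generator emulates the statistical structure its analysis stage
assumes — a transcriptome with one planted coding sequence among random
decoys, b/y-ladder MS/MS spectra with m/z jitter and decoy peaks,
Morrison-model dose-response curves with multiplicative noise,
Gaussian-fluctuation trajectories around a toy reference structure, and
conservation-correlated alanine-scan ΔΔG tables. Same seed + parameters
gives byte-identical output; every generator returns a ground-truth
manifest for round-trip tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .conservation import (
    MultipleAlignment,
    PropertyTable,
    TAYLOR_PROPERTIES,
    score_alignment,
)
from .kinetics import morrison_fraction
from .masses import CARBAMIDOMETHYL, ModificationSpec, tryptic_digest
from .spectra import Spectrum, fragment_mz
from .trajectory import Trajectory

__all__ = [
    "make_transcriptome",
    "make_spectra",
    "make_inhibition_data",
    "toy_structure",
    "make_trajectory",
    "make_homolog_alignment",
    "make_ddg_conservation",
]

_CODONS: dict[str, list[str]] = {}
from .proteogenomics import _CODON_TABLE, six_frame_translate  # noqa: E402

for codon, aa in _CODON_TABLE.items():
    _CODONS.setdefault(aa, []).append(codon)

_NT = np.array(list("ACGT"))


def _random_nt(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_NT, size=length, p=p))


def _reverse_complement(nt: str) -> str:
    return nt.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def make_transcriptome(
    planted_protein: str,
    n_decoys: int = 500,
    length_range: tuple[int, int] = (300, 3000),
    gc: float = 0.4,
    seed: int = 0,
    utr_range: tuple[int, int] = (30, 200),
) -> tuple[list[tuple[str, str]], dict]:
    """Nucleotide contigs with one planted coding sequence among decoys.

    The planted protein is back-translated with uniformly random synonymous
    codons, delimited by in-frame stop codons (so the translated open
    reading frame is exactly the planted chain), flanked by random UTRs and
    placed on a random strand. Decoy contigs are rejection-sampled so that
    none of their six reading frames contains any 8-mer of the planted
    protein.
    """
    rng = np.random.default_rng(seed)
    cds = "".join(
        _CODONS[aa][rng.integers(len(_CODONS[aa]))] for aa in planted_protein
    )
    utr5 = _random_nt(rng, int(rng.integers(*utr_range)), gc)
    utr3 = _random_nt(rng, int(rng.integers(*utr_range)), gc)
    contig = utr5 + "TAA" + cds + "TGA" + utr3
    strand = "-" if rng.random() < 0.5 else "+"
    if strand == "-":
        contig = _reverse_complement(contig)
    records = [("planted_contig", contig)]
    kmers = {
        planted_protein[i : i + 8] for i in range(len(planted_protein) - 7)
    }
    for d in range(n_decoys):
        while True:
            nt = _random_nt(rng, int(rng.integers(*length_range)), gc)
            frames = six_frame_translate(nt)
            if not any(k in frame for frame in frames for k in kmers):
                break
        records.append((f"decoy_{d:04d}", nt))
    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    manifest = {
        "planted_protein": planted_protein,
        "planted_contig_id": "planted_contig",
        "strand": strand,
        "utr5_len": len(utr5),
        "utr3_len": len(utr3),
        "n_decoys": n_decoys,
        "seed": seed,
    }
    return records, manifest


def default_charge(length: int) -> int:
    """Precursor charge model: clip(round(length / 7), 1, 5)."""
    return int(np.clip(round(length / 7), 1, 5))


def make_spectra(
    protein: str,
    max_missed: int = 1,
    min_length: int = 5,
    mods: Sequence[ModificationSpec] = (CARBAMIDOMETHYL,),
    n_decoy_peaks: int = 30,
    mz_jitter_sd: float = 0.01,
    seed: int = 0,
    mz_range: tuple[float, float] = (50.0, 1800.0),
) -> tuple[list[Spectrum], dict]:
    """One MS/MS spectrum per tryptic peptide of ``protein``.

    Each spectrum carries the full singly charged b/y ladders with Gaussian
    m/z jitter and log-normal intensities, plus uniformly placed decoy
    peaks; the precursor m/z follows the charge model and is jittered with
    the same SD.
    """
    rng = np.random.default_rng(seed)
    digest = tryptic_digest(protein, max_missed=max_missed,
                            min_length=min_length, mods=mods)
    spectra: list[Spectrum] = []
    truth: list[dict] = []
    for pep, mc in digest:
        n = len(pep.sequence)
        mz_list: list[float] = []
        for series in ("b", "y"):
            for i in range(1, n):
                mz_list.append(fragment_mz(pep, series, i, 1))
        mz = np.array(mz_list) + rng.normal(0.0, mz_jitter_sd, len(mz_list))
        inten = rng.lognormal(mean=8.0, sigma=1.0, size=mz.size)
        if n_decoy_peaks:
            decoy_mz = rng.uniform(*mz_range, size=n_decoy_peaks)
            decoy_int = rng.lognormal(mean=6.0, sigma=1.0, size=n_decoy_peaks)
            mz = np.concatenate([mz, decoy_mz])
            inten = np.concatenate([inten, decoy_int])
        charge = default_charge(n)
        prec = pep.mz if charge == 1 else (pep.neutral_mass + charge * 1.00728) / charge
        prec += rng.normal(0.0, mz_jitter_sd)
        title = f"pep_{pep.start_pos}_{pep.end_pos}"
        spectra.append(Spectrum(prec, charge, mz, inten, title=title))
        truth.append(
            {
                "sequence": pep.sequence,
                "start": pep.start_pos,
                "end": pep.end_pos,
                "missed": mc,
                "charge": charge,
                "title": title,
            }
        )
    manifest = {
        "protein": protein,
        "peptides": truth,
        "mz_jitter_sd": mz_jitter_sd,
        "n_decoy_peaks": n_decoy_peaks,
        "seed": seed,
    }
    return spectra, manifest


def make_inhibition_data(
    Ki_nM: float,
    E_nM: float,
    S_uM: float = 100.0,
    Km_uM: float = 200.0,
    I_grid_nM: Sequence[float] | None = None,
    noise_cv: float = 0.05,
    replicates: int = 1,
    v0: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Morrison-model dose-response table with multiplicative noise.

    rates = v0 * morrison_fraction(E, I, Ki*(1 + S/Km)) * (1 + eps),
    eps ~ Normal(0, noise_cv). The default inhibitor grid is a 12-point
    geometric series spanning from well below to well above max(Ki, E),
    plus a zero-inhibitor point.
    """
    if Ki_nM <= 0 or E_nM <= 0:
        raise ValueError("Ki and E must be > 0")
    rng = np.random.default_rng(seed)
    ki_app = Ki_nM * (1.0 + S_uM / Km_uM)
    if I_grid_nM is None:
        centre = max(ki_app, E_nM)
        I_grid_nM = np.concatenate(
            [[0.0], np.geomspace(centre / 50.0, centre * 50.0, 12)]
        )
    I = np.repeat(np.asarray(I_grid_nM, dtype=float), replicates)
    frac = morrison_fraction(E_nM, I, ki_app)
    rates = v0 * frac * (1.0 + rng.normal(0.0, noise_cv, I.size))
    df = pd.DataFrame({"inhibitor_nM": I, "rate": rates})
    manifest = {
        "Ki_nM": Ki_nM,
        "Ki_app_nM": ki_app,
        "E_nM": E_nM,
        "S_uM": S_uM,
        "Km_uM": Km_uM,
        "noise_cv": noise_cv,
        "replicates": replicates,
        "v0": v0,
        "seed": seed,
    }
    return df, manifest


def toy_structure(
    n_residues: int,
    chains: int = 1,
    spacing: float = 3.8,
    chain_offset: float = 5.0,
) -> Trajectory:
    """A minimal reference structure: N/CA/C/O backbone beads per residue.

    Residues are laid out along x at ``spacing`` Å; a second chain, if
    requested, runs parallel at ``chain_offset`` Å along z (close enough
    for an interface once atoms are moved). Single frame.
    """
    rows = []
    coords = []
    offsets = {"N": (-1.2, 0.6, 0.0), "CA": (0.0, 0.0, 0.0),
               "C": (1.2, 0.6, 0.0), "O": (1.4, 1.8, 0.0)}
    for c in range(chains):
        chain_id = chr(ord("A") + c)
        for r in range(n_residues):
            base = np.array([r * spacing, 0.0, c * chain_offset])
            for name, off in offsets.items():
                rows.append(
                    {
                        "name": name,
                        "element": name[0],
                        "resid": r + 1,
                        "resname": "GLY",
                        "chain": chain_id,
                    }
                )
                coords.append(base + np.array(off))
    atoms = pd.DataFrame(rows)
    return Trajectory(np.asarray(coords)[None, :, :], atoms)


def make_trajectory(
    reference: Trajectory,
    amplitudes: np.ndarray,
    n_frames: int = 5000,
    seed: int = 0,
    rigid_motion: bool = False,
    scripted_hbond: tuple[int, int, float] | None = None,
    bonded_distance: float = 2.9,
    broken_distance: float = 6.5,
) -> tuple[Trajectory, dict]:
    """Gaussian-fluctuation trajectory around a reference structure.

    ``amplitudes`` gives the per-residue, per-axis displacement SD (Å),
    indexed by residue order within each chain. ``rigid_motion`` applies an
    additional random global rotation+translation per frame (removed again
    by superposition). ``scripted_hbond`` = (donor_atom_index,
    acceptor_atom_index, fraction) pins the acceptor atom at
    ``bonded_distance`` from the donor in exactly round(fraction*n_frames)
    frames and at ``broken_distance`` otherwise.
    """
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(seed)
    ref = reference.coords[0]
    atoms = reference.atoms
    resids = atoms["resid"].to_numpy()
    chains = atoms["chain"].to_numpy()
    uniq = sorted(set(zip(chains, resids)))
    amplitudes = np.asarray(amplitudes, dtype=float)
    per_chain_index = {}
    for ch in sorted(set(chains)):
        ids = sorted({r for c, r in uniq if c == ch})
        for k, r in enumerate(ids):
            per_chain_index[(ch, r)] = k
    atom_sigma = np.array(
        [amplitudes[per_chain_index[(c, r)] % amplitudes.size]
         for c, r in zip(chains, resids)]
    )
    coords = ref[None, :, :] + rng.normal(
        0.0, 1.0, (n_frames, ref.shape[0], 3)
    ) * atom_sigma[None, :, None]

    present = None
    if scripted_hbond is not None:
        di, ai, fraction = scripted_hbond
        n_present = int(round(fraction * n_frames))
        present = np.zeros(n_frames, dtype=bool)
        present[rng.permutation(n_frames)[:n_present]] = True
        direction = np.array([0.0, 0.0, 1.0])
        for f in range(n_frames):
            d = bonded_distance if present[f] else broken_distance
            coords[f, ai] = coords[f, di] + direction * d

    if rigid_motion:
        for f in range(n_frames):
            rot = Rotation.random(rng=rng)
            shift = rng.normal(0.0, 5.0, 3)
            coords[f] = rot.apply(coords[f]) + shift

    traj = Trajectory(coords, atoms)
    manifest = {
        "amplitudes": amplitudes.tolist(),
        "n_frames": n_frames,
        "rigid_motion": rigid_motion,
        "seed": seed,
    }
    if scripted_hbond is not None:
        manifest["scripted_hbond"] = {
            "donor_atom": int(scripted_hbond[0]),
            "acceptor_atom": int(scripted_hbond[1]),
            "fraction": float(np.mean(present)),
        }
    return traj, manifest


_RESIDUE_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def make_homolog_alignment(
    length: int = 52,
    n_seqs: int = 14,
    seed: int = 0,
    conserved_fraction: float = 0.3,
) -> MultipleAlignment:
    """Gapless homolog family with a spread of column conservation levels.

    A fraction of columns is strictly conserved; the rest mutate away from
    the ancestral residue with a per-column probability drawn uniformly,
    giving scores across the whole 0-11 range.
    """
    rng = np.random.default_rng(seed)
    ancestor = rng.choice(list(_RESIDUE_ALPHABET), size=length)
    mut_p = rng.uniform(0.1, 0.9, size=length)
    mut_p[rng.random(length) < conserved_fraction] = 0.0
    rows = []
    for s in range(n_seqs):
        seq = ancestor.copy()
        mutate = rng.random(length) < mut_p
        if mutate.any():
            seq[mutate] = rng.choice(list(_RESIDUE_ALPHABET), size=mutate.sum())
        rows.append((f"hom_{s:02d}", "".join(seq)))
    return MultipleAlignment(rows)


def make_ddg_conservation(
    aln: MultipleAlignment,
    slope: float = 0.3,
    intercept: float = 0.2,
    noise_sd: float | None = 0.5,
    target_r: float | None = None,
    seed: int = 0,
    clamp: tuple[float, float] | None = None,
    table: PropertyTable = TAYLOR_PROPERTIES,
) -> tuple[pd.DataFrame, dict]:
    """Alanine-scan ΔΔG tables linearly coupled to column conservation.

    Per homolog and ungapped position (Ala/Gly positions skipped — no
    informative mutation), ΔΔG = intercept + slope*score + Normal(0, SD).
    With ``target_r`` given, the noise SD is solved analytically from the
    score variance and the per-column observation counts so that the
    column-mean regression has the requested expected Pearson r.
    ``clamp`` optionally truncates ΔΔG into a band.
    """
    rng = np.random.default_rng(seed)
    profile = score_alignment(aln, table)
    scores = profile.scores
    obs: list[tuple[str, int, str, int]] = []  # homolog, position, wt, column
    counts = np.zeros(aln.length, dtype=int)
    for rid, seq in aln.records:
        pos = 0
        for j, aa in enumerate(seq):
            if aa == "-":
                continue
            pos += 1
            if aa in ("A", "G"):
                continue
            obs.append((rid, pos, aa, j))
            counts[j] += 1
    if target_r is not None:
        observed_cols = counts > 0
        sx = float(np.std(scores[observed_cols]))
        if sx == 0:
            raise ValueError("score variance is zero; cannot calibrate r")
        mean_inv_k = float(np.mean(1.0 / counts[observed_cols]))
        noise_sd = abs(slope) * sx * np.sqrt(
            (1.0 / target_r**2 - 1.0) / mean_inv_k
        )
    if noise_sd is None:
        noise_sd = 0.0
    rows = []
    for rid, pos, aa, j in obs:
        val = intercept + slope * scores[j] + rng.normal(0.0, noise_sd)
        if clamp is not None:
            val = float(np.clip(val, *clamp))
        rows.append(
            {"homolog_id": rid, "position": pos, "wt_residue": aa,
             "ddG_kcal_mol": val}
        )
    df = pd.DataFrame(rows)
    manifest = {
        "slope": slope,
        "intercept": intercept,
        "noise_sd": float(noise_sd),
        "target_r": target_r,
        "clamp": list(clamp) if clamp else None,
        "seed": seed,
    }
    return df, manifest


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
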