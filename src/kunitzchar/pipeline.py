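"""End-to-end orchestration: spectra -> tags -> transcriptome -> chain.

`run_identification` chains the MS/MS stages into a single reproducible
report; `run_characterization` dispatches any subset of the downstream
stages (kinetics, conservation/stability, trajectory statistics) and
merges their outputs with input hashes and echoed parameters.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import conservation as cons
from . import kinetics as kin
from . import trajectory as trj
from .masses import CARBAMIDOMETHYL
from .proteogenomics import (
    reconstruct_sequence,
    search_tags,
    six_frame_translate,
    verify_candidate,
)
from .spectra import Spectrum, deduce_tags

logger = logging.getLogger("kunitzchar")

__all__ = ["IdentificationConfig", "run_identification", "run_characterization"]


@dataclass
class IdentificationConfig:
    """Tolerances and thresholds of the identification chain."""

    fragment_tol_mz: float = 0.3
    precursor_tol_mz: float = 0.5
    min_tag_len: int = 5
    tags_per_spectrum: int = 5  # longest tags kept per spectrum for search
    min_hit_tag_len: int = 6  # tag length that counts as candidate evidence
    min_candidate_len: int = 20  # shorter translated segments are discarded
    min_coverage: float = 0.5
    max_missed: int = 2

    def __post_init__(self) -> None:
        if self.fragment_tol_mz <= 0 or self.precursor_tol_mz <= 0:
            raise ValueError("tolerances must be > 0")


def _orf_segments(protein: str, min_len: int) -> list[tuple[int, str]]:
    """Stop-free segments (offset, sequence) of a translated frame."""
    out = []
    start = 0
    for part in protein.split("*"):
        if len(part) >= min_len and "X" not in part:
            out.append((start, part))
        start += len(part) + 1
    return out


def run_identification(
    spectra: Sequence[Spectrum],
    transcriptome: Sequence[tuple[str, str]],
    config: IdentificationConfig | None = None,
) -> dict:
    """Identify and reconstruct the protein behind a set of MS/MS spectra.

    Tags deduced from each spectrum are searched in all six reading frames
    of every contig (stop codons truncate candidates); candidates with tag
    evidence are verified against the observed precursors by in-silico
    digestion, and the best-covered candidate is assembled into a chain
    whose intact average mass is reported. Returns a JSON-ready dict; when
    no candidate reaches the minimum coverage the result states
    ``identified: False`` rather than raising.
    """
    cfg = config or IdentificationConfig()
    t0 = time.perf_counter()
    all_tags = []
    for sp in spectra:
        tags = deduce_tags(sp, tol_mz=cfg.fragment_tol_mz,
                           min_tag_len=cfg.min_tag_len)
        tags.sort(key=len, reverse=True)
        all_tags.extend(tags[: cfg.tags_per_spectrum])
    logger.info("deduced %d tags from %d spectra", len(all_tags), len(spectra))

    candidates: list[tuple[str, str]] = []
    for cid, nt in transcriptome:
        for frame_idx, prot in enumerate(six_frame_translate(nt)):
            for off, seg in _orf_segments(prot, cfg.min_candidate_len):
                candidates.append((f"{cid}|frame{frame_idx + 1}|off{off}", seg))
    hits = search_tags(candidates, all_tags)
    by_candidate: dict[str, list] = {}
    strong_evidence: dict[str, int] = {}
    for h in hits:
        by_candidate.setdefault(h.protein_id, []).append(h)
        if len(h.tag) >= cfg.min_hit_tag_len:
            strong_evidence[h.protein_id] = strong_evidence.get(h.protein_id, 0) + 1
    seqs = dict(candidates)
    precursors = [(sp.precursor_mz, sp.precursor_charge) for sp in spectra]

    verified = []
    for pid in strong_evidence:
        cand = verify_candidate(
            seqs[pid], precursors, tol_mz=cfg.precursor_tol_mz,
            mods=(CARBAMIDOMETHYL,), max_missed=cfg.max_missed,
            source_id=pid,
        )
        verified.append(cand)
    verified.sort(key=lambda c: (-c.coverage, -len(c.matched)))

    report: dict = {
        "n_spectra": len(spectra),
        "n_tags": len(all_tags),
        "n_candidates_searched": len(candidates),
        "n_candidates_with_tag_evidence": len(strong_evidence),
        "parameters": vars(cfg).copy(),
        "elapsed_s": None,
        "identified": False,
    }
    per_candidate = []
    for cand in verified[:5]:
        per_candidate.append(
            {
                "candidate": cand.source_id,
                "length": len(cand.sequence),
                "tag_hits": len(by_candidate.get(cand.source_id, [])),
                "matched_precursors": len(cand.matched),
                "coverage": cand.coverage,
            }
        )
    report["candidates"] = per_candidate

    if verified and verified[0].coverage >= cfg.min_coverage:
        best = verified[0]
        unique = (
            len(verified) == 1
            or (len(verified) > 1 and verified[1].coverage < cfg.min_coverage)
        )
        assembly = reconstruct_sequence([m.peptide for m in best.matched])
        report.update(
            {
                "identified": True,
                "unique": unique,
                "best_candidate": best.source_id,
                "assembled_sequence": assembly.sequence,
                "assembly_start": assembly.segment_start,
                "unresolved_positions": assembly.unresolved_positions,
                "coverage": best.coverage,
                "intact_average_mass_Da": round(assembly.average_mass, 2),
                "matched_peptides": [
                    {
                        "sequence": m.peptide.sequence,
                        "start": m.peptide.start_pos,
                        "end": m.peptide.end_pos,
                        "charge": m.observed_charge,
                        "observed_mz": m.observed_mz,
                        "delta_mz": m.delta_mz,
                    }
                    for m in best.matched
                ],
            }
        )
    report["elapsed_s"] = round(time.perf_counter() - t0, 3)
    return report


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_characterization(
    assay_path: Path | None = None,
    assay_context: dict | None = None,
    alignment_path: Path | None = None,
    ddg_path: Path | None = None,
    trajectory_path: Path | None = None,
    hbond_params: dict | None = None,
) -> dict:
    """Dispatch any subset of the downstream characterization stages.

    Stage failures are isolated into an ``errors`` section; the report
    carries input hashes and echoed parameters for reproducibility.
    """
    report: dict = {"inputs": {}, "errors": {}}
    for label, p in (
        ("assay", assay_path),
        ("alignment", alignment_path),
        ("ddg", ddg_path),
        ("trajectory", trajectory_path),
    ):
        if p is not None:
            report["inputs"][label] = {"path": str(p), "sha256": _sha256(p)}

    if assay_path is not None:
        try:
            df = pd.read_csv(assay_path, sep=None, engine="python")
            ctx = assay_context or {}
            res = kin.MorrisonKiModel.from_dataframe(df, **ctx).fit()
            report["kinetics"] = {
                "Ki_nM": res.ki,
                "Ki_SE_nM": res.ki_se,
                "Ki_app_nM": res.ki_app,
                "converged": res.converged,
                "context": ctx,
            }
        except Exception as exc:  # isolate stage failure
            report["errors"]["kinetics"] = str(exc)

    profile = None
    if alignment_path is not None:
        try:
            aln = cons.MultipleAlignment.from_fasta(alignment_path)
            profile = cons.score_alignment(aln)
            report["conservation"] = {
                "n_columns": len(profile),
                "histogram": profile.histogram().tolist(),
                "bin_counts": {
                    f"{lo}-{hi}": n
                    for (lo, hi), n in profile.bin_counts().items()
                },
            }
            if ddg_path is not None:
                ddg = pd.read_csv(ddg_path, sep="\t")
                per_col = cons.mean_ddg_per_column(ddg, aln)
                reg = cons.conservation_stability_regression(profile, per_col)
                report["stability_correlation"] = {
                    "pearson_r": reg.r,
                    "slope_kcal_per_score": reg.slope,
                    "intercept_kcal": reg.intercept,
                    "n_columns": reg.n,
                }
        except Exception as exc:
            report["errors"]["conservation"] = str(exc)

    if trajectory_path is not None:
        try:
            traj = trj.read_multimodel_pdb(trajectory_path)
            aligned, rmsd = trj.superpose_frames(
                traj, selection=traj.select(name="CA")
            )
            prof = trj.rmsf(aligned)
            hb = trj.hbond_occupancy(traj, **(hbond_params or {}))
            report["trajectory"] = {
                "n_frames": traj.n_frames,
                "n_atoms": traj.n_atoms,
                "mean_rmsd_A": float(np.mean(rmsd)),
                "rmsf_A": prof.table.to_dict(orient="records"),
                "n_hbonds_reported": int(
                    (hb["occupancy"] >= trj.REPORTED_OCCUPANCY).sum()
                ) if len(hb) else 0,
                "mean_hbonds_per_frame": float(hb["occupancy"].sum())
                if len(hb) else 0.0,
            }
        except Exception as exc:
            report["errors"]["trajectory"] = str(exc)

    return report
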