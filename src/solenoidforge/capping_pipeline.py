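"""Three-stage capping cascade for β-solenoid designs.

Uncapped β-solenoids expose the hydrophobic cross-section of their
terminal repeats, a major aggregation liability.  The cascade addresses
this by (1) checking each backbone is designable at the stricter capping
thresholds, (2) generating and filtering N-terminal caps, then (3)
repeating the process for C-terminal caps on the surviving N-capped
structures.  Every stage applies the same structural gates — RMSD to the
designed backbone below 2 Å, mean pAE below 5 Å both overall and over
the cap region alone, and above-0.80 pLDDT from two independent
predictors — so the survivor set can only shrink stage by stage.  Final
selection additionally requires an in silico melting point (Succ50)
above 0.71 and keeps one representative per structural cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design_scoring import CapFilterReport, evaluate_cap_filter, kabsch_rmsd
from .errors import IncompleteReportError, InvalidInputError, SolenoidForgeError
from .oracle_interfaces import CapGenerator, SequenceDesigner, StructurePredictor
from .structure_space import StructureSimilarityMatrix, greedy_cluster

STAGE_DESIGNABILITY = "designability"
STAGE_N_CAP = "n_cap"
STAGE_C_CAP = "c_cap"

#: Cap length multiplier switches from 2x to 4x at and below this repeat
#: length ("5mer repeats" need longer caps to cover the exposed rung).
SHORT_REPEAT_THRESHOLD = 5


def cap_length_for(repeat_length: int, short_threshold: int = SHORT_REPEAT_THRESHOLD) -> int:
    """Cap length in residues: twice the repeat, four times for short repeats."""
    if repeat_length < 1:
        raise InvalidInputError(f"repeat_length must be >= 1, got {repeat_length}")
    return 4 * repeat_length if repeat_length <= short_threshold else 2 * repeat_length


def ss_pattern(length: int) -> str:
    """Secondary-structure conditioning string: 'HXX' tiled to ``length``.

    H requests a helix, X leaves the position unconstrained — a helical
    bias without forcing one long helix.  The tiling is truncated, not
    padded, when ``length`` is not a multiple of three.
    """
    if length < 1:
        raise InvalidInputError(f"pattern length must be >= 1, got {length}")
    reps = -(-length // 3)
    return ("HXX" * reps)[:length]


@dataclass(frozen=True)
class Backbone:
    """One uncapped solenoid backbone entering the cascade."""

    backbone_id: str
    coords: np.ndarray  # (n, 3) Å
    repeat_length: int


@dataclass(frozen=True)
class CappingConfig:
    n_redesigns: int = 10
    n_caps: int = 10
    n_cap_sequences: int = 10
    temperature: float = 0.2
    forbid: frozenset = frozenset("C")


@dataclass(frozen=True)
class CappingOracles:
    """The oracle bundle the cascade consumes (all injected)."""

    predictor_a: StructurePredictor  # e.g. AF2/ColabFold
    predictor_b: StructurePredictor  # e.g. ESMFold
    designer: SequenceDesigner
    cap_generator: CapGenerator


@dataclass
class CapDesignRecord:
    """One cap candidate (a capped structure) with its filtered sequences."""

    backbone_id: str
    terminal: str  # "N" or "C"
    cap_index: int
    cap_length: int
    ss_pattern: str
    coords: np.ndarray
    sequences: list[str] = field(default_factory=list)
    reports: list[CapFilterReport] = field(default_factory=list)

    @property
    def design_id(self) -> str:
        return f"{self.backbone_id}/{self.terminal}cap{self.cap_index}"

    @property
    def passed(self) -> bool:
        return any(r.passes_structural for r in self.reports)

    @property
    def best_mean_pae(self) -> float:
        passing = [r.mean_pae_full for r in self.reports if r.passes_structural]
        return min(passing) if passing else float("nan")


@dataclass
class CappingOutcome:
    survivors: list[CapDesignRecord]  # fully capped records that passed
    stage_counts: dict[str, int]  # candidates entering each stage
    log: pd.DataFrame  # one row per (candidate, sequence) with gate booleans


def _assess_sequence(
    sequence: str,
    reference: np.ndarray,
    cap_region: tuple[int, int] | None,
    oracles: CappingOracles,
) -> CapFilterReport:
    """Repredict one sequence with both predictors and gate it."""
    ens_a = oracles.predictor_a.predict(sequence, mode="repredict")
    ens_b = oracles.predictor_b.predict(sequence, mode="repredict")
    best = ens_a.best_model()
    pae = best.pae
    if cap_region is not None:
        lo, hi = cap_region
        pae_terminal = float(pae[lo:hi, lo:hi].mean())
    else:
        # No cap yet: the terminal gate degenerates to the full-structure one.
        pae_terminal = float(pae.mean())
    return evaluate_cap_filter(
        rmsd_to_backbone=kabsch_rmsd(best.ca_coords, reference),
        mean_pae_full=float(pae.mean()),
        mean_pae_terminal=pae_terminal,
        plddt_predictor_a=ens_a.mean_plddt,
        plddt_predictor_b=ens_b.mean_plddt,
    )


def _log_row(
    backbone_id: str, stage: str, parent: str, candidate: int, seq_idx: int,
    r: CapFilterReport
) -> dict:
    return {
        "backbone_id": backbone_id,
        "stage": stage,
        "parent": parent,
        "candidate": candidate,
        "sequence_index": seq_idx,
        "rmsd_to_backbone": r.rmsd_to_backbone,
        "mean_pae_full": r.mean_pae_full,
        "mean_pae_terminal": r.mean_pae_terminal,
        "plddt_predictor_a": r.plddt_predictor_a,
        "plddt_predictor_b": r.plddt_predictor_b,
        "pass_rmsd": r.rmsd_to_backbone < 2.0,
        "pass_pae_full": r.mean_pae_full < 5.0,
        "pass_pae_terminal": r.mean_pae_terminal < 5.0,
        "pass_plddt_a": r.plddt_predictor_a > 0.80,
        "pass_plddt_b": r.plddt_predictor_b > 0.80,
        "passes_structural": r.passes_structural,
    }


def run_capping(
    backbones: Sequence[Backbone],
    oracles: CappingOracles,
    config: CappingConfig = CappingConfig(),
) -> CappingOutcome:
    """Run designability → N-cap → C-cap over a set of backbones.

    Returns the fully capped surviving records, the number of backbones
    entering each stage, and a flat per-sequence log with individual
    gate booleans so failures can be attributed to a specific criterion.
    """
    rows: list[dict] = []
    stage_counts = {
        STAGE_DESIGNABILITY: len(backbones),
        STAGE_N_CAP: 0,
        STAGE_C_CAP: 0,
    }
    survivors: list[CapDesignRecord] = []

    for backbone in backbones:
        try:
            # Stage 1: designability at capping thresholds.
            seqs = oracles.designer.design(
                backbone.coords, config.n_redesigns, config.temperature, config.forbid
            )
            designable = False
            for i, seq in enumerate(seqs):
                report = _assess_sequence(seq, backbone.coords, None, oracles)
                rows.append(_log_row(backbone.backbone_id, STAGE_DESIGNABILITY, "-", 0, i, report))
                designable = designable or report.passes_structural
            if not designable:
                continue

            stage_counts[STAGE_N_CAP] += 1
            n_capped = _cap_stage(backbone, backbone.coords, "N", "-", oracles, config, rows)
            if not n_capped:
                continue

            stage_counts[STAGE_C_CAP] += 1
            for n_record in n_capped:
                c_capped = _cap_stage(
                    backbone, n_record.coords, "C", f"N{n_record.cap_index}",
                    oracles, config, rows,
                )
                survivors.extend(c_capped)
        except SolenoidForgeError as err:
            err.backbone_id = backbone.backbone_id
            raise
    return CappingOutcome(survivors=survivors, stage_counts=stage_counts, log=pd.DataFrame(rows))


def _cap_stage(
    backbone: Backbone,
    start_coords: np.ndarray,
    terminal: str,
    parent: str,
    oracles: CappingOracles,
    config: CappingConfig,
    rows: list[dict],
) -> list[CapDesignRecord]:
    """Generate, redesign and filter caps on one terminal; return survivors."""
    length = cap_length_for(backbone.repeat_length)
    pattern = ss_pattern(length)
    capped_structs = oracles.cap_generator.generate_caps(
        start_coords, terminal, length, pattern, config.n_caps
    )
    stage = STAGE_N_CAP if terminal == "N" else STAGE_C_CAP
    survivors = []
    for c_idx, coords in enumerate(capped_structs):
        n_total = coords.shape[0]
        cap_region = (0, length) if terminal == "N" else (n_total - length, n_total)
        record = CapDesignRecord(
            backbone_id=backbone.backbone_id,
            terminal=terminal,
            cap_index=c_idx,
            cap_length=length,
            ss_pattern=pattern,
            coords=coords,
        )
        seqs = oracles.designer.design(
            coords, config.n_cap_sequences, config.temperature, config.forbid
        )
        for s_idx, seq in enumerate(seqs):
            report = _assess_sequence(seq, coords, cap_region, oracles)
            record.sequences.append(seq)
            record.reports.append(report)
            rows.append(_log_row(backbone.backbone_id, stage, parent, c_idx, s_idx, report))
        if record.passed:
            survivors.append(record)
    return survivors


@dataclass(frozen=True)
class FinalCandidate:
    """A fully filtered design entering the diversity selection."""

    design_id: str
    mean_pae: float


def select_final_designs(
    candidates: Sequence[FinalCandidate],
    tm_matrix: StructureSimilarityMatrix,
    succ50_values: Mapping[str, float],
    tm_threshold: float = 0.7,
    min_succ50: float = 0.71,
) -> list[str]:
    """Apply the melting gate, then keep one design per structural cluster.

    Candidates must carry a Succ50 value strictly above ``min_succ50``;
    survivors are clustered greedily at ``tm >= tm_threshold`` and the
    representative of each cluster is the member with the highest
    Succ50, ties broken by the lower mean pAE.
    """
    missing = [c.design_id for c in candidates if c.design_id not in succ50_values]
    if missing:
        raise IncompleteReportError(f"missing Succ50 for: {missing}")
    survivors = [c for c in candidates if succ50_values[c.design_id] > min_succ50]
    if not survivors:
        return []
    ids = [c.design_id for c in survivors]
    sub = tm_matrix.subset(ids)
    assignment = greedy_cluster(sub, threshold=tm_threshold)
    by_id = {c.design_id: c for c in survivors}
    chosen = []
    for rep in sorted(set(assignment.values())):
        members = [by_id[i] for i, r in assignment.items() if r == rep]
        best = max(members, key=lambda c: (succ50_values[c.design_id], -c.mean_pae))
        chosen.append(best.design_id)
    return chosen
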