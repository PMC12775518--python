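"""Fitness computation, threshold gates, Kabsch RMSD and filter cascades.

The optimisation objective is a single 0-1 score: the equal-weight mean
of (i) ensemble-averaged pLDDT and (ii) the solenoid discriminator score
for the target class.  All downstream filters (designability, cap gates)
are pure functions of their metric inputs with strict inequalities
throughout, so the same report always yields the same booleans.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import IncompleteReportError, InvalidInputError, InvalidStateError
from .oracle_interfaces import (
    DESIGN_MODE_MODELS,
    OracleEnsemble,
    SOLENOID_CLASSES,
    SolenoidProfile,
    StructurePredictor,
)
from .repeat_sequences import RepeatSpec, SolenoidClass

# Designability gate for redesigned sequences: the predicted structure
# must sit within 5 Å of the parent backbone and average above 0.80
# pLDDT (0-1 scale) over all models.
DESIGNABLE_MAX_RMSD = 5.0
DESIGNABLE_MIN_PLDDT = 0.80

# Cap-cascade structural gates.
CAP_MAX_RMSD = 2.0
CAP_MAX_PAE = 5.0
CAP_MIN_PLDDT = 0.80
CAP_MIN_SUCC50 = 0.71


@dataclass(frozen=True)
class FitnessReport:
    """Scores for one candidate: components, combined fitness, pass flag."""

    plddt_mean: float
    solenoid_score: float
    per_model_plddt: tuple[float, ...]
    passes: bool

    @property
    def fitness(self) -> float:
        return 0.5 * (self.plddt_mean + self.solenoid_score)


@dataclass(frozen=True)
class RedesignResult:
    """One redesigned sequence repredicted against its parent backbone."""

    sequence: str
    mean_plddt: float  # 0-1 scale
    rmsd_to_parent: float  # Å

    @property
    def designable(self) -> bool:
        return (
            self.rmsd_to_parent < DESIGNABLE_MAX_RMSD
            and self.mean_plddt > DESIGNABLE_MIN_PLDDT
        )


@dataclass(frozen=True)
class CapFilterReport:
    """Metric bundle and gate outcomes for one capped-design candidate.

    ``passes_structural`` combines the backbone-agreement and confidence
    gates; ``passes_final`` additionally requires the in silico melting
    point (Succ50) to clear its threshold.  Boundary values fail: every
    comparison is strict.
    """

    rmsd_to_backbone: float
    mean_pae_full: float
    mean_pae_terminal: float
    plddt_predictor_a: float
    plddt_predictor_b: float
    succ50: Optional[float] = None

    @property
    def passes_structural(self) -> bool:
        return (
            self.rmsd_to_backbone < CAP_MAX_RMSD
            and self.mean_pae_full < CAP_MAX_PAE
            and self.mean_pae_terminal < CAP_MAX_PAE
            and self.plddt_predictor_a > CAP_MIN_PLDDT
            and self.plddt_predictor_b > CAP_MIN_PLDDT
        )

    @property
    def passes_final(self) -> bool:
        if self.succ50 is None:
            raise IncompleteReportError(
                "final cap gate requested but succ50 is missing from the report"
            )
        return self.passes_structural and self.succ50 > CAP_MIN_SUCC50


def solenoid_score(
    profiles: Sequence[SolenoidProfile], target_class: SolenoidClass
) -> float:
    """Fraction of residues classified as the target solenoid class.

    Per model, each residue's probability row is hardened with argmax to
    a one-hot classification; the score is the fraction of residues
    whose hardened class equals the target, averaged over models.
    Argmax ties break toward the lowest class index in the fixed order
    (alpha, beta, alphabeta, non_solenoid).
    """
    if not profiles:
        raise InvalidInputError("at least one profile required")
    target_idx = SOLENOID_CLASSES.index(SolenoidClass(target_class).value)
    per_model = []
    for profile in profiles:
        hardened = np.argmax(profile.probabilities, axis=1)  # first max on ties
        per_model.append(float(np.mean(hardened == target_idx)))
    return float(np.mean(per_model))


def score_candidate(
    ensemble: OracleEnsemble,
    profiles: Sequence[SolenoidProfile],
    spec: RepeatSpec,
) -> FitnessReport:
    """Combine predictor confidence and discriminator score into fitness."""
    per_model = tuple(float(p) for p in ensemble.per_model_plddt)
    sol = solenoid_score(profiles, spec.target_class)
    report = FitnessReport(
        plddt_mean=float(np.mean(per_model)),
        solenoid_score=sol,
        per_model_plddt=per_model,
        passes=False,
    )
    return FitnessReport(
        plddt_mean=report.plddt_mean,
        solenoid_score=sol,
        per_model_plddt=per_model,
        passes=passes_design_threshold(report, spec),
    )


def passes_design_threshold(report: FitnessReport, spec: RepeatSpec) -> bool:
    """True iff every model clears the pLDDT gate and the solenoid score
    reaches the class threshold.

    All five ensemble members must individually exceed ``spec.min_plddt``
    (default 0.70); the discriminator score must reach
    ``spec.min_solenoid_score`` (0.6 for α/β targets, 0.7 for αβ).
    """
    if len(report.per_model_plddt) < DESIGN_MODE_MODELS:
        raise InvalidStateError(
            f"design mode requires {DESIGN_MODE_MODELS} per-model pLDDT values, "
            f"got {len(report.per_model_plddt)}"
        )
    all_models_pass = all(p > spec.min_plddt for p in report.per_model_plddt)
    return all_models_pass and report.solenoid_score >= spec.min_solenoid_score


def kabsch_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Minimum Cα RMSD over proper rotations and translations, in Å.

    Standard Kabsch superposition: centre both point sets, compute the
    optimal rotation from the SVD of the covariance matrix, and apply the
    determinant correction so a reflection is never used — mirror-image
    structures must not score zero.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise InvalidInputError(f"coordinate sets must share shape (n,3); got {a.shape} vs {b.shape}")
    n = a.shape[0]
    if n < 3:
        raise InvalidInputError(f"need at least 3 points, got {n}")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    h = ac.T @ bc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    # Flip the smallest singular direction if the raw solution is improper.
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    # Residuals after applying the rotation: numerically exact near zero,
    # unlike the trace formula, which cancels catastrophically there.
    diff = ac @ rot.T - bc
    return float(np.sqrt(np.sum(diff**2) / n))


def rank_redesigns(
    parent_backbone: np.ndarray,
    sequences: Sequence[str],
    predictor: StructurePredictor,
) -> list[RedesignResult]:
    """Repredict redesigned sequences and rank them against the parent.

    Each sequence is repredicted (3-recycle mode); its mean pLDDT is the
    average over residues then models, and its RMSD is the Kabsch
    superposition of the highest-confidence model's Cα trace onto the
    parent backbone.  Ordering: designable results first, then by
    descending pLDDT, then ascending RMSD.
    """
    results = []
    for seq in sequences:
        ensemble = predictor.predict(seq, mode="repredict")
        best = ensemble.best_model()
        results.append(
            RedesignResult(
                sequence=seq,
                mean_plddt=ensemble.mean_plddt,
                rmsd_to_parent=kabsch_rmsd(best.ca_coords, parent_backbone),
            )
        )
    return sorted(
        results, key=lambda r: (not r.designable, -r.mean_plddt, r.rmsd_to_parent)
    )


def is_designable_backbone(results: Sequence[RedesignResult]) -> bool:
    """A backbone is designable if any redesign refolds onto it.

    "Refolds" means the repredicted structure lies within 5 Å RMSD of
    the original backbone with mean pLDDT above 0.80.
    """
    if not results:
        raise InvalidInputError("designability needs at least one redesign result")
    return any(r.designable for r in results)


def evaluate_cap_filter(
    rmsd_to_backbone: float,
    mean_pae_full: float,
    mean_pae_terminal: float,
    plddt_predictor_a: float,
    plddt_predictor_b: float,
    succ50: Optional[float] = None,
    require_final: bool = False,
) -> CapFilterReport:
    """Assemble a cap-filter report and optionally demand the final gate.

    With ``require_final`` the report must include a Succ50 value;
    otherwise the structural gates alone are decidable and the melting
    gate is deferred.
    """
    report = CapFilterReport(
        rmsd_to_backbone=rmsd_to_backbone,
        mean_pae_full=mean_pae_full,
        mean_pae_terminal=mean_pae_terminal,
        plddt_predictor_a=plddt_predictor_a,
        plddt_predictor_b=plddt_predictor_b,
        succ50=succ50,
    )
    if require_final:
        report.passes_final  # raises IncompleteReportError when succ50 is absent
    return report
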