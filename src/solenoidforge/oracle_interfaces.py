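"""Oracle contracts and deterministic surrogate implementations.

The design loop consumes four neural oracles — a structure predictor, a
solenoid-class discriminator, an inverse-folding sequence designer, and a
terminal-cap generator — strictly through the protocols defined here.
The pipeline never imports a concrete predictor; adapters are injected.

The surrogate ("mock") oracles implement a transparent fitness landscape:
a hidden target repeat unit defines a match fraction ``q`` for any
candidate, and every confidence metric is a fixed monotone function of
``q``.  That monotonicity is the property the evolution-engine
convergence tests rely on.  Real adapters (ColabFold/AF2, ESMFold,
ProteinMPNN, ProteinGenerator, SOLeNNoID) are subprocess wrappers that
raise :class:`~solenoidforge.errors.OracleUnavailableError` when their
backend is absent — never a silent fallback.
"""

from __future__ import annotations

import shutil
import zlib
from dataclasses import dataclass
from typing import Iterable, Protocol, Sequence, runtime_checkable

import numpy as np

from .errors import InvalidInputError, OracleUnavailableError
from .fixtures import synth_solenoid_coords
from .repeat_sequences import AMINO_ACIDS, RepeatUnit, SolenoidClass

#: Fixed order of discriminator classes in every probability row.
SOLENOID_CLASSES = ("alpha", "beta", "alphabeta", "non_solenoid")

#: Per-model confidence offsets for the surrogate ensemble.  Non-zero so
#: the "all models must pass" gate is exercised non-trivially: the worst
#: model sits 0.02 below the ensemble mean.
MOCK_MODEL_OFFSETS = (-0.02, -0.01, 0.0, 0.01, 0.02)

#: Number of predictor models in design mode.
DESIGN_MODE_MODELS = 5


@dataclass(frozen=True)
class StructurePrediction:
    """One predictor model's output for a single sequence.

    ``plddt`` and ``ptm`` are stored on the 0-1 scale; adapters that
    receive 0-100 pLDDT convert at the boundary.  ``pae`` is in Å.
    """

    model_id: int
    ca_coords: np.ndarray  # (n, 3) Å
    plddt: np.ndarray  # (n,) fractions
    pae: np.ndarray  # (n, n) Å
    ptm: float

    def __post_init__(self) -> None:
        n = self.ca_coords.shape[0]
        if self.ca_coords.ndim != 2 or self.ca_coords.shape[1] != 3:
            raise InvalidInputError("ca_coords must be (n, 3)")
        if self.plddt.shape != (n,):
            raise InvalidInputError("plddt length must equal coordinate rows")
        if self.pae.shape != (n, n):
            raise InvalidInputError("pae must be square n x n")
        if np.any(self.plddt < 0) or np.any(self.plddt > 1):
            raise InvalidInputError("plddt values must be fractions in [0,1]")
        if not 0.0 <= self.ptm <= 1.0:
            raise InvalidInputError(f"ptm must be in [0,1], got {self.ptm}")
        if np.any(self.pae < 0):
            raise InvalidInputError("pae entries must be non-negative")

    @property
    def n_residues(self) -> int:
        return self.ca_coords.shape[0]

    @property
    def mean_plddt(self) -> float:
        return float(self.plddt.mean())


@dataclass(frozen=True)
class SolenoidProfile:
    """Per-residue class probabilities over (alpha, beta, alphabeta, non)."""

    probabilities: np.ndarray  # (n, 4)

    def __post_init__(self) -> None:
        p = self.probabilities
        if p.ndim != 2 or p.shape[1] != len(SOLENOID_CLASSES):
            raise InvalidInputError("profile must be (n, 4)")
        if p.shape[0] == 0:
            raise InvalidInputError("profile must cover at least one residue")
        if np.any(p < 0) or np.any(p > 1):
            raise InvalidInputError("probabilities must lie in [0,1]")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
            raise InvalidInputError("each residue's probabilities must sum to 1")

    @property
    def n_residues(self) -> int:
        return self.probabilities.shape[0]


@dataclass(frozen=True)
class OracleEnsemble:
    """All predictor models' outputs for one sequence."""

    predictions: tuple[StructurePrediction, ...]

    def __post_init__(self) -> None:
        if not self.predictions:
            raise InvalidInputError("ensemble must contain at least one model")
        n = self.predictions[0].n_residues
        if any(p.n_residues != n for p in self.predictions):
            raise InvalidInputError("all ensemble members must share residue count")

    @property
    def n_residues(self) -> int:
        return self.predictions[0].n_residues

    @property
    def per_model_plddt(self) -> np.ndarray:
        return np.array([p.mean_plddt for p in self.predictions])

    @property
    def mean_plddt(self) -> float:
        """Mean over residues within each model, then over models."""
        return float(self.per_model_plddt.mean())

    def best_model(self) -> StructurePrediction:
        """The member with the highest mean pLDDT (first on ties)."""
        return self.predictions[int(np.argmax(self.per_model_plddt))]


@runtime_checkable
class StructurePredictor(Protocol):
    def predict(self, sequence: str, mode: str = "design") -> OracleEnsemble:
        """Predict structure; ``mode`` is 'design' (5 models, 1 recycle)
        or 'repredict' (3 recycles)."""
        ...


@runtime_checkable
class SolenoidClassifier(Protocol):
    def classify(self, ensemble: OracleEnsemble) -> tuple[SolenoidProfile, ...]:
        """Per-model solenoid class profiles for a predicted ensemble."""
        ...


@runtime_checkable
class SequenceDesigner(Protocol):
    def design(
        self,
        backbone_coords: np.ndarray,
        n_sequences: int,
        temperature: float = 0.2,
        forbid: frozenset[str] = frozenset("C"),
    ) -> list[str]:
        """Fixed-backbone sequence design (inverse folding)."""
        ...


@runtime_checkable
class CapGenerator(Protocol):
    def generate_caps(
        self,
        backbone_coords: np.ndarray,
        terminal: str,
        cap_length: int,
        ss_pattern: str,
        n_caps: int,
    ) -> list[np.ndarray]:
        """Generate candidate capped backbones (full-length coordinates)."""
        ...


def _match_fraction(sequence: str, hidden_target: RepeatUnit) -> float:
    """Fraction of repeat-aligned positions matching the hidden unit."""
    L = len(hidden_target)
    if not sequence:
        raise InvalidInputError("sequence must be non-empty")
    if len(sequence) % L != 0:
        raise InvalidInputError(
            f"sequence length {len(sequence)} not divisible by unit length {L}"
        )
    target = hidden_target.residues
    matches = sum(1 for i, aa in enumerate(sequence) if aa == target[i % L])
    return matches / len(sequence)


def mock_predict(
    sequence: str, hidden_target: RepeatUnit, n_models: int = DESIGN_MODE_MODELS
) -> OracleEnsemble:
    """Surrogate structure prediction over the match-fraction landscape.

    With ``q`` the fraction of positions matching the hidden target unit:
    per-residue pLDDT of model ``m`` is ``clip(0.2 + 0.8 q + delta_m, 0, 1)``,
    pTM equals ``q``, and every pAE entry is ``20 (1 - q)`` Å.
    Coordinates come from the synthetic solenoid generator with positional
    noise shrinking as ``q`` grows, seeded from the sequence itself, so
    output is a pure function of the input sequence.
    """
    q = _match_fraction(sequence, hidden_target)
    L = len(hidden_target)
    n = len(sequence)
    num_repeats = n // L
    rng = np.random.default_rng(zlib.crc32(sequence.encode()) & 0x7FFFFFFF)
    distortion = 3.0 * (1.0 - q)
    coords = synth_solenoid_coords(
        L, num_repeats, distortion=distortion, rng=rng if distortion > 0 else None
    )
    pae = np.full((n, n), 20.0 * (1.0 - q))
    preds = []
    for m in range(n_models):
        delta = MOCK_MODEL_OFFSETS[m % len(MOCK_MODEL_OFFSETS)]
        plddt = np.full(n, np.clip(0.2 + 0.8 * q + delta, 0.0, 1.0))
        preds.append(
            StructurePrediction(
                model_id=m + 1, ca_coords=coords, plddt=plddt, pae=pae, ptm=q
            )
        )
    return OracleEnsemble(predictions=tuple(preds))


def mock_classify(
    ensemble: OracleEnsemble,
    sequence: str,
    hidden_target: RepeatUnit,
    target_class: SolenoidClass,
) -> tuple[SolenoidProfile, ...]:
    """Surrogate discriminator: target-class probability equals ``q``.

    The remaining mass ``1 - q`` is split equally over the other three
    classes, for every residue and every model.
    """
    q = _match_fraction(sequence, hidden_target)
    n = ensemble.n_residues
    target_idx = SOLENOID_CLASSES.index(SolenoidClass(target_class).value)
    row = np.full(len(SOLENOID_CLASSES), (1.0 - q) / 3.0)
    row[target_idx] = q
    profile = SolenoidProfile(probabilities=np.tile(row, (n, 1)))
    return tuple(profile for _ in ensemble.predictions)


class MockOracleSuite:
    """Bundled surrogate predictor + classifier sharing one hidden target.

    Satisfies both the :class:`StructurePredictor` and
    :class:`SolenoidClassifier` protocols.  The classifier caches the
    sequence of the last prediction because profiles are a function of
    the sequence, not the coordinates.
    """

    def __init__(self, hidden_target: RepeatUnit, target_class: SolenoidClass):
        self.hidden_target = hidden_target
        self.target_class = SolenoidClass(target_class)
        self._last_sequence: str | None = None
        self.n_predict_calls = 0

    def predict(self, sequence: str, mode: str = "design") -> OracleEnsemble:
        self.n_predict_calls += 1
        self._last_sequence = sequence
        return mock_predict(sequence, self.hidden_target)

    def classify(self, ensemble: OracleEnsemble) -> tuple[SolenoidProfile, ...]:
        if self._last_sequence is None or len(self._last_sequence) != ensemble.n_residues:
            raise InvalidInputError("classify must follow a matching predict call")
        return mock_classify(
            ensemble, self._last_sequence, self.hidden_target, self.target_class
        )


class FlatOracleSuite(MockOracleSuite):
    """Adversarial surrogate with a constant landscape (q fixed at 0.5).

    Useful for exercising the termination path: no candidate can ever
    clear a non-trivial threshold, and selection has nothing to favour.
    """

    def predict(self, sequence: str, mode: str = "design") -> OracleEnsemble:
        self.n_predict_calls += 1
        self._last_sequence = sequence
        n = len(sequence)
        coords = synth_solenoid_coords(len(self.hidden_target), n // len(self.hidden_target))
        pae = np.full((n, n), 10.0)
        preds = tuple(
            StructurePrediction(
                model_id=m + 1,
                ca_coords=coords,
                plddt=np.full(n, 0.5),
                pae=pae,
                ptm=0.5,
            )
            for m in range(DESIGN_MODE_MODELS)
        )
        return OracleEnsemble(predictions=preds)

    def classify(self, ensemble: OracleEnsemble) -> tuple[SolenoidProfile, ...]:
        n = ensemble.n_residues
        target_idx = SOLENOID_CLASSES.index(self.target_class.value)
        row = np.full(4, 0.5 / 3.0)
        row[target_idx] = 0.5
        profile = SolenoidProfile(probabilities=np.tile(row, (n, 1)))
        return tuple(profile for _ in ensemble.predictions)


class MockSequenceDesigner:
    """Deterministic surrogate for fixed-backbone sequence design.

    Perturbs a base sequence position-by-position: roughly
    ``temperature`` of the positions are resampled uniformly from the
    allowed (non-forbidden) alphabet.  Output is a pure function of
    (base sequence or backbone length, seed, sequence index).
    """

    def __init__(self, base_sequence: str | None = None, seed: int = 0):
        self.base_sequence = base_sequence
        self.seed = seed

    def design(
        self,
        backbone_coords: np.ndarray,
        n_sequences: int,
        temperature: float = 0.2,
        forbid: frozenset[str] = frozenset("C"),
    ) -> list[str]:
        if n_sequences < 1:
            raise InvalidInputError("n_sequences must be >= 1")
        n = backbone_coords.shape[0]
        allowed = [aa for aa in AMINO_ACIDS if aa not in forbid]
        rng = np.random.default_rng((self.seed, n))
        if self.base_sequence is not None:
            if len(self.base_sequence) != n:
                raise InvalidInputError("base sequence length must match backbone")
            base = list(self.base_sequence)
        else:
            base = list(rng.choice(allowed, size=n))
        # Forbidden letters in the base are always resampled.
        out = []
        for _ in range(n_sequences):
            seq = base.copy()
            flip = rng.random(n) < temperature
            for i in range(n):
                if flip[i] or seq[i] in forbid:
                    seq[i] = allowed[rng.integers(len(allowed))]
            out.append("".join(seq))
        return out


class ScriptedCapPredictor:
    """Scripted surrogate predictor for the capping cascade.

    Deterministically per sequence (hash-seeded), the prediction either
    "passes" — coordinates agreeing with the reference geometry for that
    length, low pAE, high pLDDT — or "fails" on one chosen gate while
    keeping the remaining metrics passing, so filter attribution can be
    tested gate by gate.

    ``reference_for_length`` maps a sequence length to the reference
    Cα coordinates the pipeline will superpose predictions onto; for the
    ``pae_terminal`` fail gate, ``cap_region`` gives the (start, stop)
    residue slice of the cap.
    """

    def __init__(
        self,
        reference_for_length,
        pass_rate: float = 1.0,
        fail_gate: str = "rmsd",
        cap_region: tuple[int, int] | None = None,
        seed: int = 0,
        base_pae: float = 3.0,
        base_plddt: float = 0.90,
    ):
        if fail_gate not in ("rmsd", "pae_full", "pae_terminal", "plddt"):
            raise InvalidInputError(f"unknown fail gate {fail_gate!r}")
        self.reference_for_length = reference_for_length
        self.pass_rate = pass_rate
        self.fail_gate = fail_gate
        self.cap_region = cap_region
        self.seed = seed
        self.base_pae = base_pae
        self.base_plddt = base_plddt

    def predict(self, sequence: str, mode: str = "repredict") -> OracleEnsemble:
        n = len(sequence)
        rng = np.random.default_rng(
            (zlib.crc32(sequence.encode()) + self.seed) & 0x7FFFFFFF
        )
        passing = rng.random() < self.pass_rate
        coords = np.array(self.reference_for_length(n), dtype=float)
        pae = np.full((n, n), self.base_pae)
        plddt_val = self.base_plddt
        if not passing:
            if self.fail_gate == "rmsd":
                coords = coords + rng.normal(0.0, 3.0, size=coords.shape)
            elif self.fail_gate == "pae_full":
                pae = np.full((n, n), 8.0)
            elif self.fail_gate == "pae_terminal":
                lo, hi = self.cap_region if self.cap_region else (0, n)
                pae[lo:hi, lo:hi] = 8.0
            elif self.fail_gate == "plddt":
                plddt_val = 0.70
        preds = tuple(
            StructurePrediction(
                model_id=m + 1,
                ca_coords=coords,
                plddt=np.full(n, plddt_val),
                pae=pae,
                ptm=plddt_val,
            )
            for m in range(DESIGN_MODE_MODELS)
        )
        return OracleEnsemble(predictions=preds)


class MockCapGenerator:
    """Surrogate terminal-cap generator.

    Returns full-length capped backbones on the shared reference
    geometry for the extended length, with a small per-cap seeded jitter
    so the candidates are distinct.
    """

    def __init__(self, reference_for_length, seed: int = 0, jitter: float = 0.05):
        self.reference_for_length = reference_for_length
        self.seed = seed
        self.jitter = jitter

    def generate_caps(
        self,
        backbone_coords: np.ndarray,
        terminal: str,
        cap_length: int,
        ss_pattern: str,
        n_caps: int,
    ) -> list[np.ndarray]:
        if terminal not in ("N", "C"):
            raise InvalidInputError(f"terminal must be 'N' or 'C', got {terminal!r}")
        if len(ss_pattern) != cap_length:
            raise InvalidInputError("ss_pattern length must equal cap_length")
        n_total = backbone_coords.shape[0] + cap_length
        base = np.array(self.reference_for_length(n_total), dtype=float)
        rng = np.random.default_rng((self.seed, n_total))
        return [base + rng.normal(0.0, self.jitter, size=base.shape) for _ in range(n_caps)]


def _require_binary(name: str, purpose: str) -> str:
    path = shutil.which(name)
    if path is None:
        raise OracleUnavailableError(
            f"{purpose} requires the '{name}' executable, which is not on PATH; "
            "configure a mock oracle or install the backend"
        )
    return path


class ColabFoldAdapter:
    """Subprocess adapter for ColabFold/AF2 structure prediction.

    Only the availability contract is implemented here: construction
    fails with :class:`OracleUnavailableError` when the backend binary is
    absent, and it never degrades to a surrogate.
    """

    def __init__(self, binary: str = "colabfold_batch"):
        self.binary = _require_binary(binary, "ColabFold structure prediction")

    def predict(self, sequence: str, mode: str = "design") -> OracleEnsemble:
        raise NotImplementedError(
            "ColabFold adapter invocation is environment-specific; subclass "
            "and implement predict() against your local installation"
        )


class ESMFoldAdapter:
    """Subprocess adapter contract for ESMFold (availability check only)."""

    def __init__(self, binary: str = "esmfold"):
        self.binary = _require_binary(binary, "ESMFold structure prediction")

    def predict(self, sequence: str, mode: str = "design") -> OracleEnsemble:
        raise NotImplementedError("implement against your local ESMFold install")


class ProteinMPNNAdapter:
    """Subprocess adapter contract for ProteinMPNN inverse folding."""

    def __init__(self, binary: str = "protein_mpnn_run"):
        self.binary = _require_binary(binary, "ProteinMPNN sequence design")

    def design(self, backbone_coords, n_sequences, temperature=0.2, forbid=frozenset("C")):
        raise NotImplementedError("implement against your local ProteinMPNN install")
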