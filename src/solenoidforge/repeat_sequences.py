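"""Repeat-sequence data model for solenoid hallucination.

A design candidate is a single repeat unit of length ``L`` concatenated
``N`` times into a perfect tandem array.  The evolutionary search operates
on the unit only; per-repeat variation is introduced later, at the
inverse-folding redesign stage, which is outside this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np

from .errors import InfeasibleSpecError, InvalidParameterError, InvalidSpecError

#: Canonical amino-acid alphabet in standard IUPAC order.  The order is
#: load-bearing: uniform sampling indexes into this string, so a fixed
#: order makes seeded runs reproducible across platforms.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)
_AA_ARRAY = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)

#: Minimum number of repeating units in any scaffold.
MIN_REPEATS = 4

#: Default total-length band (residues) for scaffolds.
DEFAULT_LENGTH_BAND = (130, 180)


class SolenoidClass(str, Enum):
    """Target solenoid architecture for a design run."""

    ALPHA = "alpha"
    BETA = "beta"
    ALPHABETA = "alphabeta"

    @property
    def default_min_solenoid_score(self) -> float:
        # alpha/beta designs use 0.6; mixed alpha-beta repeats need the
        # stricter 0.7 gate or they collapse into loopy beta-like folds.
        return 0.7 if self is SolenoidClass.ALPHABETA else 0.6


@dataclass(frozen=True)
class RepeatSpec:
    """Definition of one design problem.

    Parameters
    ----------
    repeat_length : int
        Length ``L`` of the repeating unit in residues.
    num_repeats : int
        Number of tandem copies ``N`` (at least 4).
    target_class : SolenoidClass
        Which solenoid architecture the discriminator score rewards.
    min_plddt : float
        Per-model pLDDT gate on the 0-1 scale that every ensemble member
        must exceed for a candidate to count as a finished design.
    min_solenoid_score : float
        Minimum discriminator score for the target class.
    length_band : tuple[int, int]
        Allowed total length ``N*L`` in residues.
    """

    repeat_length: int
    num_repeats: int
    target_class: SolenoidClass = SolenoidClass.ALPHA
    min_plddt: float = 0.70
    min_solenoid_score: Optional[float] = None
    length_band: tuple[int, int] = DEFAULT_LENGTH_BAND

    def __post_init__(self) -> None:
        if self.repeat_length < 1:
            raise InvalidSpecError(f"repeat_length must be >= 1, got {self.repeat_length}")
        if self.num_repeats < MIN_REPEATS:
            raise InvalidSpecError(
                f"num_repeats must be >= {MIN_REPEATS}, got {self.num_repeats}"
            )
        if not 0.0 <= self.min_plddt <= 1.0:
            raise InvalidSpecError(f"min_plddt must be in [0,1], got {self.min_plddt}")
        object.__setattr__(self, "target_class", SolenoidClass(self.target_class))
        if self.min_solenoid_score is None:
            object.__setattr__(
                self, "min_solenoid_score", self.target_class.default_min_solenoid_score
            )
        if not 0.0 <= self.min_solenoid_score <= 1.0:
            raise InvalidSpecError(
                f"min_solenoid_score must be in [0,1], got {self.min_solenoid_score}"
            )

    @property
    def total_length(self) -> int:
        return self.repeat_length * self.num_repeats

    @classmethod
    def from_length(
        cls,
        repeat_length: int,
        target_class: SolenoidClass = SolenoidClass.ALPHA,
        length_band: tuple[int, int] = DEFAULT_LENGTH_BAND,
        **kwargs,
    ) -> "RepeatSpec":
        """Build a spec choosing ``N`` automatically from the length band."""
        n = choose_repeat_number(repeat_length, length_band)
        return cls(
            repeat_length=repeat_length,
            num_repeats=n,
            target_class=target_class,
            length_band=length_band,
            **kwargs,
        )


@dataclass(frozen=True)
class RepeatUnit:
    """A single repeating unit: a string over the 20 canonical residues."""

    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise InvalidSpecError("repeat unit must be non-empty")
        bad = set(self.residues) - _AA_SET
        if bad:
            raise InvalidSpecError(f"non-canonical residues in unit: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class SequenceCandidate:
    """A repeat unit together with its full concatamer and fitness."""

    unit: RepeatUnit
    num_repeats: int
    fitness: Optional[object] = field(default=None)  # FitnessReport once scored

    @property
    def full_sequence(self) -> str:
        return build_concatamer(self.unit, self.num_repeats)


def random_repeat_unit(length: int, rng: np.random.Generator) -> RepeatUnit:
    """Draw a repeat unit uniformly over the 20-letter alphabet.

    Each position is i.i.d. uniform; the same generator state always
    yields the same unit.
    """
    if length < 1:
        raise InvalidSpecError(f"repeat length must be >= 1, got {length}")
    idx = rng.integers(0, len(AMINO_ACIDS), size=length)
    return RepeatUnit(_AA_ARRAY[idx].tobytes().decode())


def build_concatamer(unit: RepeatUnit | str, num_repeats: int) -> str:
    """Concatenate ``num_repeats`` identical copies of the unit."""
    if num_repeats < 1:
        raise InvalidSpecError(f"num_repeats must be >= 1, got {num_repeats}")
    residues = unit.residues if isinstance(unit, RepeatUnit) else unit
    return residues * num_repeats


def choose_repeat_number(
    repeat_length: int, band: tuple[int, int] = DEFAULT_LENGTH_BAND
) -> int:
    """Smallest ``N >= 4`` whose total length reaches the band minimum.

    Raises
    ------
    InfeasibleSpecError
        If the resulting total would overshoot the band maximum, i.e. no
        repeat count satisfies both the minimum-repeat rule and the band.
    """
    if repeat_length < 1:
        raise InvalidSpecError(f"repeat length must be >= 1, got {repeat_length}")
    min_total, max_total = band
    if min_total > max_total:
        raise InvalidParameterError(f"invalid length band {band}")
    n = max(MIN_REPEATS, -(-min_total // repeat_length))  # ceil division
    if n * repeat_length > max_total:
        raise InfeasibleSpecError(
            f"no repeat count with N>=4 fits L={repeat_length} into band {band}: "
            f"minimal N={n} gives total {n * repeat_length}"
        )
    return n


def mutate_unit(
    unit: RepeatUnit,
    rate: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
) -> RepeatUnit:
    """Point-mutate each position independently with probability ``rate``.

    The default rate is ``1/L``, which yields one mutation per offspring
    on average.  A mutated position is resampled uniformly from the 19
    letters other than its current one, so a flip always changes the
    residue; unflipped positions are untouched.
    """
    if rng is None:
        raise InvalidParameterError("mutate_unit requires a seeded numpy Generator")
    n = len(unit)
    if rate is None:
        rate = 1.0 / n
    if not 0.0 <= rate <= 1.0:
        raise InvalidParameterError(f"mutation rate must be in [0,1], got {rate}")
    current = np.frombuffer(unit.residues.encode(), dtype=np.uint8).copy()
    flip = rng.random(n) < rate
    if flip.any():
        k = int(flip.sum())
        cur_idx = np.searchsorted(_AA_ARRAY, current[flip])
        # Draw from 19 slots and skip over the current letter's slot:
        # branch-free uniform sampling on the complement.
        draw = rng.integers(0, len(AMINO_ACIDS) - 1, size=k)
        draw = draw + (draw >= cur_idx)
        current[flip] = _AA_ARRAY[draw]
    return RepeatUnit(current.tobytes().decode())
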