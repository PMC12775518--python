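"""Synthetic fixtures: parametric solenoid geometry and simulated data.

Everything here is generative and synthetic — it stands in for predicted
backbones and oracle landscapes so that the surrounding algorithms can be
exercised deterministically at desk scale.  None of it approximates real
protein energetics; see the methods note for what that implies.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidParameterError


def synth_solenoid_coords(
    repeat_length: int,
    num_repeats: int,
    rise_per_repeat: float = 4.8,
    radius: float = 9.0,
    twist_per_repeat_deg: float = 30.0,
    distortion: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Cα coordinates of an idealised solenoid superhelix, in Å.

    Residue ``i`` of repeat ``j`` is placed on a circular helix at phase
    ``(j + i/L) * twist`` and height ``(j + i/L) * rise``, so repeat ``j+1``
    is the exact screw image (rotation + axial translation) of repeat ``j``.
    With ``distortion == 0`` every repeat therefore superposes on every
    other with zero RMSD; ``distortion > 0`` adds isotropic Gaussian
    displacement of that standard deviation to each coordinate.

    Defaults loosely mimic a β-solenoid cross-section (≈9 Å radius,
    ≈4.8 Å rise between stacked rungs); they are geometry knobs, not fits.
    """
    if repeat_length < 1 or num_repeats < 1:
        raise InvalidParameterError("repeat_length and num_repeats must be >= 1")
    if radius <= 0:
        raise InvalidParameterError(f"radius must be positive, got {radius}")
    if rise_per_repeat <= 0:
        raise InvalidParameterError(f"rise_per_repeat must be positive, got {rise_per_repeat}")
    if distortion < 0:
        raise InvalidParameterError(f"distortion must be >= 0, got {distortion}")
    n = repeat_length * num_repeats
    t = np.arange(n) / repeat_length  # repeat-fraction coordinate
    theta = np.deg2rad(twist_per_repeat_deg) * t
    coords = np.column_stack(
        (radius * np.cos(theta), radius * np.sin(theta), rise_per_repeat * t)
    )
    if distortion > 0:
        if rng is None:
            raise InvalidParameterError("distortion > 0 requires a seeded Generator")
        coords = coords + rng.normal(0.0, distortion, size=coords.shape)
    return coords


def synth_cap_coords(
    n_residues: int,
    start: np.ndarray,
    direction: np.ndarray,
    rng: np.random.Generator | None = None,
    jitter: float = 0.0,
) -> np.ndarray:
    """An ideal α-helix of ``n_residues`` Cα atoms grown from ``start``.

    Used as the synthetic terminal cap appended to solenoid backbones:
    3.6 residues/turn, 1.5 Å rise, 2.3 Å Cα radius, axis along
    ``direction``.
    """
    if n_residues < 1:
        raise InvalidParameterError("n_residues must be >= 1")
    direction = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(direction)
    if norm == 0:
        raise InvalidParameterError("direction must be non-zero")
    axis = direction / norm
    # Build an orthonormal frame around the helix axis.
    ref = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    i = np.arange(n_residues)
    phase = 2.0 * np.pi * i / 3.6
    coords = (
        np.asarray(start, dtype=float)
        + np.outer(1.5 * (i + 1), axis)
        + np.outer(2.3 * np.cos(phase), u)
        + np.outer(2.3 * np.sin(phase), v)
    )
    if jitter > 0:
        if rng is None:
            raise InvalidParameterError("jitter > 0 requires a seeded Generator")
        coords = coords + rng.normal(0.0, jitter, size=coords.shape)
    return coords


def canonical_coords(n_residues: int) -> np.ndarray:
    """Deterministic reference Cα trace of a given length.

    A pure function of the length: an ideal helix grown from the origin
    along +z.  Mock cap generators and scripted predictors share this
    geometry so that "the prediction matches the design" is expressible
    without any real structure in the loop.
    """
    return synth_cap_coords(n_residues, start=np.zeros(3), direction=np.array([0.0, 0.0, 1.0]))


def logistic_success_curve(
    levels: np.ndarray,
    m50: float,
    slope: float = 30.0,
    upper: float = 1.0,
    lower: float = 0.0,
) -> np.ndarray:
    """Noise-free decreasing logistic success-rate curve over mask levels."""
    levels = np.asarray(levels, dtype=float)
    return lower + (upper - lower) / (1.0 + np.exp(slope * (levels - m50)))


def synth_melting_curve(
    levels: np.ndarray,
    m50: float,
    slope: float = 30.0,
    upper: float = 1.0,
    lower: float = 0.0,
    n_replicates: int = 64,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Binomial-noise success rates drawn around a known logistic curve.

    Each level's rate is ``Binomial(n_replicates, p)/n_replicates`` with
    ``p`` from :func:`logistic_success_curve`, emulating the finite
    replicate count of a melting experiment with a known ground truth.
    """
    if rng is None:
        raise InvalidParameterError("synth_melting_curve requires a seeded Generator")
    p = logistic_success_curve(levels, m50, slope, upper, lower)
    return rng.binomial(n_replicates, p) / float(n_replicates)
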