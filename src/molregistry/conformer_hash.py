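"""Coordinate hashing for 3D conformer deduplication.

A conformer's identity is the SHA256 digest of its rounded coordinates:

1. round each Cartesian coordinate to ``digits`` decimal places
   (default 3, i.e. milli-angstrom resolution);
2. write each atom position as ``"x,y,z"`` in fixed-point notation;
3. sort the position strings lexicographically;
4. join them with semicolons and take the SHA256 of the UTF-8 bytes.

The sort makes the hash independent of atom ordering, but it is
*neither translationally nor rotationally invariant* — deliberately, so
that pre-aligned conformers (docking poses, crystal structures) with
different placements register as distinct. Callers who want
orientation-free identity run :func:`canonicalize_orientation` first
(or use the corresponding standardization step).

Formatting is locale-independent fixed point with round-half-even,
negative zero normalized to positive zero, no exponent notation.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

__all__ = [
    "ConformerCoordinates",
    "atom_position_strings",
    "conformer_hash",
    "canonicalize_orientation",
]

DEFAULT_DIGITS = 3


@dataclass(frozen=True)
class ConformerCoordinates:
    """One conformer: per-atom (x, y, z) positions in angstrom.

    ``digits`` is the decimal precision used when hashing; storage and
    geometry always use the full input precision.
    """

    positions: Tuple[Tuple[float, float, float], ...]
    digits: int = DEFAULT_DIGITS

    def __post_init__(self):
        if len(self.positions) == 0:
            raise ValueError("a conformer needs at least one atom")
        if self.digits < 0:
            raise ValueError("digits must be non-negative")
        object.__setattr__(
            self, "positions", tuple(tuple(float(c) for c in p) for p in self.positions)
        )

    @classmethod
    def from_array(cls, arr, digits: int = DEFAULT_DIGITS) -> "ConformerCoordinates":
        a = np.asarray(arr, dtype=float)
        if a.ndim != 2 or a.shape[1] != 3:
            raise ValueError("expected an (n_atoms, 3) array")
        return cls(tuple(map(tuple, a)), digits=digits)

    def as_array(self) -> np.ndarray:
        return np.array(self.positions, dtype=float)


def _format_component(value: float, digits: int) -> str:
    if not math.isfinite(value):
        raise ValueError(f"non-finite coordinate: {value!r}")
    # Python's fixed-point formatting rounds half-to-even on the decimal
    # expansion of the double, which is exactly the rule we document.
    text = f"{value:.{digits}f}"
    # normalize negative zero ("-0", "-0.000") to positive zero
    if text.startswith("-") and float(text) == 0.0:
        text = text[1:]
    return text


def atom_position_strings(coords: ConformerCoordinates) -> List[str]:
    """Fixed-point ``"x,y,z"`` text per atom, in input atom order."""
    return [
        ",".join(_format_component(c, coords.digits) for c in pos)
        for pos in coords.positions
    ]


def conformer_hash(coords: ConformerCoordinates) -> str:
    """64-char lowercase-hex SHA256 identifying the conformer.

    Invariant under permutation of atoms; sensitive to translation and
    rotation beyond the rounding resolution.
    """
    preimage = ";".join(sorted(atom_position_strings(coords)))
    return hashlib.sha256(preimage.encode("utf-8")).hexdigest()


def canonicalize_orientation(coords: ConformerCoordinates) -> ConformerCoordinates:
    """Translate/rotate a conformer into a canonical pose.

    The centroid is moved to the origin and the conformer rotated onto
    the principal axes of its coordinate covariance, ordered by
    descending eigenvalue. Each of the first two axes is signed so the
    coordinate of largest absolute value along it is positive; the third
    axis is their cross product, enforcing a right-handed frame. Any
    rigid transform of an asymmetric conformer therefore maps to the
    same canonical coordinates (up to ~1e-12 angstrom numerical noise);
    pairwise interatomic distances are preserved exactly up to rounding.

    Degenerate inputs (a single atom, all atoms coincident) are handled
    by translation alone.
    """
    x = coords.as_array()
    centered = x - x.mean(axis=0)
    if len(centered) == 1 or np.allclose(centered, 0.0):
        return ConformerCoordinates.from_array(centered, digits=coords.digits)

    cov = centered.T @ centered
    eigvals, eigvecs = np.linalg.eigh(cov)
    # eigh returns ascending order; we want the dominant axis first
    axes = eigvecs[:, ::-1].copy()

    for j in range(2):
        proj = centered @ axes[:, j]
        if proj[int(np.argmax(np.abs(proj)))] < 0:
            axes[:, j] = -axes[:, j]
    axes[:, 2] = np.cross(axes[:, 0], axes[:, 1])

    return ConformerCoordinates.from_array(centered @ axes, digits=coords.digits)
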