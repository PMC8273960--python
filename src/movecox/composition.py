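"""Simplex arithmetic for three-part movement-behaviour compositions.

A waking day is partitioned into sedentary behaviour (SB), light-intensity
physical activity (LIPA) and moderate-to-vigorous physical activity (MVPA).
Because the three durations are constrained to a fixed waking total, they
carry only relative information and live on the 2-simplex.  This module
provides the closure operation, isometric log-ratio (ilr) pivot coordinates
under the three rotations used in the analysis, the inverse transform, and
the Aitchison distance.

The pivot ilr for a composition with parts ordered ``(a, b, c)`` is

    z1 = sqrt(2/3) * ln( a / sqrt(b * c) )
    z2 = sqrt(1/2) * ln( b / c )

``z1`` contrasts the pivot behaviour against the geometric mean of the other
two; ``z2`` contrasts the remaining pair.  The three rotations re-order the
pivot so each behaviour in turn occupies the first coordinate; they are
orthogonal reparameterisations of the same space, so distances, likelihoods
and hazard-ratio contrasts are rotation-invariant.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PARTS",
    "WAKING_DAY_MIN",
    "GUIDELINE_WEEKLY_MVPA_MIN",
    "guideline_daily_mvpa",
    "Rotation",
    "Composition",
    "IlrCoordinates",
    "close",
    "ilr",
    "ilr_inverse",
    "ilr_matrix",
    "aitchison_distance",
]

#: Behaviour labels, in the canonical column order used throughout.
PARTS = ("SB", "LIPA", "MVPA")

#: Default waking-day total: 16 h = 960 min, the mean waking duration the
#: analysis normalises to.
WAKING_DAY_MIN = 960.0

#: Public-health MVPA guideline, minutes per week.
GUIDELINE_WEEKLY_MVPA_MIN = 150.0

_SQ23 = math.sqrt(2.0 / 3.0)
_SQ12 = math.sqrt(1.0 / 2.0)


def guideline_daily_mvpa(weekly_min: float = GUIDELINE_WEEKLY_MVPA_MIN) -> float:
    """Daily equivalent of the weekly MVPA guideline, rounded to whole minutes.

    150 min/week corresponds to 21 min/day at the resolution of the
    reference compositions.
    """
    return round(weekly_min / 7.0)


class Rotation(enum.Enum):
    """Pivot orderings of (SB, LIPA, MVPA) for the ilr transform.

    Each rotation puts a different behaviour first, so its ``z1``
    coordinate measures that behaviour relative to the geometric mean of
    the other two, and ``z2`` contrasts the remaining pair (second part in
    the numerator).
    """

    SB_FIRST = ("SB", "LIPA", "MVPA")
    LIPA_FIRST = ("LIPA", "SB", "MVPA")
    MVPA_FIRST = ("MVPA", "SB", "LIPA")

    @property
    def pivot_order(self) -> tuple[str, str, str]:
        return self.value

    @property
    def indices(self) -> tuple[int, int, int]:
        """Indices of the pivot order into the canonical (SB, LIPA, MVPA)."""
        return tuple(PARTS.index(p) for p in self.value)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Rotation.{self.name}"


@dataclass(frozen=True)
class Composition:
    """A closed three-part composition in minutes of a waking day."""

    sb_min: float
    lipa_min: float
    mvpa_min: float
    total_min: float = WAKING_DAY_MIN

    def __post_init__(self) -> None:
        s = self.sb_min + self.lipa_min + self.mvpa_min
        if not math.isclose(s, self.total_min, rel_tol=0.0, abs_tol=1e-9):
            raise ValueError(
                f"parts sum to {s!r}, not the stated total {self.total_min!r}"
            )
        if self.total_min <= 0:
            raise ValueError("total_min must be positive")

    @property
    def parts(self) -> np.ndarray:
        return np.array([self.sb_min, self.lipa_min, self.mvpa_min])

    def as_dict(self) -> dict[str, float]:
        return dict(zip(PARTS, self.parts))

    def __getitem__(self, behaviour: str) -> float:
        return self.as_dict()[behaviour]


@dataclass(frozen=True)
class IlrCoordinates:
    """The two pivot ilr coordinates under a named rotation."""

    z1: float
    z2: float
    rotation: Rotation

    @property
    def values(self) -> np.ndarray:
        return np.array([self.z1, self.z2])


def close(parts, total: float = WAKING_DAY_MIN) -> Composition:
    """Rescale three nonnegative minute values to sum exactly to ``total``.

    The third part is set by subtraction so the sum is exact in floating
    point, which keeps downstream closure invariants bit-testable.
    """
    p = np.asarray(parts, dtype=float)
    if p.shape != (3,):
        raise ValueError("expected exactly three parts (SB, LIPA, MVPA)")
    if np.any(p < 0):
        raise ValueError("negative part duration")
    s = p.sum()
    if s <= 0:
        raise ValueError("at least one part must be positive")
    if total <= 0:
        raise ValueError("total must be positive")
    scaled = p * (total / s)
    scaled[2] = total - scaled[0] - scaled[1]
    return Composition(scaled[0], scaled[1], scaled[2], total)


def _ordered_parts(c: Composition, r: Rotation) -> np.ndarray:
    return c.parts[list(r.indices)]


def ilr(c: Composition, r: Rotation = Rotation.SB_FIRST) -> IlrCoordinates:
    """Pivot ilr coordinates of a strictly positive composition.

    Scale-invariant: the closure total drops out of every log ratio.
    Raises if any part is nonpositive (zeros must be imputed first).
    """
    a, b, c_ = _ordered_parts(c, r)
    if a <= 0 or b <= 0 or c_ <= 0:
        raise ValueError("ilr requires strictly positive parts; impute zeros first")
    z1 = _SQ23 * math.log(a / math.sqrt(b * c_))
    z2 = _SQ12 * math.log(b / c_)
    return IlrCoordinates(z1, z2, r)


def ilr_matrix(parts: np.ndarray, r: Rotation = Rotation.SB_FIRST) -> np.ndarray:
    """Vectorised pivot ilr: (n, 3) canonical-ordered parts -> (n, 2).

    Used on whole cohorts; same contract as :func:`ilr` row-wise.
    """
    x = np.asarray(parts, dtype=float)[:, list(r.indices)]
    if np.any(x <= 0):
        raise ValueError("ilr requires strictly positive parts; impute zeros first")
    lx = np.log(x)
    z1 = _SQ23 * (lx[:, 0] - 0.5 * (lx[:, 1] + lx[:, 2]))
    z2 = _SQ12 * (lx[:, 1] - lx[:, 2])
    return np.column_stack([z1, z2])


def ilr_inverse(
    z: IlrCoordinates, total: float = WAKING_DAY_MIN
) -> Composition:
    """Map ilr coordinates back to a composition summing to ``total``.

    Inverse of :func:`ilr` under the same rotation: the centred log-ratio
    vector is reconstructed from the orthonormal basis and exponentiated.
    """
    if not (math.isfinite(z.z1) and math.isfinite(z.z2)):
        raise ValueError("ilr coordinates must be finite")
    # clr of (a, b, c) in pivot order from the orthonormal basis columns.
    clr = np.array(
        [
            _SQ23 * z.z1,
            -z.z1 / math.sqrt(6.0) + _SQ12 * z.z2,
            -z.z1 / math.sqrt(6.0) - _SQ12 * z.z2,
        ]
    )
    ordered = np.exp(clr - clr.max())  # guard overflow; closure removes scale
    canonical = np.empty(3)
    r = z.rotation
    for pos, idx in enumerate(r.indices):
        canonical[idx] = ordered[pos]
    return close(canonical, total)


def aitchison_distance(c1: Composition, c2: Composition) -> float:
    """Aitchison distance: Euclidean distance between ilr images.

    Rotation choice is immaterial (the rotations are isometries).
    """
    z1 = ilr(c1).values
    z2 = ilr(c2).values
    return float(np.linalg.norm(z1 - z2))
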