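"""Reference compositions, time reallocation, and hazard-ratio contrasts.

The fitted compositional Cox model is interrogated through hypothetical
*reallocations*: starting from a reference waking-day composition, a fixed
number of minutes is moved from one behaviour to another while the third
is held constant.  Because covariates are held at the reference, the
hazard ratio of the reallocated versus reference composition depends only
on the ilr displacement:

    log HR = beta_z . (ilr(reallocated) - ilr(reference))
    se     = sqrt(dz' Sigma_z dz)          (delta method, z-block only)

Two families of reference compositions are supported: MVPA-anchored
(MVPA fixed at 10/21/30 min, SB taking a stated share — 77% by default —
of the remaining waking time) and SB-anchored (SB fixed at e.g. the 5th or
95th percentile, MVPA fixed, LIPA the remainder).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .composition import (
    PARTS,
    WAKING_DAY_MIN,
    Composition,
    Rotation,
    close,
    ilr,
)

__all__ = [
    "InfeasibleReallocation",
    "ReferenceComposition",
    "ReallocationEstimate",
    "build_reference_mvpa",
    "build_reference_sb",
    "reallocate",
    "reallocation_hr",
    "reallocation_table",
    "hr_surface",
]

Z975 = 1.959964  # normal quantile for two-sided 95% intervals


class InfeasibleReallocation(ValueError):
    """A displacement that would drive a behaviour to zero or below.

    Corresponds to the "not observed" cells of the reallocation tables
    (e.g. MVPA cannot be decreased by 10 min when the reference has
    MVPA at 10 min).
    """


@dataclass(frozen=True)
class ReferenceComposition:
    """A labelled reference waking-day composition."""

    label: str
    composition: Composition
    rule: str

    def __getitem__(self, behaviour: str) -> float:
        return self.composition[behaviour]


def build_reference_mvpa(
    mvpa_min: float,
    sb_share: float = 0.77,
    total: float = WAKING_DAY_MIN,
    label: str | None = None,
) -> ReferenceComposition:
    """MVPA-anchored reference: SB takes ``sb_share`` of the non-MVPA time.

    Fractional minutes are kept exactly; display rounding is left to
    reporting code.
    """
    if not 0 < mvpa_min < total:
        raise ValueError("mvpa_min must lie strictly inside (0, total)")
    if not 0 < sb_share < 1:
        raise ValueError("sb_share must lie strictly inside (0, 1)")
    remainder = total - mvpa_min
    sb = sb_share * remainder
    comp = close([sb, remainder - sb, mvpa_min], total)
    return ReferenceComposition(
        label or f"MVPA={mvpa_min:g}min",
        comp,
        f"mvpa_anchored(mvpa={mvpa_min:g}, sb_share={sb_share:g})",
    )


def build_reference_sb(
    sb_min: float,
    mvpa_min: float,
    total: float = WAKING_DAY_MIN,
    label: str | None = None,
) -> ReferenceComposition:
    """SB-anchored reference: LIPA is the remaining waking time."""
    lipa = total - sb_min - mvpa_min
    if lipa <= 0:
        raise ValueError("SB + MVPA leave no waking time for LIPA")
    if sb_min <= 0 or mvpa_min <= 0:
        raise ValueError("anchored durations must be positive")
    comp = close([sb_min, lipa, mvpa_min], total)
    return ReferenceComposition(
        label or f"SB={sb_min:g}min,MVPA={mvpa_min:g}min",
        comp,
        f"sb_anchored(sb={sb_min:g}, mvpa={mvpa_min:g})",
    )


def reallocate(
    ref: ReferenceComposition | Composition,
    from_behaviour: str,
    to_behaviour: str,
    delta_min: float,
) -> Composition:
    """Move ``delta_min`` minutes between two behaviours of a reference.

    The third behaviour and the waking total are unchanged.  Raises
    :class:`InfeasibleReallocation` when the donor behaviour would be
    driven to zero or below.
    """
    comp = ref.composition if isinstance(ref, ReferenceComposition) else ref
    if from_behaviour not in PARTS or to_behaviour not in PARTS:
        raise ValueError(f"behaviours must be among {PARTS}")
    if from_behaviour == to_behaviour:
        raise ValueError("source and destination behaviours must differ")
    if delta_min < 0:
        raise ValueError("delta_min must be nonnegative")
    parts = comp.as_dict()
    if delta_min >= parts[from_behaviour]:
        raise InfeasibleReallocation(
            f"{from_behaviour} cannot be decreased by {delta_min:g} min when "
            f"the reference composition value of {from_behaviour} is at "
            f"{parts[from_behaviour]:g} min"
        )
    parts[from_behaviour] -= delta_min
    parts[to_behaviour] += delta_min
    return Composition(
        parts["SB"], parts["LIPA"], parts["MVPA"], comp.total_min
    )


@dataclass(frozen=True)
class ReallocationEstimate:
    """Hazard ratio with 95% CI for one minute-displacement."""

    from_behaviour: str
    to_behaviour: str
    delta_min: float
    hr: float
    ci_low: float
    ci_high: float
    log_hr_se: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.hr <= self.ci_high):
            raise ValueError("confidence interval must bracket the estimate")


def reallocation_hr(
    beta_z,
    cov_z,
    rotation: Rotation,
    ref: ReferenceComposition,
    from_behaviour: str,
    to_behaviour: str,
    delta_min: float,
) -> ReallocationEstimate:
    """Delta-method HR for a reallocated versus reference composition.

    ``beta_z`` and ``cov_z`` are the ilr-coordinate block of the fitted
    model's coefficients and covariance, in the model's rotation.  The
    result is rotation-invariant because the ilr displacement rotates
    with the coefficients.
    """
    beta = np.asarray(beta_z, dtype=float)
    V = np.asarray(cov_z, dtype=float)
    if delta_min == 0:
        return ReallocationEstimate(
            from_behaviour, to_behaviour, 0.0, 1.0, 1.0, 1.0, 0.0
        )
    new = reallocate(ref, from_behaviour, to_behaviour, delta_min)
    dz = ilr(new, rotation).values - ilr(ref.composition, rotation).values
    log_hr = float(beta @ dz)
    se = float(np.sqrt(dz @ V @ dz))
    return ReallocationEstimate(
        from_behaviour,
        to_behaviour,
        delta_min,
        float(np.exp(log_hr)),
        float(np.exp(log_hr - Z975 * se)),
        float(np.exp(log_hr + Z975 * se)),
        se,
    )


def reallocation_table(
    beta_z,
    cov_z,
    rotation: Rotation,
    references,
    deltas=(10.0, 20.0, 30.0),
) -> pd.DataFrame:
    """Reallocation report over references x behaviour pairs x deltas.

    One row per (reference, add-to, remove-from, delta); infeasible
    displacements are kept as rows with ``feasible = False`` and missing
    estimates, mirroring the "-" cells of the published tables.
    """
    rows = []
    for ref in references:
        for to_b in PARTS:
            for from_b in PARTS:
                if to_b == from_b:
                    continue
                for d in deltas:
                    base = {
                        "reference": ref.label,
                        "add_to": to_b,
                        "remove_from": from_b,
                        "delta_min": d,
                    }
                    try:
                        est = reallocation_hr(
                            beta_z, cov_z, rotation, ref, from_b, to_b, d
                        )
                    except InfeasibleReallocation:
                        rows.append(
                            base
                            | {
                                "hr": np.nan,
                                "ci_low": np.nan,
                                "ci_high": np.nan,
                                "feasible": False,
                            }
                        )
                        continue
                    rows.append(
                        base
                        | {
                            "hr": est.hr,
                            "ci_low": est.ci_low,
                            "ci_high": est.ci_high,
                            "feasible": True,
                        }
                    )
    return pd.DataFrame(rows)


def hr_surface(
    beta_z,
    cov_z,
    rotation: Rotation,
    ref: ReferenceComposition,
    grid_step: float = 5.0,
    ranges: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """HR over a simplex grid relative to a reference composition.

    Grid points are multiples of ``grid_step`` minutes with all parts
    positive, restricted to the supplied observed ``ranges`` (a mapping
    behaviour -> (min, max) minutes).  The reference point itself is
    appended with HR exactly 1.  Output columns: sb_min, lipa_min,
    mvpa_min, hr, is_reference — directly renderable as a ternary
    heatmap.
    """
    beta = np.asarray(beta_z, dtype=float)
    total = ref.composition.total_min
    z_ref = ilr(ref.composition, rotation).values
    steps = np.arange(grid_step, total, grid_step)
    rows = []
    for sb in steps:
        for lipa in np.arange(grid_step, total - sb, grid_step):
            mvpa = total - sb - lipa
            if mvpa <= 0:
                continue
            point = {"SB": sb, "LIPA": lipa, "MVPA": mvpa}
            if ranges is not None and any(
                not (lo <= point[b] <= hi) for b, (lo, hi) in ranges.items()
            ):
                continue
            comp = Composition(sb, lipa, mvpa, total)
            dz = ilr(comp, rotation).values - z_ref
            rows.append(
                {
                    "sb_min": sb,
                    "lipa_min": lipa,
                    "mvpa_min": mvpa,
                    "hr": float(np.exp(beta @ dz)),
                    "is_reference": False,
                }
            )
    rows.append(
        {
            "sb_min": ref.composition.sb_min,
            "lipa_min": ref.composition.lipa_min,
            "mvpa_min": ref.composition.mvpa_min,
            "hr": 1.0,
            "is_reference": True,
        }
    )
    df = pd.DataFrame(rows)
    if len(df) == 1 and ranges is not None:
        raise ValueError("observed ranges leave an empty grid")
    return df
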