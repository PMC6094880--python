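"""Disease-activity outcome definitions for juvenile dermatomyositis.

Four continuous instruments are modelled jointly:

* **CK** — serum creatine kinase (U/L). Right-skewed, analysed on the natural
  log scale; no boundary point mass.
* **CMAS** — childhood myositis assessment scale, 0–52 points, 52 = best.
* **MMT8** — manual muscle testing of 8 muscle groups, 0–80 points, 80 = best.
* **PGA** — physician's global assessment of disease activity, 0–10 cm visual
  analogue scale, 0 = best.

CMAS, MMT8 and PGA are analysed on the square-root scale and carry an excess
of the best clinical value for visits in remission, handled downstream by a
hurdle component with a point mass at the best value.  Each outcome also has a
validated remission cutoff (CK <= 150, CMAS >= 48, MMT8 >= 78, PGA <= 0.2)
used for Brier-score calibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "OutcomeSpec",
    "OUTCOME_NAMES",
    "default_outcome_specs",
    "transform_outcome",
    "inverse_transform",
    "remission_indicator",
]

#: Canonical ordering of the four outcomes everywhere in the package.
OUTCOME_NAMES = ("ck", "cmas", "mmt8", "pga")

#: Index of each outcome in parameter arrays.
OUTCOME_INDEX = {name: i for i, name in enumerate(OUTCOME_NAMES)}

#: Hurdle outcomes (boundary point mass at the best clinical value).
HURDLE_NAMES = ("cmas", "mmt8", "pga")
HURDLE_INDEX = {name: i for i, name in enumerate(HURDLE_NAMES)}


@dataclass(frozen=True)
class OutcomeSpec:
    """Metadata for one disease-activity outcome.

    Parameters
    ----------
    name:
        One of ``ck``, ``cmas``, ``mmt8``, ``pga``.
    unit:
        Measurement unit (U/L, points, points, cm).
    lower_bound, upper_bound:
        Raw-scale support; CK is unbounded above.
    best_value:
        The best possible clinical value carrying the hurdle point mass, or
        ``None`` for CK (no point mass).
    transform:
        ``"log"`` (CK) or ``"sqrt"`` (CMAS, MMT8, PGA).
    remission_cutoff:
        Validated cutoff for inactive disease.
    cutoff_direction:
        ``"le"`` if inactive means value <= cutoff (CK, PGA), ``"ge"`` if
        inactive means value >= cutoff (CMAS, MMT8).
    """

    name: str
    unit: str
    lower_bound: float
    upper_bound: float
    best_value: float | None
    transform: Literal["log", "sqrt"]
    remission_cutoff: float
    cutoff_direction: Literal["le", "ge"]

    def __post_init__(self) -> None:
        if self.name not in OUTCOME_NAMES:
            raise ValueError(f"unknown outcome name {self.name!r}")
        if self.cutoff_direction not in ("le", "ge"):
            raise ValueError("cutoff_direction must be 'le' or 'ge'")
        if self.best_value is not None:
            on_boundary = self.best_value in (self.lower_bound, self.upper_bound)
            if not on_boundary:
                raise ValueError(
                    f"best_value {self.best_value} of {self.name} must lie on "
                    f"the boundary of [{self.lower_bound}, {self.upper_bound}]"
                )

    # -- scale bookkeeping ------------------------------------------------

    @property
    def has_hurdle(self) -> bool:
        return self.best_value is not None

    @property
    def transformed_lower(self) -> float:
        """Lower end of the transformed-scale support."""
        if self.transform == "log":
            return -math.inf
        return math.sqrt(self.lower_bound)

    @property
    def transformed_upper(self) -> float:
        if math.isinf(self.upper_bound):
            return math.inf
        if self.transform == "log":
            return math.log(self.upper_bound)
        return math.sqrt(self.upper_bound)

    @property
    def transformed_best(self) -> float | None:
        if self.best_value is None:
            return None
        return transform_outcome(self, self.best_value)

    def continuous_support(self) -> tuple[float, float]:
        """Transformed-scale truncation interval of the continuous branch.

        The hurdle point mass sits at the transformed best value; the
        continuous branch is a Gaussian truncated to the rest of the
        transformed support, so the two components are disjoint.
        """
        lo, hi = self.transformed_lower, self.transformed_upper
        if not self.has_hurdle:
            return lo, hi
        if self.best_value == self.upper_bound:  # CMAS, MMT8: mass at the top
            return lo, self.transformed_best
        return self.transformed_best, hi  # PGA: mass at zero

    # -- value-level operations -------------------------------------------

    def in_bounds(self, value: float) -> bool:
        return self.lower_bound <= value <= self.upper_bound

    def is_best(self, value: float) -> bool:
        if self.best_value is None:
            return False
        return bool(np.isclose(value, self.best_value, rtol=0.0, atol=1e-9))

    def is_inactive(self, value: float) -> bool:
        if self.cutoff_direction == "le":
            return value <= self.remission_cutoff
        return value >= self.remission_cutoff


def transform_outcome(spec: OutcomeSpec, value):
    """Map a raw outcome value to the analysis scale (log or sqrt).

    CK must be strictly positive for the log transform.
    """
    value = np.asarray(value, dtype=float)
    if spec.transform == "log":
        if np.any(value <= 0.0):
            raise ValueError(f"{spec.name}: log transform requires value > 0")
        out = np.log(value)
    else:
        if np.any(value < 0.0):
            raise ValueError(f"{spec.name}: sqrt transform requires value >= 0")
        out = np.sqrt(value)
    return out if out.ndim else float(out)


def inverse_transform(spec: OutcomeSpec, value):
    """Inverse of :func:`transform_outcome` (exp or square)."""
    value = np.asarray(value, dtype=float)
    out = np.exp(value) if spec.transform == "log" else np.square(value)
    return out if out.ndim else float(out)


def remission_indicator(spec: OutcomeSpec, value: float) -> str:
    """Classify an observed value as ``"inactive"`` or ``"active"``.

    Inactive iff the validated cutoff inequality holds (inclusive): CK <= 150,
    CMAS >= 48, MMT8 >= 78, PGA <= 0.2.
    """
    return "inactive" if spec.is_inactive(value) else "active"


def default_outcome_specs() -> dict[str, OutcomeSpec]:
    """The four outcome definitions used throughout the package."""
    return {
        "ck": OutcomeSpec(
            name="ck", unit="U/L", lower_bound=0.0, upper_bound=math.inf,
            best_value=None, transform="log",
            remission_cutoff=150.0, cutoff_direction="le",
        ),
        "cmas": OutcomeSpec(
            name="cmas", unit="points", lower_bound=0.0, upper_bound=52.0,
            best_value=52.0, transform="sqrt",
            remission_cutoff=48.0, cutoff_direction="ge",
        ),
        "mmt8": OutcomeSpec(
            name="mmt8", unit="points", lower_bound=0.0, upper_bound=80.0,
            best_value=80.0, transform="sqrt",
            remission_cutoff=78.0, cutoff_direction="ge",
        ),
        "pga": OutcomeSpec(
            name="pga", unit="cm", lower_bound=0.0, upper_bound=10.0,
            best_value=0.0, transform="sqrt",
            remission_cutoff=0.2, cutoff_direction="le",
        ),
    }
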