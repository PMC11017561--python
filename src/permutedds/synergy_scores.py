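"""Synergy labels computed from dose-response quantities.

Two continuous labels are supported, matching the two benchmark screens the
model is trained on:

* the **Loewe score**, built on dose equivalence and the sham-combination
  principle: a four-parameter sigmoid response (R_min, R_max, midpoint dose
  m, shape lambda) evaluated at the combined dose x_A + x_B;
* the **ComboScore**, a Bliss-independence modification: the sum over a
  concentration grid of observed minus expected growth fractions.

The sign convention of the ComboScore follows the formula as used by the
NCI-ALMANAC screen: observed (Y) minus expected (Z), summed over all dose
pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, ShapeMismatchError


@dataclass(frozen=True)
class DoseResponseParams:
    """Sigmoid dose-response parameterization.

    Parameters
    ----------
    r_min, r_max : float
        Response at zero and saturating total dose (response units).
    m : float
        Dose producing the midpoint between ``r_min`` and ``r_max``; > 0.
    lam : float
        Hill-type shape parameter; > 0.
    """

    r_min: float
    r_max: float
    m: float
    lam: float

    def __post_init__(self):
        if not self.m > 0:
            raise DomainError(f"midpoint dose m must be > 0, got {self.m}")
        if not self.lam > 0:
            raise DomainError(f"shape parameter lam must be > 0, got {self.lam}")


@dataclass(frozen=True)
class CombinationGrid:
    """Observed (Y) and Bliss-expected (Z) growth fractions on a dose grid.

    An optional boolean ``mask`` marks the measured cells; unmeasured cells
    are skipped by :func:`combo_score` (real HTS grids are often ragged).
    """

    observed: np.ndarray
    expected: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self):
        obs = np.atleast_2d(np.asarray(self.observed, dtype=float))
        exp = np.atleast_2d(np.asarray(self.expected, dtype=float))
        if obs.shape != exp.shape:
            raise ShapeMismatchError(
                f"observed shape {obs.shape} != expected shape {exp.shape}"
            )
        if obs.size == 0:
            raise ShapeMismatchError("grid must be at least 1x1")
        object.__setattr__(self, "observed", obs)
        object.__setattr__(self, "expected", exp)
        if self.mask is not None:
            msk = np.atleast_2d(np.asarray(self.mask, dtype=bool))
            if msk.shape != obs.shape:
                raise ShapeMismatchError(
                    f"mask shape {msk.shape} != grid shape {obs.shape}"
                )
            object.__setattr__(self, "mask", msk)


def loewe_score(params: DoseResponseParams, x_a: float, x_b: float) -> float:
    """Loewe synergy score at doses ``x_a`` and ``x_b``.

    Computes ``(R_min + R_max * ((x_a+x_b)/m)^lam) / (1 + ((x_a+x_b)/m)^lam)``.
    By construction the value depends on the doses only through their sum
    (sham combination): a drug "combined" with itself scores exactly as the
    pooled dose of one drug.
    """
    if x_a < 0 or x_b < 0:
        raise DomainError("doses must be >= 0")
    ratio = ((x_a + x_b) / params.m) ** params.lam
    return (params.r_min + params.r_max * ratio) / (1.0 + ratio)


def combo_score(grid: CombinationGrid) -> float:
    """ComboScore: sum of observed minus expected growth fractions.

    Masked-out cells (``grid.mask == False``) are excluded from the sum.
    """
    diff = grid.observed - grid.expected
    if grid.mask is not None:
        diff = diff[grid.mask]
    return float(np.sum(diff))
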