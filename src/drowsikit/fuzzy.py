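"""Mamdani fuzzy fusion of the three drowsiness evidence channels.

Three unit-interval scores — channel 1 (EEG or EOG evidence), channel 2
(face-recognition eye-state fraction, "FR") and channel 3 (EAR open fraction)
— are combined by a Mamdani fuzzy inference system into a crisp value on
[0, 1] and a DROWSY/ALERT label.  Each input has two linguistic terms, L
(low, closed-eye / drowsy evidence) and H (high, alert evidence); the output
has terms DR (drowsy, mass below 0.5) and AL (alert, mass above).

The rule base covers all 8 corners of {L, H}^3 and encodes a majority rule:
the consequent is DR exactly when at least two antecedent terms are L.  The
standard Mamdani stack is used: AND = min, implication = clip, aggregation =
pointwise max, defuzzification = area centroid; crisp values below 0.5 are
labelled DROWSY (ties go to ALERT).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Term",
    "OutTerm",
    "MembershipFunction",
    "FuzzyRule",
    "FuzzyDecision",
    "MamdaniFuser",
    "membership_degree",
    "build_rule_base",
    "default_input_mfs",
    "default_output_mfs",
]

DECISION_THRESHOLD = 0.5
DEFAULT_GRID_POINTS = 1001


class Term(str, Enum):
    L = "L"
    H = "H"


class OutTerm(str, Enum):
    DR = "DR"
    AL = "AL"


@dataclass(frozen=True)
class MembershipFunction:
    """Trapezoid membership function on [0, 1] with breakpoints a<=b<=c<=d."""

    name: str
    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if not (self.a <= self.b <= self.c <= self.d):
            raise ValueError("trapezoid breakpoints must satisfy a <= b <= c <= d")

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        # rising edge
        if self.b > self.a:
            rise = (x - self.a) / (self.b - self.a)
            out = np.where((x > self.a) & (x < self.b), rise, out)
        out = np.where((x >= self.b) & (x <= self.c), 1.0, out)
        # falling edge
        if self.d > self.c:
            fall = (self.d - x) / (self.d - self.c)
            out = np.where((x > self.c) & (x < self.d), fall, out)
        return out if out.ndim else float(out)


def default_input_mfs() -> dict[Term, MembershipFunction]:
    """Symmetric L/H input terms; L(0)=1, L(1)=0, H mirrors L about 0.5.

    The plateaus overlap at 0.5 so that max(L(x), H(x)) = 1 for every x.
    With a majority rule base this matters: an input's H degree feeds one DR
    rule (the corner where the other two inputs are L), so if both terms
    dipped mid-range the crisp output would bump non-monotonically as that
    input swept from 0 to 1.  Overlapping plateaus keep the crisp output
    non-decreasing in each input.
    """
    return {
        Term.L: MembershipFunction("L", 0.0, 0.0, 0.5, 0.8),
        Term.H: MembershipFunction("H", 0.2, 0.5, 1.0, 1.0),
    }


def default_output_mfs() -> dict[OutTerm, MembershipFunction]:
    """DR mass below 0.5, AL above; mirror-symmetric about 0.5."""
    return {
        OutTerm.DR: MembershipFunction("DR", 0.0, 0.0, 0.3, 0.5),
        OutTerm.AL: MembershipFunction("AL", 0.5, 0.7, 1.0, 1.0),
    }


def membership_degree(x: float, mf: MembershipFunction) -> float:
    """Degree of membership of a score in a linguistic term."""
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"score {x} outside [0, 1]")
    return float(mf(x))


@dataclass(frozen=True)
class FuzzyRule:
    """IF ch1 is a AND fr is b AND ear is c THEN state is consequent."""

    antecedent: tuple[Term, Term, Term]
    consequent: OutTerm


def build_rule_base() -> list[FuzzyRule]:
    """All 8 {L,H}^3 corners; DR exactly when >= 2 antecedent terms are L.

    The canonical decision-table rows — (L,L,L)->DR, (L,L,H)->DR,
    (L,H,H)->AL, (H,H,H)->AL — are instances of this majority rule; the
    remaining four corners follow from it by symmetry.
    """
    rules = []
    for combo in product((Term.L, Term.H), repeat=3):
        n_low = sum(t is Term.L for t in combo)
        rules.append(
            FuzzyRule(combo, OutTerm.DR if n_low >= 2 else OutTerm.AL)
        )
    return rules


@dataclass(frozen=True)
class FuzzyDecision:
    inputs: tuple[float, float, float]
    crisp: float
    label: str  # "DROWSY" or "ALERT"


@dataclass
class MamdaniFuser:
    """Mamdani inference engine over the three evidence channels.

    Parameters
    ----------
    input_mfs : L/H trapezoids shared by all three inputs.
    output_mfs : DR/AL trapezoids on the decision axis.
    rules : complete 8-corner rule base.
    n_grid : output-axis discretisation for aggregation and centroid.
    threshold : crisp values strictly below it are DROWSY.
    """

    input_mfs: dict[Term, MembershipFunction] = field(default_factory=default_input_mfs)
    output_mfs: dict[OutTerm, MembershipFunction] = field(
        default_factory=default_output_mfs
    )
    rules: list[FuzzyRule] = field(default_factory=build_rule_base)
    n_grid: int = DEFAULT_GRID_POINTS
    threshold: float = DECISION_THRESHOLD

    def __post_init__(self) -> None:
        covered = {r.antecedent for r in self.rules}
        if len(covered) != len(self.rules):
            raise ValueError("duplicate rule antecedents")
        self._grid = np.linspace(0.0, 1.0, self.n_grid)
        # consequent MFs sampled once on the grid
        self._out_curves = {t: mf(self._grid) for t, mf in self.output_mfs.items()}

    # -- core Mamdani steps -------------------------------------------------

    def firing_strengths(self, scores: Sequence[float]) -> np.ndarray:
        """min-AND antecedent degree for every rule."""
        s = self._check_scores(scores)
        degrees = {
            t: np.array([membership_degree(x, mf) for x in s])
            for t, mf in self.input_mfs.items()
        }
        return np.array(
            [min(degrees[t][i] for i, t in enumerate(r.antecedent)) for r in self.rules]
        )

    def infer(self, scores: Sequence[float]) -> np.ndarray:
        """Aggregated output membership curve over the [0, 1] grid.

        Per rule the consequent MF is clipped at the firing strength;
        aggregation is the pointwise max over rules.
        """
        strengths = self.firing_strengths(scores)
        agg = np.zeros_like(self._grid)
        for r, w in zip(self.rules, strengths):
            np.maximum(agg, np.minimum(self._out_curves[r.consequent], w), out=agg)
        return agg

    def defuzzify_centroid(self, curve: np.ndarray) -> float:
        """Area centroid of an aggregated curve sampled on the output grid."""
        area = np.trapezoid(curve, self._grid)
        if area <= 0.0:
            raise ValueError("zero-area aggregate curve: no rule fired")
        return float(np.trapezoid(curve * self._grid, self._grid) / area)

    # -- public API ---------------------------------------------------------

    def decide(self, scores: Sequence[float]) -> FuzzyDecision:
        """Fuse three channel scores into a crisp value and a label."""
        crisp = self.defuzzify_centroid(self.infer(scores))
        # ties at the threshold go to ALERT; the 1e-9 guard absorbs grid
        # round-off at exactly symmetric inputs
        label = "DROWSY" if crisp < self.threshold - 1e-9 else "ALERT"
        return FuzzyDecision(tuple(float(x) for x in scores), crisp, label)

    def decision_surface(
        self,
        grid_resolution: int = 21,
        fixed_input: float = 1.0,
        fixed_axis: int = 0,
    ) -> pd.DataFrame:
        """Crisp value over a 2-D grid of two inputs, the third held fixed.

        Returns a DataFrame with columns x, y, crisp where x and y sweep the
        two free inputs in axis order.
        """
        if grid_resolution < 2:
            raise ValueError("grid_resolution must be >= 2")
        axes = [i for i in range(3) if i != fixed_axis]
        g = np.linspace(0.0, 1.0, grid_resolution)
        rows = []
        for x in g:
            for y in g:
                scores = [0.0, 0.0, 0.0]
                scores[fixed_axis] = fixed_input
                scores[axes[0]] = x
                scores[axes[1]] = y
                rows.append((x, y, self.decide(scores).crisp))
        return pd.DataFrame(rows, columns=["x", "y", "crisp"])

    # -- helpers ------------------------------------------------------------

    @staticmethod
    def _check_scores(scores: Sequence[float]) -> list[float]:
        s = [float(x) for x in scores]
        if len(s) != 3:
            raise ValueError("exactly three channel scores required")
        for x in s:
            if not 0.0 <= x <= 1.0:
                raise ValueError(f"score {x} outside [0, 1]")
        return s
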