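"""Closed-form assay arithmetic.

Relative migration distance compares treated gap closure with control closure
over the same interval:

    relative migration (%) = 100 * (A - B) / (a - b)

where A/a are the wound widths before incubation and B/b after; A, B refer to
the treated condition and a, b to the control.  The caliper tumour volume is
V = L * W^2 / 2 (length L, width W, both in mm), and normalization to control
expresses any nonnegative measurement as a percentage of its matched control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .errors import DegenerateControlError


@dataclass(frozen=True)
class MigrationResult:
    """Widths of a treated/control pair and the derived migration percentage.

    All four widths must share one unit (px or um); the percentage is unit
    independent.
    """

    A: float
    B: float
    a: float
    b: float
    relative_migration_pct: float

    @property
    def closure_treated(self) -> float:
        return self.A - self.B

    @property
    def closure_control(self) -> float:
        return self.a - self.b


@dataclass(frozen=True)
class TumourMeasurement:
    """Caliper length/width (mm) and the derived volume (mm^3)."""

    L: float
    W: float
    V: float


def relative_migration(A: float, B: float, a: float, b: float) -> MigrationResult:
    """Relative migration distance of a treated condition versus its control.

    Parameters are wound widths: ``A`` treated before incubation, ``B``
    treated after, ``a`` control before, ``b`` control after (one shared
    unit).  Closure is expected (B <= A, b <= a); a widening wound is allowed
    but warned about, as is the both-widened case where the sign semantics
    (positive percentage from two negative closures) need care.

    Raises
    ------
    DegenerateControlError
        If a == b: the control did not move and the ratio is undefined
        (never reported as infinity or 0).
    ValueError
        If any width is negative.
    """
    for name, v in (("A", A), ("B", B), ("a", a), ("b", b)):
        if v < 0:
            raise ValueError(f"width {name} must be >= 0, got {v}")
    if a == b:
        raise DegenerateControlError(
            "control wound did not move (a == b): relative migration undefined"
        )
    if B > A:
        warnings.warn("treated wound widened (B > A)", stacklevel=2)
    if b > a:
        warnings.warn("control wound widened (b > a)", stacklevel=2)
    if B > A and b > a:
        warnings.warn(
            "both wounds widened: the percentage is a ratio of two negative closures",
            stacklevel=2,
        )
    pct = 100.0 * (A - B) / (a - b)
    return MigrationResult(A=A, B=B, a=a, b=b, relative_migration_pct=pct)


def tumour_volume(L: float, W: float) -> TumourMeasurement:
    """Caliper (ellipsoid) tumour volume V = L * W^2 / 2, in mm^3.

    Raises
    ------
    ValueError
        If either dimension is non-positive.
    """
    if L <= 0 or W <= 0:
        raise ValueError(f"tumour dimensions must be > 0 mm, got L={L}, W={W}")
    if W > L:
        warnings.warn("caliper width exceeds length; conventionally L >= W", stacklevel=2)
    return TumourMeasurement(L=L, W=W, V=L * W * W / 2.0)


def normalize_to_control(value: float, control: float) -> float:
    """Express ``value`` as a percentage of its matched control: 100*value/control.

    Raises
    ------
    ValueError
        If ``control`` <= 0 or ``value`` < 0.
    """
    if control <= 0:
        raise ValueError(f"control must be > 0, got {control}")
    if value < 0:
        raise ValueError(f"value must be >= 0, got {value}")
    return 100.0 * value / control
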