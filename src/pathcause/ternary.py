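"""Three-valued sign logic.

Every quantity entering a causality check is ternary: a change direction
(up / down / insignificant), the effect of a phosphosite on its protein's
activity (activating / inhibiting / uncurated), and the sign of a prior
relation.  ``TRUE`` and ``FALSE`` carry a definite sign; ``UNKNOWN`` marks
an insignificant change or an uncurated site.  The parity operator below is
the n-ary extension of XOR over this domain, with the convention that a
single ``UNKNOWN`` operand makes the whole expression ``UNKNOWN`` — an
undetermined term can never support a causal explanation.
"""

from __future__ import annotations

import enum
from typing import Iterable


class Ternary(enum.Enum):
    """Three-valued truth value closed under negation and XOR."""

    TRUE = "true"
    FALSE = "false"
    UNKNOWN = "unknown"

    @classmethod
    def from_bool(cls, value: bool | None) -> "Ternary":
        """Map ``True``/``False``/``None`` to the corresponding ternary."""
        if value is None:
            return cls.UNKNOWN
        return cls.TRUE if value else cls.FALSE

    @classmethod
    def from_sign(cls, x: float) -> "Ternary":
        """Positive -> TRUE, negative -> FALSE, zero -> UNKNOWN."""
        if x > 0:
            return cls.TRUE
        if x < 0:
            return cls.FALSE
        return cls.UNKNOWN

    @property
    def is_known(self) -> bool:
        return self is not Ternary.UNKNOWN

    def __bool__(self) -> bool:  # pragma: no cover - guard
        raise TypeError(
            "Ternary values have no implicit truth value; "
            "compare against Ternary members explicitly"
        )

    def __invert__(self) -> "Ternary":
        if self is Ternary.UNKNOWN:
            return Ternary.UNKNOWN
        return Ternary.FALSE if self is Ternary.TRUE else Ternary.TRUE

    def __xor__(self, other: "Ternary") -> "Ternary":
        if not isinstance(other, Ternary):
            return NotImplemented
        if self is Ternary.UNKNOWN or other is Ternary.UNKNOWN:
            return Ternary.UNKNOWN
        return Ternary.from_bool(self is not other)


def ternary_parity(values: Iterable[Ternary]) -> Ternary:
    """Ternary XOR folded over ``values``.

    Returns ``UNKNOWN`` if any input is ``UNKNOWN``; otherwise ``TRUE``
    exactly when an odd number of inputs are ``TRUE``.

    Raises
    ------
    ValueError
        If fewer than two values are supplied (the parity of a single sign
        is not a meaningful causality check).
    """
    vals = list(values)
    if len(vals) < 2:
        raise ValueError("ternary_parity requires at least two operands")
    n_true = 0
    for v in vals:
        if not isinstance(v, Ternary):
            raise TypeError(f"not a Ternary: {v!r}")
        if v is Ternary.UNKNOWN:
            return Ternary.UNKNOWN
        if v is Ternary.TRUE:
            n_true += 1
    return Ternary.from_bool(n_true % 2 == 1)
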