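"""Unions of closed angular intervals in degrees.

Polar angles (theta) live on [0, 180]; dihedrals (tau) on the circle,
normalized to (-180, 180].  Interval unions are the carrier for the allowed
theta/tau ranges attached to interaction sites: sampling is uniform in the
angle value, length-weighted across the member intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field


def wrap_degrees(x: float) -> float:
    """Map an angle to the principal branch (-180, 180]."""
    y = ((x + 180.0) % 360.0) - 180.0
    if y == -180.0:
        y = 180.0
    return y


@dataclass(frozen=True)
class AngleIntervals:
    """A union of closed intervals [lo, hi] in degrees.

    ``circular`` intervals are normalized to (-180, 180], splitting any
    interval that crosses the branch cut; non-circular (polar) intervals are
    validated against [0, 180].
    """

    intervals: tuple[tuple[float, float], ...]
    circular: bool = field(default=False)

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_pairs(cls, pairs, circular: bool = False) -> "AngleIntervals":
        out: list[tuple[float, float]] = []
        for lo, hi in pairs:
            lo, hi = float(lo), float(hi)
            if hi < lo:
                raise ValueError(f"empty interval [{lo}, {hi}]")
            if circular:
                out.extend(_normalize_circular(lo, hi))
            else:
                if lo < 0.0 or hi > 180.0:
                    raise ValueError(
                        f"polar interval [{lo}, {hi}] outside [0, 180]"
                    )
                out.append((lo, hi))
        if not out:
            raise ValueError("interval union is empty")
        return cls(tuple(sorted(out)), circular)

    @classmethod
    def parse(cls, text: str, circular: bool = False) -> "AngleIntervals":
        """Parse ``"[90,180]"`` or ``"[-45,45];[135,225]"``."""
        pairs = []
        for chunk in text.split(";"):
            chunk = chunk.strip().strip("[]")
            if not chunk:
                continue
            lo, hi = chunk.split(",")
            pairs.append((float(lo), float(hi)))
        if not pairs:
            raise ValueError(f"no intervals in {text!r}")
        return cls.from_pairs(pairs, circular)

    @classmethod
    def full_theta(cls) -> "AngleIntervals":
        return cls(((0.0, 180.0),), False)

    @classmethod
    def full_tau(cls) -> "AngleIntervals":
        return cls(((-180.0, 180.0),), True)

    # -- queries ------------------------------------------------------------

    @property
    def total_length(self) -> float:
        return sum(hi - lo for lo, hi in self.intervals)

    def contains(self, x: float, tol: float = 1e-9) -> bool:
        if self.circular:
            x = wrap_degrees(x)
        for lo, hi in self.intervals:
            if lo - tol <= x <= hi + tol:
                return True
            # a circular query sitting exactly at -180 also matches 180
            if self.circular and x == 180.0 and lo - tol <= -180.0 <= hi + tol:
                return True
        return False

    def is_full(self) -> bool:
        return abs(self.total_length - (360.0 if self.circular else 180.0)) < 1e-9

    def sample(self, rng) -> float:
        """Draw uniformly (length-weighted over member intervals)."""
        u = rng.uniform(0.0, self.total_length)
        for lo, hi in self.intervals:
            w = hi - lo
            if u <= w or (lo, hi) == self.intervals[-1]:
                return lo + min(u, w)
            u -= w
        raise AssertionError("unreachable")

    def serialize(self) -> str:
        return ";".join(f"[{lo:g},{hi:g}]" for lo, hi in self.intervals)


def _normalize_circular(lo: float, hi: float) -> list[tuple[float, float]]:
    width = hi - lo
    if width >= 360.0:
        return [(-180.0, 180.0)]
    lo = wrap_degrees(lo)
    if lo == 180.0:  # lower endpoints prefer the -180 representative
        lo = -180.0
    hi = lo + width
    if hi <= 180.0:
        return [(lo, hi)]
    return [(lo, 180.0), (-180.0, hi - 360.0)]
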