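"""Closed-form collision model for identifier generation.

Uniform insertion of I identifiers into N equally likely slots is a
balls-in-bins process. The expected number of empty slots afterwards is

    EE = N (1 - 1/N)^I

and, since N - EE slots are occupied, the expected number of collisions
(insertions that landed on an occupied slot) is

    EC = I - N + N (1 - 1/N)^I.

For identifier spaces of practical interest N is around 1e12-1e18 while
I <= 1e8, so EC is the difference of nearly equal huge numbers: in double
precision (1 - 1/N)^I is indistinguishable from exp(-I/N) rounded to a
handful of ulps and the subtraction cancels catastrophically. All
evaluation here therefore runs in mpmath arbitrary precision (default 50
significant digits) and returns a float at the end.

N is the *inverse probability* of the generator: the effective number of
equally likely identifier values. For NHash it is bracketed per component
(skewed name frequencies push the name factor below the uniform 26^n).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import mpmath
import pandas as pd

from .core import CSR_PROFILE, HashProfile
from .errors import NHashError

__all__ = [
    "expected_collisions",
    "expected_empty_slots",
    "BoundsTable",
    "csr_bounds",
    "ec_table",
    "random_string_inverse_probability",
    "round_sig",
    "format_sci",
]

#: Working precision (significant decimal digits) for the EC/EE evaluation.
#: 50 digits keeps >30 significant digits in (1 - 1/N) even at N = 1e18.
DPS = 50


def _check(N: float, I: float) -> None:
    if N < 1:
        raise NHashError(f"inverse probability N must be >= 1, got {N}")
    if I < 0:
        raise NHashError(f"insertion count I must be >= 0, got {I}")


def expected_empty_slots(N: float, I: float, dps: int = DPS) -> float:
    """Expected empty slots EE = N (1 - 1/N)^I after I uniform insertions."""
    _check(N, I)
    with mpmath.workdps(dps):
        Nm, Im = mpmath.mpf(N), mpmath.mpf(I)
        return float(Nm * mpmath.power(1 - 1 / Nm, Im))


def expected_collisions(N: float, I: float, dps: int = DPS) -> float:
    """Expected collisions EC = I - N + N (1 - 1/N)^I, evaluated in
    arbitrary precision so the near-total cancellation at I << N is exact
    to well below 1e-9 relative.

    Limits: EC(N, 0) = EC(N, 1) = 0; EC(1, I) = I - 1; for I/N -> 0,
    EC -> I(I-1)/(2N).
    """
    _check(N, I)
    with mpmath.workdps(dps):
        Nm, Im = mpmath.mpf(N), mpmath.mpf(I)
        return float(Im - Nm + Nm * mpmath.power(1 - 1 / Nm, Im))


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures."""
    if x == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(x)))
    return round(x, sig - 1 - exponent)


def format_sci(x: float, sig: int = 2) -> str:
    """Render like the collision table: e.g. 6.561e15 -> '6.6 x 10^15'."""
    m, e = f"{x:.{sig - 1}e}".split("e")
    return f"{m} x 10^{int(e)}"


@dataclass(frozen=True)
class BoundsTable:
    """Per-component inverse-probability bounds and their exact products.

    ``components`` holds (label, lower, upper) rows; the totals are exact
    integer products. Lower bounds discount real-world skew (name-length
    concentration, frequency-weighted names); upper bounds assume uniform
    use of the full character space.
    """

    components: tuple[tuple[str, int, int], ...]

    @property
    def lower_total(self) -> int:
        out = 1
        for _, lo, _ in self.components:
            out *= lo
        return out

    @property
    def upper_total(self) -> int:
        out = 1
        for _, _, hi in self.components:
            out *= hi
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"component": label, "lower": lo, "upper": hi}
            for label, lo, hi in self.components
        ]
        rows.append(
            {"component": "Total", "lower": self.lower_total, "upper": self.upper_total}
        )
        return pd.DataFrame(rows)


def csr_bounds(profile: HashProfile = CSR_PROFILE) -> BoundsTable:
    """Inverse-probability bounds for an NHash profile.

    Per component of gram size n: name contributes between 10^n (skewed
    names, dominant 5-letter name lengths) and 26^n (uniform letters); MRN
    between 9^n and 10^n; DOB 10^n on both sides (a deliberate
    underestimate — only two year digits vary freely); the random suffix
    contributes its full 10^random_digits exactly. For the deployed
    profile the totals are 6.561e15 and 4.56976e17, i.e. 6.6 x 10^15 and
    4.6 x 10^17 at two significant figures.
    """
    comps: list[tuple[str, int, int]] = []
    for src, n in profile.components:
        if src == "name":
            comps.append(("Name", 10**n, 26**n))
        elif src == "mrn":
            comps.append(("MRN", 9**n, 10**n))
        else:
            comps.append(("DOB", 10**n, 10**n))
    rd = profile.random_digits
    comps.append(("Random number", 10**rd, 10**rd))
    return BoundsTable(components=tuple(comps))


def ec_table(Ns: list[float], Is: list[float], dps: int = DPS) -> pd.DataFrame:
    """Cross-evaluate EC over inverse probabilities (rows) and insertion
    counts (columns). Pass the published *rounded* N values to reproduce a
    printed table; pass exact products for the sharp numbers."""
    data = {I: [expected_collisions(N, I, dps=dps) for N in Ns] for I in Is}
    return pd.DataFrame(data, index=Ns)


def random_string_inverse_probability(n: int) -> int:
    """Identifier-space size of the length-n random-string baseline:
    4 uniform uppercase letters followed by n-4 uniform digits."""
    if n < 5:
        raise NHashError("random-string baseline needs n >= 5")
    return 26**4 * 10 ** (n - 4)
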