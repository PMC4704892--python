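"""Shared fixtures: the published worked example and an independent
reference pipeline used as a brute-force oracle.

The reference pipeline deliberately avoids the package's implementation
choices: n-grams come from an explicit doubled-string slice, the cipher
from alphabet index lookup, so agreement between the two paths is a real
cross-check rather than the same code twice.
"""

from __future__ import annotations

import string
from datetime import date

import pytest

from nhash import DemographicRecord

ALPHA = string.ascii_uppercase
DIGITS = string.digits


@pytest.fixture
def aaron() -> DemographicRecord:
    """The fictional participant used throughout the worked examples."""
    return DemographicRecord(
        first_name="Aaron", last_name="Skotnica", mrn="07172485", dob=date(1956, 8, 13)
    )


def ref_ngram(r: int, n: int, m: str) -> str:
    """Oracle n-gram: tile m until long enough, slice [s, s+n)."""
    s = r % len(m)
    tiled = m * (n // len(m) + 2)
    return tiled[s : s + n]


def ref_shift(text: str, letter_by: int, digit_by: int) -> str:
    """Oracle shift cipher via alphabet index lookup."""
    out = []
    for ch in text:
        if ch in ALPHA:
            out.append(ALPHA[(ALPHA.index(ch) + letter_by) % 26])
        else:
            out.append(DIGITS[(DIGITS.index(ch) + digit_by) % 10])
    return "".join(out)


def ref_identifier(first: str, last: str, mrn: str, dob: date, r: int) -> str:
    """Oracle end-to-end pipeline for the default 16-character profile."""
    name = "".join(c for c in (first + last).upper() if c in ALPHA)
    mrn8 = mrn.zfill(8)
    dob8 = dob.strftime("%m%d%Y")
    inter = ref_ngram(r, 4, name) + ref_ngram(r, 4, mrn8) + ref_ngram(r, 2, dob8)
    k1, k2 = len(name), dob.month
    c = (k1 + k2) * (k1 + k2 + 1) // 2 + k2
    return ref_shift(inter, c % 26, c % 10) + str(r).zfill(6)
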