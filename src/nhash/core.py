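"""Core NHash algorithm: sanitization, randomized n-gram extraction,
shift-cipher encryption, and identifier assembly.

An NHash identifier pseudonymizes a study participant from three
demographic fields (name, medical record number, date of birth) in two
phases:

1. A shared random number ``r`` selects, for each field, the start position
   ``s = r mod |m|`` of an n-gram within the sanitized field string ``m``.
   The n-grams are concatenated into an intermediate string.
2. The intermediate string is encrypted with a shift cipher whose key is
   derived from the Cantor pairing of the sanitized name length and the
   birth month: letters rotate by ``C mod 26``, digits by ``C mod 10``.
   The ciphertext concatenated with the zero-padded ``r`` is the final
   identifier.

Because ``r`` is embedded in clear, anyone holding the codebook record can
regenerate the identifier and byte-compare it — this is what makes NHash
identifiers validatable (see :mod:`nhash.registry`).
"""

from __future__ import annotations

import secrets
import string
import unicodedata
from dataclasses import dataclass
from datetime import date, datetime

from .errors import (
    InvalidCharacterError,
    InvalidDOBError,
    InvalidMRNError,
    InvalidNameError,
    NHashError,
    RetryExhaustedError,
)

__all__ = [
    "DemographicRecord",
    "SanitizedInput",
    "HashProfile",
    "ShiftKey",
    "NHashIdentifier",
    "CSR_PROFILE",
    "sanitize",
    "parse_dob",
    "ngram_extract",
    "cantor_pair",
    "derive_shift_key",
    "shift_encrypt",
    "shift_decrypt",
    "intermediate_string",
    "generate_identifier",
    "generate_unique",
]

_LETTERS = string.ascii_uppercase
_DIGITS = string.digits

#: Field sources an n-gram component may draw from.
SOURCES = ("name", "mrn", "dob")

MRN_WIDTH = 8


@dataclass(frozen=True)
class DemographicRecord:
    """Raw participant identity fields consumed by the hash.

    ``mrn`` is kept as a string because leading zeros are significant
    (hospital MRNs may start with 0). ``dob`` is a real calendar date;
    use :func:`parse_dob` to accept ``mm/dd/yyyy`` or ISO text.
    """

    first_name: str
    last_name: str
    mrn: str
    dob: date


@dataclass(frozen=True)
class SanitizedInput:
    """The three canonical hash-input strings.

    ``name_token``: uppercased first+last name, every non-letter removed.
    ``mrn_token``:  MRN left-zero-padded to 8 digits.
    ``dob_token``:  date of birth rendered ``mmddyyyy``.
    """

    name_token: str
    mrn_token: str
    dob_token: str

    def source(self, which: str) -> str:
        if which == "name":
            return self.name_token
        if which == "mrn":
            return self.mrn_token
        if which == "dob":
            return self.dob_token
        raise NHashError(f"unknown component source {which!r}")


@dataclass(frozen=True)
class HashProfile:
    """Shape of an NHash identifier: which n-grams, and suffix width.

    ``components`` is an ordered list of ``(source, n)`` pairs; the cipher
    part of the identifier is the encrypted concatenation of those n-grams.
    ``random_digits`` fixes the width of the zero-padded random suffix and
    thereby the random range ``[0, 10**random_digits)``.
    """

    components: tuple[tuple[str, int], ...] = (("name", 4), ("mrn", 4), ("dob", 2))
    random_digits: int = 6

    def __post_init__(self) -> None:
        if not self.components:
            raise NHashError("profile needs at least one component")
        for src, n in self.components:
            if src not in SOURCES:
                raise NHashError(f"unknown component source {src!r}")
            if n < 1:
                raise NHashError(f"gram size must be >= 1, got {n}")
        if self.random_digits < 1:
            raise NHashError("random_digits must be >= 1")

    @property
    def cipher_length(self) -> int:
        return sum(n for _, n in self.components)

    @property
    def id_length(self) -> int:
        return self.cipher_length + self.random_digits

    @property
    def random_range(self) -> int:
        """Exclusive upper bound of the random suffix, ``10**random_digits``."""
        return 10 ** self.random_digits

    def position_classes(self) -> str:
        """Character class per cipher position: 'L' letter or 'D' digit.

        Name-derived positions hold letters; MRN- and DOB-derived positions
        hold digits. The shift cipher preserves the class.
        """
        out = []
        for src, n in self.components:
            out.append(("L" if src == "name" else "D") * n)
        return "".join(out)


#: Default deployed profile ("csr"): 4-gram of name, 4-gram of MRN,
#: 2-gram of DOB, 6-digit random suffix (16-character identifiers).
CSR_PROFILE = HashProfile()


@dataclass(frozen=True)
class ShiftKey:
    """Shift-cipher key derived from name length and birth month.

    ``pairing_value`` is the Cantor pairing ``C = (k1+k2)(k1+k2+1)/2 + k2``
    of ``k1`` (sanitized name length) and ``k2`` (birth month, 1-12);
    letters shift by ``C mod 26`` and digits by ``C mod 10``.
    """

    k1: int
    k2: int
    pairing_value: int
    letter_shift: int
    digit_shift: int


@dataclass(frozen=True)
class NHashIdentifier:
    """An assembled study identifier: cipher part plus random suffix."""

    cipher_part: str
    random_part: str

    @property
    def full(self) -> str:
        return self.cipher_part + self.random_part

    @property
    def r(self) -> int:
        return int(self.random_part)

    def __str__(self) -> str:
        return self.full


def parse_dob(text: str | date) -> date:
    """Parse a date of birth given as ``mm/dd/yyyy`` or ISO ``yyyy-mm-dd``."""
    if isinstance(text, date):
        return text
    s = str(text).strip()
    for fmt in ("%m/%d/%Y", "%Y-%m-%d"):
        try:
            return datetime.strptime(s, fmt).date()
        except ValueError:
            continue
    raise InvalidDOBError(f"cannot parse date of birth {text!r}")


def _fold_letters(text: str) -> str:
    """Uppercase and keep A-Z only; diacritics fold to their base letter."""
    decomposed = unicodedata.normalize("NFKD", text)
    return "".join(c for c in decomposed.upper() if c in _LETTERS)


def sanitize(record: DemographicRecord) -> SanitizedInput:
    """Normalize raw demographics into the three hash-input strings.

    The name is uppercased and stripped of everything outside A-Z (spaces,
    hyphens, apostrophes; accented letters fold to their ASCII base). The
    MRN is left-zero-padded to 8 digits; MRNs longer than 8 digits are
    rejected. The date of birth is rendered ``mmddyyyy``.

    Raises :class:`InvalidNameError`, :class:`InvalidMRNError`, or
    :class:`InvalidDOBError` on the respective field.
    """
    name_token = _fold_letters(record.first_name) + _fold_letters(record.last_name)
    if not name_token:
        raise InvalidNameError("name is empty after removing non-letters")
    mrn = str(record.mrn).strip()
    if not mrn or not mrn.isascii() or not mrn.isdigit():
        raise InvalidMRNError(f"MRN must be a nonempty digit string, got {record.mrn!r}")
    if len(mrn) > MRN_WIDTH:
        raise InvalidMRNError(f"MRN longer than {MRN_WIDTH} digits: {record.mrn!r}")
    if not isinstance(record.dob, date):
        raise InvalidDOBError(f"dob must be a calendar date, got {record.dob!r}")
    return SanitizedInput(
        name_token=name_token,
        mrn_token=mrn.zfill(MRN_WIDTH),
        dob_token=record.dob.strftime("%m%d%Y"),
    )


def ngram_extract(r: int, n: int, m: str, *, overflow: str = "wrap") -> str:
    """Extract the n-gram of ``m`` starting at position ``r mod |m|``.

    The start index is 0-based. When the gram would run past the end of
    ``m`` the string is read circularly (``overflow="wrap"``, the default),
    so the result always has exactly ``n`` characters; ``overflow="reject"``
    raises instead, for callers that want the strict non-wrapping dialect.
    """
    if r < 0:
        raise NHashError("r must be nonnegative")
    if n < 1:
        raise NHashError("gram size must be >= 1")
    if not m:
        raise NHashError("cannot extract an n-gram from an empty string")
    L = len(m)
    s = r % L
    if s + n <= L:
        return m[s : s + n]
    if overflow == "reject":
        raise NHashError(f"n-gram of size {n} at position {s} overruns |m|={L}")
    if overflow != "wrap":
        raise NHashError(f"unknown overflow mode {overflow!r}")
    # n may exceed |m|; wrap as many times as needed
    return "".join(m[(s + i) % L] for i in range(n))


def cantor_pair(k1: int, k2: int) -> int:
    """Cantor pairing function ``(k1+k2)(k1+k2+1)/2 + k2``, exact integers."""
    if k1 < 0 or k2 < 0:
        raise NHashError("Cantor pairing requires nonnegative integers")
    s = k1 + k2
    return s * (s + 1) // 2 + k2


def derive_shift_key(s: SanitizedInput, dob: date) -> ShiftKey:
    """Derive the shift-cipher key from sanitized name length and birth month."""
    k1 = len(s.name_token)
    k2 = dob.month
    c = cantor_pair(k1, k2)
    return ShiftKey(k1=k1, k2=k2, pairing_value=c, letter_shift=c % 26, digit_shift=c % 10)


def _shift(s: str, letter_by: int, digit_by: int) -> str:
    out = []
    for ch in s:
        o = ord(ch)
        if 65 <= o <= 90:
            out.append(chr((o - 65 + letter_by) % 26 + 65))
        elif 48 <= o <= 57:
            out.append(chr((o - 48 + digit_by) % 10 + 48))
        else:
            raise InvalidCharacterError(f"character {ch!r} outside A-Z0-9")
    return "".join(out)


def shift_encrypt(s: str, key: ShiftKey) -> str:
    """Rotate letters forward by ``key.letter_shift`` (mod 26) and digits by
    ``key.digit_shift`` (mod 10); length and per-position character class
    are preserved."""
    return _shift(s, key.letter_shift, key.digit_shift)


def shift_decrypt(s: str, key: ShiftKey) -> str:
    """Exact inverse of :func:`shift_encrypt`."""
    return _shift(s, -key.letter_shift, -key.digit_shift)


def intermediate_string(
    s: SanitizedInput,
    rs: int | list[int] | tuple[int, ...],
    profile: HashProfile = CSR_PROFILE,
    *,
    overflow: str = "wrap",
) -> str:
    """Phase-1 concatenation of the per-component n-grams.

    ``rs`` may be one shared random number (the deployed configuration) or
    a sequence giving one ``r_i`` per component (the general scheme). Only
    the shared form produces an identifier that can later be validated,
    because the suffix stores a single number.
    """
    if isinstance(rs, int):
        rs = [rs] * len(profile.components)
    if len(rs) != len(profile.components):
        raise NHashError(
            f"need {len(profile.components)} per-component random numbers, got {len(rs)}"
        )
    return "".join(
        ngram_extract(r_i, n, s.source(src), overflow=overflow)
        for r_i, (src, n) in zip(rs, profile.components)
    )


def generate_identifier(
    record: DemographicRecord,
    r: int,
    profile: HashProfile = CSR_PROFILE,
) -> NHashIdentifier:
    """Run the full two-phase algorithm for one participant and one ``r``.

    Deterministic: the same (record, r, profile) always yields the same
    identifier, which is what makes regeneration-based validation possible.
    ``r`` must lie in ``[0, profile.random_range)`` so the suffix fits its
    fixed width.
    """
    if not 0 <= r < profile.random_range:
        raise NHashError(
            f"r={r} outside [0, {profile.random_range}) for a "
            f"{profile.random_digits}-digit suffix"
        )
    s = sanitize(record)
    inter = intermediate_string(s, r, profile)
    key = derive_shift_key(s, record.dob)
    cipher = shift_encrypt(inter, key)
    return NHashIdentifier(cipher_part=cipher, random_part=str(r).zfill(profile.random_digits))


def _draw(rng, upper: int) -> int:
    """Uniform integer in [0, upper) from numpy Generator, random.Random,
    or None (cryptographically secure default)."""
    if rng is None:
        return secrets.randbelow(upper)
    if hasattr(rng, "integers"):  # numpy Generator
        return int(rng.integers(0, upper))
    return rng.randrange(upper)  # random.Random


def generate_unique(
    record: DemographicRecord,
    registry,
    rng=None,
    profile: HashProfile = CSR_PROFILE,
    max_retries: int = 100,
    ref=None,
):
    """Generate an identifier absent from ``registry``, insert it, return it.

    Redraws ``r`` on a local collision (an identifier already registered at
    this site), up to ``max_retries`` times; exhausting the retries raises
    :class:`RetryExhaustedError` and signals a saturated registry. With the
    default ``rng=None`` the random number comes from a cryptographically
    secure source; pass a seeded ``numpy`` Generator or ``random.Random``
    for reproducible runs.
    """
    if max_retries < 1:
        raise NHashError("max_retries must be >= 1")
    for _ in range(max_retries):
        r = _draw(rng, profile.random_range)
        ident = generate_identifier(record, r, profile)
        if ident.full not in registry:
            registry.add(ident.full, ref=ref)
            return ident
    raise RetryExhaustedError(
        f"no unused identifier found in {max_retries} draws; registry saturated?"
    )
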