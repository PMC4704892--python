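"""Identifier parsing, regeneration-based validation, error-tolerance
scanning, the local identifier registry, and visit-report naming.

Validation works by regeneration: the random suffix is public, so given
the codebook record (name, MRN, DOB) one recomputes the identifier with
the parsed ``r`` and byte-compares. A mistyped cipher character always
mismatches (regeneration is deterministic); a mistyped suffix digit
changes ``r`` and hence, almost surely, the regenerated cipher part.
Validation therefore always needs the demographic record — without the
codebook the scheme cannot (by design) distinguish a valid identifier
from a well-formed fake.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from datetime import datetime, timezone

from .core import CSR_PROFILE, DemographicRecord, HashProfile, generate_identifier
from .errors import MalformedIdentifierError, ProfileMismatchError

__all__ = [
    "Registry",
    "ValidationReport",
    "ScanResult",
    "parse_identifier",
    "validate_identifier",
    "error_tolerance_scan",
    "report_name",
    "merge_registries",
]

_LETTERS = set("ABCDEFGHIJKLMNOPQRSTUVWXYZ")
_DIGITS = set("0123456789")


def parse_identifier(id_string: str, profile: HashProfile = CSR_PROFILE) -> tuple[str, int]:
    """Split an identifier into (cipher_part, r).

    Rejects wrong length and characters outside the per-position class
    (letters at name-derived positions, digits elsewhere) with
    :class:`MalformedIdentifierError`. A malformed identifier is distinct
    from a well-formed one that merely fails regeneration.
    """
    if len(id_string) != profile.id_length:
        raise MalformedIdentifierError(
            f"expected {profile.id_length} characters, got {len(id_string)}"
        )
    cipher = id_string[: profile.cipher_length]
    suffix = id_string[profile.cipher_length :]
    for ch, cls in zip(cipher, profile.position_classes()):
        if cls == "L" and ch not in _LETTERS:
            raise MalformedIdentifierError(f"expected a letter, found {ch!r}")
        if cls == "D" and ch not in _DIGITS:
            raise MalformedIdentifierError(f"expected a digit, found {ch!r}")
    if not all(ch in _DIGITS for ch in suffix):
        raise MalformedIdentifierError(f"random suffix {suffix!r} is not numeric")
    return cipher, int(suffix)


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of a regeneration check for one identifier."""

    identifier: str
    parsed_r: int
    regenerated: str
    valid: bool
    mismatch_positions: tuple[int, ...]


def validate_identifier(
    id_string: str,
    record: DemographicRecord,
    profile: HashProfile = CSR_PROFILE,
) -> ValidationReport:
    """Regenerate the identifier from the record and the embedded ``r`` and
    byte-compare. ``valid`` is True iff the regenerated identifier equals
    ``id_string`` exactly; ``mismatch_positions`` lists differing indices."""
    _, r = parse_identifier(id_string, profile)
    regen = generate_identifier(record, r, profile).full
    mismatches = tuple(i for i, (a, b) in enumerate(zip(id_string, regen)) if a != b)
    return ValidationReport(
        identifier=id_string,
        parsed_r=r,
        regenerated=regen,
        valid=regen == id_string,
        mismatch_positions=mismatches,
    )


@dataclass(frozen=True)
class ScanResult:
    """Exhaustive single-substitution error-tolerance scan.

    For every position, every same-class substitution (25 per letter,
    9 per digit) is validated against the record; ``fraction_detected``
    is the share flagged invalid. Cipher and suffix positions are broken
    out because cipher edits are detected deterministically while a suffix
    edit is only caught when the new ``r`` regenerates a different cipher.
    """

    total: int
    detected: int
    cipher_total: int
    cipher_detected: int
    suffix_total: int
    suffix_detected: int
    undetected: tuple[str, ...]

    @property
    def fraction_detected(self) -> float:
        return self.detected / self.total if self.total else 1.0


def error_tolerance_scan(
    id_string: str,
    record: DemographicRecord,
    profile: HashProfile = CSR_PROFILE,
) -> ScanResult:
    """Enumerate all single-character same-class substitutions of a valid
    identifier and count how many fail validation."""
    base = validate_identifier(id_string, record, profile)
    if not base.valid:
        raise MalformedIdentifierError(
            "error_tolerance_scan requires an identifier that validates "
            "against the record"
        )
    cipher_len = profile.cipher_length
    totals = {"cipher": 0, "suffix": 0}
    detected = {"cipher": 0, "suffix": 0}
    undetected: list[str] = []
    for i, ch in enumerate(id_string):
        region = "cipher" if i < cipher_len else "suffix"
        alphabet = sorted(_LETTERS) if ch in _LETTERS else sorted(_DIGITS)
        for alt in alphabet:
            if alt == ch:
                continue
            variant = id_string[:i] + alt + id_string[i + 1 :]
            totals[region] += 1
            if not validate_identifier(variant, record, profile).valid:
                detected[region] += 1
            else:
                undetected.append(variant)
    return ScanResult(
        total=totals["cipher"] + totals["suffix"],
        detected=detected["cipher"] + detected["suffix"],
        cipher_total=totals["cipher"],
        cipher_detected=detected["cipher"],
        suffix_total=totals["suffix"],
        suffix_detected=detected["suffix"],
        undetected=tuple(undetected),
    )


def report_name(identifier: str, visit_number: int) -> str:
    """Name a per-visit report: identifier plus a zero-padded 2-digit visit
    number (01-99), e.g. visit 1 of TSXP606170783305 -> TSXP60617078330501."""
    if not 1 <= visit_number <= 99:
        raise ValueError(f"visit_number must be in 1..99, got {visit_number}")
    return f"{identifier}{visit_number:02d}"


class Registry:
    """Local site registry of issued identifiers.

    Maps identifier -> opaque local reference (never PHI). Persisted as
    JSON lines, one entry per line with fields ``id``, ``ref``, ``site``,
    ``created`` — append-friendly and auditable. The expected identifier
    width (from the active profile) is enforced on insert when set.
    """

    def __init__(self, site: str = "local", id_length: int | None = CSR_PROFILE.id_length):
        self.site = site
        self.id_length = id_length
        self._entries: dict[str, dict] = {}

    def __contains__(self, identifier: str) -> bool:
        return identifier in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries)

    @property
    def entries(self) -> dict[str, dict]:
        return dict(self._entries)

    def add(self, identifier: str, ref=None, created: str | None = None) -> None:
        if self.id_length is not None and len(identifier) != self.id_length:
            raise ProfileMismatchError(
                f"identifier length {len(identifier)} != registry width {self.id_length}"
            )
        if identifier in self._entries:
            raise ProfileMismatchError(f"identifier {identifier} already registered")
        self._entries[identifier] = {
            "id": identifier,
            "ref": ref,
            "site": self.site,
            "created": created or datetime.now(timezone.utc).isoformat(),
        }

    def get(self, identifier: str) -> dict | None:
        return self._entries.get(identifier)

    def save(self, path: str | os.PathLike) -> None:
        """Write JSON-lines atomically (temp file + rename)."""
        tmp = f"{path}.tmp"
        with open(tmp, "w", encoding="utf-8") as fh:
            for entry in self._entries.values():
                fh.write(json.dumps(entry, sort_keys=True) + "\n")
        os.replace(tmp, path)

    @classmethod
    def load(cls, path: str | os.PathLike, id_length: int | None = None) -> "Registry":
        reg = cls(id_length=None)
        site = None
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                entry = json.loads(line)
                reg._entries[entry["id"]] = entry
                site = entry.get("site", site)
        if site:
            reg.site = site
        reg.id_length = id_length
        if id_length is None and reg._entries:
            widths = {len(k) for k in reg._entries}
            if len(widths) == 1:
                reg.id_length = widths.pop()
        return reg


def merge_registries(central: Registry, incoming: Registry) -> tuple[Registry, list[dict]]:
    """Union two site registries, reporting cross-site collisions.

    Identifiers present in both are returned in the collision list (with
    both entries preserved) and are *not* overwritten in the merged result;
    the caller is expected to have the colliding site regenerate. Raises
    :class:`ProfileMismatchError` if the registries use different widths.
    """
    if (
        central.id_length is not None
        and incoming.id_length is not None
        and central.id_length != incoming.id_length
    ):
        raise ProfileMismatchError(
            f"registry widths differ: {central.id_length} vs {incoming.id_length}"
        )
    merged = Registry(site=central.site, id_length=central.id_length)
    merged._entries = dict(central._entries)
    collisions: list[dict] = []
    for ident, entry in incoming._entries.items():
        if ident in merged._entries:
            collisions.append(
                {"id": ident, "central": merged._entries[ident], "incoming": entry}
            )
        else:
            merged._entries[ident] = entry
    return merged, collisions
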