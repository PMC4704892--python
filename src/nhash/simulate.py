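"""Synthetic-cohort generation and collision-counting experiments.

The simulator emulates the enrollment stream of a large multicenter
study: participants with frequency-weighted US surnames and first names,
uniform 8-digit medical record numbers (leading zeros allowed), and
birth dates uniform over 1910-01-01..2015-12-31. Identifiers — NHash or
a random-string baseline (4 uniform letters + n-4 uniform digits) — are
generated for the stream, and collisions are counted as insertions that
land on an already-seen identifier, the quantity whose expectation is the
closed-form EC of :mod:`nhash.collisions`.

Counting streams through a set, so memory is bounded by the number of
*distinct* identifiers, never the raw record stream.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from datetime import date, timedelta
from functools import cached_property
from typing import Iterable

import numpy as np
import pandas as pd

from . import _namedata
from .collisions import (
    csr_bounds,
    expected_collisions,
    random_string_inverse_probability,
)
from .core import CSR_PROFILE, DemographicRecord, HashProfile, generate_identifier
from .errors import NHashError

__all__ = [
    "SyntheticCohortConfig",
    "ExperimentResult",
    "default_config",
    "load_name_table",
    "sample_person",
    "sample_cohort",
    "random_string_id",
    "count_collisions",
    "run_experiment",
]

#: Default per-run size cap; the full-scale published protocol (1e8 records
#: per run) is possible but must be requested explicitly via allow_large.
DEFAULT_MAX_SIZE = 10**6

_LETTERS = np.array(list(string.ascii_uppercase))
_DIGITS = np.array(list(string.digits))


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Generation rules for one synthetic cohort.

    Name tables are (name, weight) pairs sampled proportionally to weight;
    MRNs are uniform ``mrn_digits``-digit strings; DOBs are uniform over
    the closed day range ``[dob_start, dob_end]``.
    """

    surnames: tuple[tuple[str, float], ...]
    firstnames: tuple[tuple[str, float], ...]
    mrn_digits: int = 8
    dob_start: date = date(1910, 1, 1)
    dob_end: date = date(2015, 12, 31)

    def __post_init__(self) -> None:
        for table in (self.surnames, self.firstnames):
            if not table:
                raise NHashError("name tables must be non-empty")
            if any(w <= 0 or not np.isfinite(w) for _, w in table):
                raise NHashError("name weights must be positive and finite")
        if self.dob_end < self.dob_start:
            raise NHashError("dob range is empty")

    @cached_property
    def _surname_probs(self) -> np.ndarray:
        w = np.array([w for _, w in self.surnames], dtype=float)
        return w / w.sum()

    @cached_property
    def _firstname_probs(self) -> np.ndarray:
        w = np.array([w for _, w in self.firstnames], dtype=float)
        return w / w.sum()

    @property
    def n_days(self) -> int:
        return (self.dob_end - self.dob_start).days + 1


def default_config() -> SyntheticCohortConfig:
    """Config with the bundled frequency-weighted US name tables."""
    return SyntheticCohortConfig(
        surnames=tuple(_namedata.SURNAMES),
        firstnames=tuple(_namedata.FIRST_NAMES),
    )


def load_name_table(path) -> tuple[tuple[str, float], ...]:
    """Read a 2-column delimited (name, weight) file; comma or whitespace."""
    out: list[tuple[str, float]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(",") if "," in line else line.split()
            if len(parts) != 2:
                raise NHashError(f"expected 'name,weight' rows, got {line!r}")
            out.append((parts[0].strip(), float(parts[1])))
    if not out:
        raise NHashError(f"no name rows in {path}")
    return tuple(out)


def sample_person(rng: np.random.Generator, config: SyntheticCohortConfig) -> DemographicRecord:
    """Draw one synthetic participant: weighted names, uniform MRN and DOB."""
    first = config.firstnames[rng.choice(len(config.firstnames), p=config._firstname_probs)][0]
    last = config.surnames[rng.choice(len(config.surnames), p=config._surname_probs)][0]
    mrn = "".join(_DIGITS[rng.integers(0, 10, size=config.mrn_digits)])
    dob = config.dob_start + timedelta(days=int(rng.integers(0, config.n_days)))
    return DemographicRecord(first_name=first, last_name=last, mrn=mrn, dob=dob)


def sample_cohort(
    rng: np.random.Generator, config: SyntheticCohortConfig, size: int
) -> list[DemographicRecord]:
    """Draw ``size`` participants; vectorized equivalent of repeated
    :func:`sample_person` (the per-field draw order differs, so streams
    from the two paths are not interleavable under one seed)."""
    fi = rng.choice(len(config.firstnames), size=size, p=config._firstname_probs)
    li = rng.choice(len(config.surnames), size=size, p=config._surname_probs)
    mrn_digits = rng.integers(0, 10, size=(size, config.mrn_digits))
    days = rng.integers(0, config.n_days, size=size)
    firstnames = [config.firstnames[i][0] for i in fi]
    surnames = [config.surnames[i][0] for i in li]
    mrns = ["".join(row) for row in _DIGITS[mrn_digits]]
    start = config.dob_start
    return [
        DemographicRecord(f, s, m, start + timedelta(days=int(d)))
        for f, s, m, d in zip(firstnames, surnames, mrns, days)
    ]


def random_string_id(rng: np.random.Generator, n: int) -> str:
    """One length-n baseline identifier: 4 uniform uppercase letters then
    n-4 uniform digits (inverse probability 26^4 * 10^(n-4))."""
    if n < 5:
        raise NHashError("random-string baseline needs n >= 5")
    letters = _LETTERS[rng.integers(0, 26, size=4)]
    digits = _DIGITS[rng.integers(0, 10, size=n - 4)]
    return "".join(letters) + "".join(digits)


def _random_string_ids(rng: np.random.Generator, n: int, count: int) -> list[str]:
    """Vectorized batch of baseline identifiers (same charset as
    :func:`random_string_id`)."""
    if n < 5:
        raise NHashError("random-string baseline needs n >= 5")
    letters = _LETTERS[rng.integers(0, 26, size=(count, 4))]
    digits = _DIGITS[rng.integers(0, 10, size=(count, n - 4))]
    chars = np.concatenate([letters, digits], axis=1)
    return ["".join(row) for row in chars]


def count_collisions(ids: Iterable[str]) -> int:
    """Insertions landing on an occupied slot: len(stream) - len(distinct).

    Streams through a set, so an iterator of any length is accepted without
    materializing it.
    """
    seen: set[str] = set()
    inserted = 0
    for ident in ids:
        inserted += 1
        seen.add(ident)
    return inserted - len(seen)


@dataclass(frozen=True)
class ExperimentResult:
    """Replicated collision counts for one method at one cohort size.

    ``ec`` is the analytic expectation at the method's inverse probability
    (for NHash, the lower-bound total — the convention used when quoting a
    single EC); ``ec_upper`` is additionally set for NHash, giving the
    uniform upper-bound expectation that brackets the truth from below.
    """

    method: str
    size: int
    runs: int
    base_seed: int
    counts: tuple[int, ...]
    ec: float
    ec_upper: float | None = None

    @property
    def mean(self) -> float:
        return float(np.mean(self.counts))

    def to_frame(self) -> pd.DataFrame:
        row: dict[str, object] = {f"Run {i + 1}": c for i, c in enumerate(self.counts)}
        row["Average"] = self.mean
        row["EC"] = self.ec
        if self.ec_upper is not None:
            row["EC (upper bound)"] = self.ec_upper
        return pd.DataFrame([row], index=[self.method])


def _nhash_run(rng: np.random.Generator, size: int, profile: HashProfile,
               config: SyntheticCohortConfig) -> Iterable[str]:
    upper = profile.random_range
    for record in sample_cohort(rng, config, size):
        r = int(rng.integers(0, upper))
        yield generate_identifier(record, r, profile).full


def run_experiment(
    method: str,
    size: int,
    runs: int,
    base_seed: int,
    profile: HashProfile | None = None,
    config: SyntheticCohortConfig | None = None,
    max_size: int = DEFAULT_MAX_SIZE,
    allow_large: bool = False,
) -> ExperimentResult:
    """Run ``runs`` independent collision-counting replicates.

    ``method`` is ``"random:<n>"`` for the length-n random-string baseline
    or ``"nhash"`` for full identifier generation over a synthetic cohort
    (CSR profile unless ``profile`` is given). Per-run seeds are spawned
    from ``base_seed`` via ``numpy.random.SeedSequence``, so identical
    arguments reproduce the table exactly. Sizes above ``max_size`` per
    run are refused unless ``allow_large=True`` — the published protocol's
    1e8-record runs take hours and tens of GB of identifier set.
    """
    if size < 1 or runs < 1:
        raise NHashError("size and runs must be >= 1")
    if size > max_size and not allow_large:
        raise NHashError(
            f"size {size} exceeds the per-run cap {max_size}; "
            "pass allow_large=True to opt in"
        )
    seeds = np.random.SeedSequence(base_seed).spawn(runs)
    counts: list[int] = []
    if method.startswith("random:"):
        n = int(method.split(":", 1)[1])
        N = random_string_inverse_probability(n)
        for ss in seeds:
            rng = np.random.default_rng(ss)
            counts.append(count_collisions(_random_string_ids(rng, n, size)))
        return ExperimentResult(
            method=f"Random-{n}", size=size, runs=runs, base_seed=base_seed,
            counts=tuple(counts), ec=expected_collisions(N, size),
        )
    if method == "nhash":
        profile = profile or CSR_PROFILE
        config = config or default_config()
        bounds = csr_bounds(profile)
        for ss in seeds:
            rng = np.random.default_rng(ss)
            counts.append(count_collisions(_nhash_run(rng, size, profile, config)))
        return ExperimentResult(
            method=f"NHash-{profile.id_length}", size=size, runs=runs,
            base_seed=base_seed, counts=tuple(counts),
            ec=expected_collisions(bounds.lower_total, size),
            ec_upper=expected_collisions(bounds.upper_total, size),
        )
    raise NHashError(f"unknown method {method!r}; use 'random:<n>' or 'nhash'")
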