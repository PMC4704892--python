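# Methods

## The identifier scheme

NHash maps a participant's demographics — name, medical record number
(MRN), date of birth (DOB) — plus a random number *r* to a fixed-width
alphanumeric pseudonym in two phases.

**Phase 1 (randomized n-grams).** The demographics are sanitized into
three canonical strings: the name uppercased with every non-letter
removed (diacritics fold to their ASCII base where Unicode decomposition
provides one, and are dropped otherwise), the MRN left-zero-padded to 8
digits, the DOB rendered `mmddyyyy`. For each string *m* the component
n-gram starts at the 0-based offset *r* mod |*m*| and is read circularly:
if the gram would run past the end of the string it wraps to the front,
so the output length is always exactly *n* regardless of the offset.
Circular reading is the package's resolution of the boundary case the
scheme's informal description leaves open (an offset as late as |*m*|−1
is always possible); a strict `overflow="reject"` dialect is provided for
interoperability testing. The component grams are concatenated in profile
order.

**Phase 2 (shift cipher).** The concatenation is encrypted with a
per-participant shift cipher so that raw name letters and MRN/DOB digits
never appear in the identifier. The key is the Cantor pairing
*C = (k₁+k₂)(k₁+k₂+1)/2 + k₂* of *k₁* = length of the *sanitized* name
token and *k₂* = birth month (1–12); letters rotate forward by *C* mod 26,
digits by *C* mod 10, each within their own alphabet, so the
letter/digit pattern of the identifier is invariant. The identifier is
the ciphertext concatenated with *r* zero-padded to the profile's suffix
width. Zero-padding keeps identifiers fixed-width and makes the suffix
parseable without a delimiter.

A **profile** fixes the shape: an ordered list of (source, n) components
and the suffix width. The default ("csr") profile is 4-gram of name,
4-gram of MRN, 2-gram of DOB, 6-digit suffix — 16-character identifiers,
with *r* uniform on [0, 10⁶). The upper endpoint is taken exclusive so
the suffix always fits its 6 digits. The general scheme admits distinct
random numbers per component (`intermediate_string` accepts a sequence),
but only the shared-*r* form is invertible for validation, because the
suffix stores a single number; `generate_identifier` therefore always
shares one *r*.

**Local uniqueness.** `generate_unique` redraws *r* (default cap: 100
attempts) whenever the fresh identifier is already in the site registry,
and raises after the cap — at realistic registry sizes a single redraw is
already rare, so hitting the cap indicates a saturated or misconfigured
registry. Production draws come from a cryptographically secure source
by default; tests and simulations pass seeded generators.

## Validation and error tolerance

Validation is regeneration: parse the suffix as *r*, recompute the
identifier from the codebook record, byte-compare. The package
distinguishes *malformed* (wrong length, character outside the
position's class — refused at parse time) from *well-formed but invalid*
(parses fine, fails regeneration); conflating the two would hide data
errors behind formatting errors. Validation intrinsically requires the
demographic record: without the codebook the scheme cannot — by design —
distinguish a valid identifier from a plausible fake.

The error-tolerance scan enumerates every single-position substitution
that stays within the position's character class (25 alternatives per
letter, 9 per digit; class-crossing edits are already malformed) and
validates each variant. Cipher-position edits are detected with
certainty, since regeneration from the unchanged suffix deterministically
reproduces the original cipher. A suffix edit changes *r*, so detection
requires the new *r* to regenerate a different cipher part; failure would
need an accidental fixed-point and none exists among the 208 variants of
the worked example (verified exhaustively, including against a
brute-force reimplementation).

Per-visit report names append a 2-digit visit number (01–99) to the
identifier; visit 0 is disallowed so the numbering matches the 01-based
convention of deployed report names.

**Registries** persist as JSON lines (`id`, `ref`, `site`, `created` per
line) — append-friendly, auditable, trivially convertible. Merging two
site registries returns the union plus the list of identifiers present
in both, with both entries preserved; nothing is overwritten, and the
colliding site is expected to regenerate. The scheme deliberately does
not detect the converse failure (the same person enrolled at two sites
receiving two identifiers): that is a documented limitation of
decentralized generation, not solvable from identifiers alone.

## Collision model

Identifier generation is modeled as uniform insertion of *I* balls into
*N* bins, where *N* — the *inverse probability* — is the effective number
of equally likely identifier values. The expected number of empty bins
after *I* insertions is EE = N(1 − 1/N)^I, the occupied count is N − EE,
and the expected number of collisions (insertions landing on an occupied
bin) is

    EC = I − N + N(1 − 1/N)^I.

*N* is bracketed per component: the name 4-gram contributes between 10⁴
(5-letter names dominate real name-length distributions, and name
frequencies are heavily skewed) and 26⁴ (uniform letters); the MRN
4-gram between 9⁴ and 10⁴ (the lower bound discounts one digit value per
position as a conservative convention; it is adopted as a constant, not
re-derived); the DOB 2-gram 10² on both sides (only the two trailing
year digits vary freely across the full range, so 10² is itself an
underestimate); the random suffix contributes exactly 10^(suffix
digits). For the default profile the exact totals are 6.561 × 10¹⁵ and
4.56976 × 10¹⁷.

**Numerical evaluation.** At N ≈ 10¹⁵ and I ≤ 10⁸ the term (1 − 1/N)^I
differs from 1 by ~10⁻⁷ while 1/N sits below double-precision resolution
of 1; the naive formula loses every significant digit. `expected_collisions`
and `expected_empty_slots` therefore evaluate in mpmath arbitrary
precision at 50 significant digits (leaving >30 digits of headroom at
N = 10¹⁸) and return a float. The tests check agreement with an
independent 200-digit exp/log evaluation to 10⁻⁹ relative. Published
reference values for this model are quoted at *rounded* N (6.6 × 10¹⁵,
4.6 × 10¹², …); the reproduction tests pass those rounded N values
rather than the exact products, which is what matches numbers like
1086.95 — the exact-product evaluations are exposed alongside.

Reference points (recomputed by `scripts/acceptance.py`): EC(6.6 × 10¹⁵,
10⁶) = 0.000076; EC(6.6 × 10¹⁵, 10⁸) = 0.76; EC(4.6 × 10¹⁷, 10⁸) =
0.0109; EC(4.6 × 10¹², 10⁸) = 1086.95.

## Synthetic cohort and simulations

The cohort generator emulates a large multicenter enrollment stream:
surnames and first names drawn proportionally to frequency weights, MRNs
uniform over 8-digit strings (leading zeros allowed), DOBs uniform over
1910-01-01..2015-12-31. The bundled tables hold ~160 common US surnames
and ~100 given names with approximate per-100k weights; the skew of the
weights, not the specific names, is what matters, since the analytic EC
checks — not name realism — carry the evidential weight. Users wanting
the full published rank lists (top 5000 surnames / 2500 first names) can
load their own two-column files.

What the generator does *not* emulate: name-length distribution tails,
correlated fields (ethnicity-linked surname/first-name pairs), MRN
assignment schemes of real hospitals, or non-uniform birth-date
seasonality. Passing simulations therefore demonstrate the collision
*arithmetic* under the stated sampling assumptions, not collision rates
of any particular hospital population.

The **random-string baseline** (length *n*) is 4 uniform uppercase
letters followed by *n* − 4 uniform digits, giving inverse probability
26⁴ · 10^(n−4). This composition is an inference: it is the unique
simple letters+digits split consistent with the published baseline EC
column (e.g. 4.6 × 10¹² for length 11), and it is overridable by
construction (any id stream can be fed to `count_collisions`).

`count_collisions` streams identifiers through a set and reports
insertions − distinct, the quantity whose expectation is EC.
`run_experiment` runs independent replicates with per-run seeds spawned
from a base seed (`numpy.random.SeedSequence`), so every table is
exactly reproducible. For NHash runs each record draws a fresh *r* with
replacement, without a deduplicating registry — matching the model the
EC formula describes. Experiment sizes default to a per-run cap of 10⁶
records (the test-suite runs use 10⁴–10⁵ with 20 replicates, which keeps
the whole suite in seconds while leaving the baseline EC around 11
collisions per run — comfortably measurable); full-scale 10⁸-record
replication is supported behind an explicit opt-in flag, as it needs
hours and tens of gigabytes for the identifier set.

Statistical acceptance bands: replicate means are compared with EC using
Poisson-style bands (σ ≈ √EC) divided by √runs; the NHash scaled runs,
whose bracketing ECs are ≪ 1 collision per run, add a +0.25 variance
floor inside the square root so that count discreteness cannot produce a
vacuously impossible band.

## Design choices where the scheme was underspecified

- **0-based offsets.** Forced by the worked example: offset 783305 mod
  13 = 3 selects `ONSK` from `AARONSKOTNICA` only with 0-based indexing.
- **k₁ counts the sanitized token** (13 for "AARONSKOTNICA"), not the raw
  name with spaces.
- **Circular n-gram overflow** (above), with a `reject` dialect flag.
- **MRNs shorter than 8 digits are left-zero-padded; longer are
  rejected** — 8 digits with possibly-leading zeros is the assumed
  hospital format.
- **Suffix zero-padding and the exclusive random upper bound** (above).
- **Identifier regenerated for a mistyped suffix**: the worked example's
  typo 783306 regenerates `SXPT061302783306` (16 characters). The
  scheme's own description elsewhere prints an 18-character string for
  this case whose first 10 cipher characters agree with recomputation;
  the 2 extra characters are treated as a typesetting artifact and not
  imitated.
- **Visit postfix fixed at 2 digits, 01–99.**

## Known limitations

- False splits (one person, two sites, two identifiers) are undetectable
  by construction.
- Validation requires codebook access; the identifier alone cannot be
  authenticated.
- The shift cipher is a deterrent against casual inspection and
  dictionary attacks on raw n-grams, not cryptographically strong
  encryption; profiles trade PHI leakage (longer grams) against
  identifier-space size.
- The collision bounds treat components as independent and uniform
  within their bound; real demographic correlations are only captured to
  the extent the lower bounds discount them.
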