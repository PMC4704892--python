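# nhash — decentralized, validatable study identifiers

`nhash` implements randomized n-gram hashing (NHash) for generating unique
study identifiers in multicenter clinical research. Each participating
site generates pseudonyms locally — no central identifier service, no
shared code blocks — yet the identifiers are globally collision-safe with
overwhelming probability and, unlike sequential or purely random codes,
*validatable*: anyone holding the codebook record can recompute an
identifier and detect transcription errors.

It is intended for clinical research informatics teams running
multicenter studies who need participant pseudonyms that (a) carry no
protected health information, (b) can be minted independently at each
site, and (c) can be checked for typos against the honest broker's
codebook.

## The algorithm

For a participant with name, medical record number (MRN) and date of
birth (DOB), and a random number *r*:

1. **Sanitize.** Uppercase the name and strip non-letters (`m1`),
   left-zero-pad the MRN to 8 digits (`m2`), render the DOB as
   `mmddyyyy` (`m3`).
2. **Randomized n-grams.** For each field *mᵢ* extract the *nᵢ*-gram
   starting at position *sᵢ = r mod |mᵢ|* (read circularly). The default
   profile takes a 4-gram of name, a 4-gram of MRN and a 2-gram of DOB,
   concatenated into an intermediate string.
3. **Shift cipher.** Compute the Cantor pairing
   *C = ½(k₁+k₂)(k₁+k₂+1) + k₂* of *k₁* = sanitized name length and
   *k₂* = birth month; rotate letters by *C* mod 26 and digits by
   *C* mod 10.
4. **Assemble.** Identifier = ciphertext ‖ zero-padded *r*
   (16 characters for the default profile). A local registry check
   redraws *r* on the rare within-site duplicate.

Because *r* is embedded in clear, validation is regeneration: recompute
the identifier from the codebook demographics and the parsed *r*, and
byte-compare. Any cipher-position edit is caught deterministically; a
suffix edit changes *r* and almost surely regenerates a different
ciphertext.

Collision risk is quantified by the balls-in-bins model: with *N* equally
likely identifier values and *I* insertions, the expected number of
collisions is **EC = I − N + N(1 − 1/N)^I**. For the default profile *N*
is between 6.6 × 10¹⁵ and 4.6 × 10¹⁷, so EC stays below one even at 10⁸
enrollments. The package evaluates EC in arbitrary precision (the naive
double-precision formula cancels catastrophically at these scales).

## Worked example

```bash
python examples/generate_and_validate.py
```

prints

```
sanitized inputs : AARONSKOTNICA 07172485 08131956
intermediate     : ONSK717281
shift key        : C=239 (letters +5, digits +9)
identifier       : TSXP606170783305
validates        : True
suffix typo      : False - regeneration gives SXPT061302783306
```

For Aaron Skotnica (MRN 07172485, DOB 08/13/1956) and *r* = 783305, the
n-grams start at offsets 783305 mod 13 = 3, mod 8 = 1, mod 8 = 1, giving
`ONSK`+`7172`+`81`; the Cantor key 239 shifts letters by 5 and digits
by 9, producing `TSXP606170`, and appending *r* yields the identifier.
Mistyping the final digit (783306) regenerates a different cipher part,
so the typo is detected. The other examples scan all 208 single-character
typos (all detected), print the collision-bound table, and run scaled
collision simulations against the closed-form EC.

## Command line

```bash
nhash generate --csv demographics.csv --out coded.csv --registry site.jsonl
nhash validate --id TSXP606170783305 --csv demographics.csv
nhash merge --central a.jsonl --incoming b.jsonl --out merged.jsonl
nhash ec --N 6.6e15 --I 1e8
nhash ec-table --profile csr
nhash simulate --method random:11 --size 100000 --runs 5 --seed 42
```

Exit codes: 0 success, 1 validation failure, 2 malformed input,
3 environment error. Audit logs never contain PHI.

## Documentation

See `docs/methods.md` for the model, its assumptions, parameter choices,
numerical notes, and what the synthetic-cohort simulations do and do not
demonstrate.
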