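"""Unit and property tests for sanitization, n-gram extraction, the
Cantor-pairing shift key, the shift cipher, and identifier assembly."""

from __future__ import annotations

import random
import string
from datetime import date

import pytest
from hypothesis import given, settings, strategies as st

import nhash
from nhash import (
    CSR_PROFILE,
    DemographicRecord,
    HashProfile,
    InvalidDOBError,
    InvalidMRNError,
    InvalidNameError,
    NHashError,
    Registry,
    RetryExhaustedError,
    cantor_pair,
    derive_shift_key,
    generate_identifier,
    generate_unique,
    ngram_extract,
    parse_dob,
    sanitize,
    shift_decrypt,
    shift_encrypt,
)
from nhash.core import ShiftKey

from .conftest import ref_ngram, ref_shift

ALNUM = string.ascii_uppercase + string.digits


class TestSanitize:
    def test_worked_example_tokens(self, aaron):
        s = sanitize(aaron)
        assert s.name_token == "AARONSKOTNICA"
        assert s.mrn_token == "07172485"
        assert s.dob_token == "08131956"

    def test_punctuation_case_and_padding(self):
        rec = DemographicRecord("o'Hara", "X", "1", date(2000, 1, 2))
        s = sanitize(rec)
        assert s.name_token == "OHARAX"
        assert s.mrn_token == "00000001"
        assert s.dob_token == "01022000"

    def test_diacritics_fold_to_ascii(self):
        rec = DemographicRecord("José", "Muñoz-Núñez", "42", date(1980, 12, 31))
        assert sanitize(rec).name_token == "JOSEMUNOZNUNEZ"

    @pytest.mark.parametrize(
        "record, err",
        [
            (DemographicRecord("  ", "''", "1234", date(1990, 1, 1)), InvalidNameError),
            (DemographicRecord("A", "B", "1234567890", date(1990, 1, 1)), InvalidMRNError),
            (DemographicRecord("A", "B", "12a4", date(1990, 1, 1)), InvalidMRNError),
            (DemographicRecord("A", "B", "", date(1990, 1, 1)), InvalidMRNError),
            (DemographicRecord("A", "B", "1234", "1990-01-01"), InvalidDOBError),
        ],
    )
    def test_distinct_validation_errors(self, record, err):
        with pytest.raises(err):
            sanitize(record)

    def test_parse_dob_both_dialects(self):
        assert parse_dob("08/13/1956") == date(1956, 8, 13)
        assert parse_dob("1956-08-13") == date(1956, 8, 13)
        with pytest.raises(InvalidDOBError):
            parse_dob("13/08/1956")


class TestNgramExtract:
    @pytest.mark.parametrize(
        "r, n, m, expected",
        [
            (783305, 4, "AARONSKOTNICA", "ONSK"),
            (783305, 4, "07172485", "7172"),
            (783305, 2, "08131956", "81"),
            (0, 3, "ABC", "ABC"),
            (12, 4, "AARONSKOTNICA", "AAAR"),  # wraps past the end
        ],
    )
    def test_examples(self, r, n, m, expected):
        assert ngram_extract(r, n, m) == expected

    def test_reject_dialect_refuses_overflow(self):
        with pytest.raises(NHashError):
            ngram_extract(12, 4, "AARONSKOTNICA", overflow="reject")
        assert ngram_extract(3, 4, "AARONSKOTNICA", overflow="reject") == "ONSK"

    def test_empty_string_rejected(self):
        with pytest.raises(NHashError):
            ngram_extract(1, 1, "")

    @settings(derandomize=True, max_examples=300)
    @given(
        r=st.integers(min_value=0, max_value=10**9),
        n=st.integers(min_value=1, max_value=30),
        m=st.text(alphabet=ALNUM, min_size=1, max_size=20),
    )
    def test_offset_law_and_length_against_oracle(self, r, n, m):
        """Start index is r mod |m| and the result has exactly n characters,
        matching the doubled-string reference implementation."""
        got = ngram_extract(r, n, m)
        assert len(got) == n
        assert got[0] == m[r % len(m)]
        assert got == ref_ngram(r, n, m)


class TestCantorAndKey:
    @pytest.mark.parametrize("k1, k2, expected", [(13, 8, 239), (0, 0, 0), (1, 2, 8)])
    def test_pairing_values(self, k1, k2, expected):
        assert cantor_pair(k1, k2) == expected

    def test_negative_rejected(self):
        with pytest.raises(NHashError):
            cantor_pair(-1, 0)

    @settings(derandomize=True, max_examples=200)
    @given(k1=st.integers(0, 10**6), k2=st.integers(0, 10**6))
    def test_closed_form(self, k1, k2):
        assert cantor_pair(k1, k2) == (k1 + k2) * (k1 + k2 + 1) // 2 + k2

    def test_worked_example_key(self, aaron):
        key = derive_shift_key(sanitize(aaron), aaron.dob)
        assert (key.k1, key.k2) == (13, 8)
        assert key.pairing_value == 239
        assert key.letter_shift == 5
        assert key.digit_shift == 9

    def test_small_key(self):
        rec = DemographicRecord("A", "B", "1", date(1999, 1, 1))
        key = derive_shift_key(sanitize(rec), rec.dob)
        assert (key.k1, key.k2, key.pairing_value) == (2, 1, 7)
        assert key.letter_shift == 7 and key.digit_shift == 7


class TestShiftCipher:
    KEY = ShiftKey(k1=13, k2=8, pairing_value=239, letter_shift=5, digit_shift=9)

    def test_worked_example(self):
        assert shift_encrypt("ONSK717281", self.KEY) == "TSXP606170"
        assert shift_decrypt("TSXP606170", self.KEY) == "ONSK717281"

    def test_identity_and_wraparound(self):
        zero = ShiftKey(0, 0, 0, 0, 0)
        assert shift_encrypt("AZ09", zero) == "AZ09"
        one = ShiftKey(0, 0, 0, 1, 1)
        assert shift_encrypt("Z9", one) == "A0"

    def test_rejects_foreign_characters(self):
        with pytest.raises(NHashError):
            shift_encrypt("a1", self.KEY)
        with pytest.raises(NHashError):
            shift_encrypt("A-1", self.KEY)

    def test_round_trip_1000_random_strings(self):
        rng = random.Random(7)
        for _ in range(1000):
            s = "".join(rng.choices(ALNUM, k=rng.randint(1, 30)))
            key = ShiftKey(0, 0, 0, rng.randrange(26), rng.randrange(10))
            assert shift_decrypt(shift_encrypt(s, key), key) == s

    @settings(derandomize=True, max_examples=200)
    @given(
        s=st.text(alphabet=ALNUM, max_size=40),
        ls=st.integers(0, 25),
        ds=st.integers(0, 9),
    )
    def test_bijectivity_and_class_preservation(self, s, ls, ds):
        key = ShiftKey(0, 0, 0, ls, ds)
        enc = shift_encrypt(s, key)
        assert shift_decrypt(enc, key) == s
        assert len(enc) == len(s)
        for a, b in zip(s, enc):
            assert a.isdigit() == b.isdigit()
        assert enc == ref_shift(s, ls, ds)


class TestGenerateIdentifier:
    def test_worked_example_full_pipeline(self, aaron):
        ident = generate_identifier(aaron, 783305)
        assert ident.full == "TSXP606170783305"
        assert ident.cipher_part == "TSXP606170"
        assert ident.random_part == "783305"
        assert ident.r == 783305
        assert nhash.intermediate_string(sanitize(aaron), 783305) == "ONSK717281"

    def test_adjacent_random_number_changes_cipher(self, aaron):
        # one more than the worked example: offsets move to (4, 2, 2)
        assert generate_identifier(aaron, 783306).full == "SXPT061302783306"

    def test_zero_r(self, aaron):
        ident = generate_identifier(aaron, 0)
        assert ident.random_part == "000000"
        s = sanitize(aaron)
        key = derive_shift_key(s, aaron.dob)
        expected = shift_encrypt(s.name_token[:4] + s.mrn_token[:4] + s.dob_token[:2], key)
        assert ident.cipher_part == expected

    def test_r_out_of_range(self, aaron):
        with pytest.raises(NHashError):
            generate_identifier(aaron, 10**6)
        with pytest.raises(NHashError):
            generate_identifier(aaron, -1)

    def test_determinism(self, aaron):
        a = generate_identifier(aaron, 123456).full
        b = generate_identifier(aaron, 123456).full
        assert a == b

    @settings(derandomize=True, max_examples=200)
    @given(
        first=st.text(alphabet=string.ascii_letters + " '-", min_size=1, max_size=12),
        last=st.text(alphabet=string.ascii_letters + " '-", min_size=1, max_size=12),
        mrn=st.text(alphabet=string.digits, min_size=1, max_size=8),
        days=st.integers(0, 38000),
        r=st.integers(0, 10**6 - 1),
    )
    def test_length_and_class_invariant(self, first, last, mrn, days, r):
        """Identifiers are fixed-width with letters at name positions and
        digits everywhere else, for every sanitizable input."""
        from datetime import timedelta

        rec = DemographicRecord(first, last, mrn, date(1910, 1, 1) + timedelta(days=days))
        try:
            ident = generate_identifier(rec, r)
        except InvalidNameError:
            return  # name had no letters: correctly rejected
        full = ident.full
        assert len(full) == CSR_PROFILE.id_length == 16
        assert full[:4].isalpha() and full[:4].isupper()
        assert full[4:].isdigit()

    def test_custom_profile_shapes_output(self, aaron):
        prof = HashProfile(components=(("name", 2), ("dob", 3)), random_digits=4)
        ident = generate_identifier(aaron, 17, prof)
        assert len(ident.full) == 9
        assert ident.full[:2].isalpha() and ident.full[2:5].isdigit()
        assert ident.random_part == "0017"


class TestGenerateUnique:
    def test_empty_registry_first_draw_accepted(self, aaron):
        reg = Registry()
        rng = random.Random(1)
        expected_r = random.Random(1).randrange(10**6)
        ident = generate_unique(aaron, reg, rng=rng)
        assert ident.r == expected_r
        assert ident.full in reg

    def test_local_collision_triggers_redraw(self, aaron):
        probe = random.Random(99)
        first_r, second_r = probe.randrange(10**6), probe.randrange(10**6)
        reg = Registry()
        reg.add(generate_identifier(aaron, first_r).full)
        ident = generate_unique(aaron, reg, rng=random.Random(99))
        assert ident.r == second_r

    def test_numpy_generator_accepted(self, aaron):
        import numpy as np

        reg = Registry()
        a = generate_unique(aaron, reg, rng=np.random.default_rng(5))
        b = generate_unique(aaron, Registry(), rng=np.random.default_rng(5))
        assert a.full == b.full

    def test_saturated_registry_exhausts_retries(self, aaron):
        # a 1-digit suffix has only 10 variants per record
        prof = HashProfile(random_digits=1)
        reg = Registry(id_length=prof.id_length)
        for r in range(10):
            ident = generate_identifier(aaron, r, prof)
            if ident.full not in reg:
                reg.add(ident.full)
        with pytest.raises(RetryExhaustedError):
            generate_unique(aaron, reg, rng=random.Random(0), profile=prof, max_retries=50)
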