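"""Expected-collision analysis for the default identifier profile.

Prints the per-component inverse-probability bounds (how many equally
likely values each identifier component contributes), their totals, and
the expected number of colliding identifiers EC = I - N + N(1 - 1/N)^I
after enrolling 1e6, 1e7, and 1e8 participants.
"""

from nhash import CSR_PROFILE, csr_bounds, expected_collisions
from nhash.collisions import format_sci

bounds = csr_bounds(CSR_PROFILE)
print(bounds.to_frame().to_string(index=False))
print()
print(f"lower-bound space N = {format_sci(float(bounds.lower_total))}"
      f"  (skewed names, 9 effective values per MRN digit)")
print(f"upper-bound space N = {format_sci(float(bounds.upper_total))}"
      f"  (uniform letters and digits)")
print()
for I in (1e6, 1e7, 1e8):
    lo = expected_collisions(float(bounds.lower_total), I)
    hi = expected_collisions(float(bounds.upper_total), I)
    print(f"EC after {I:.0e} insertions: between {hi:.3g} and {lo:.3g}")

# Even at 1e8 enrollments (far beyond any real multicenter study) the
# expected number of duplicate identifiers is below one under the
# conservative lower bound - collisions are negligible in practice.
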