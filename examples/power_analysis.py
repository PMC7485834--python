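"""Analytic power of a two-sample MR study on a binary outcome.

For a 120k-case / 100k-control outcome GWAS and instruments explaining 5%
of exposure variance, prints the detectable odds ratio at 80% power with a
1% two-sided error rate.
"""

from mrkit import mr_power

ncase, ncontrol, r2 = 120_000, 100_000, 0.05

print(f"outcome: {ncase:,} cases / {ncontrol:,} controls; "
      f"instrument r2 = {r2:.2f}; alpha = 0.01\n")
print("OR    power")
for or_alt in (1.02, 1.04, 1.057, 1.06, 1.08, 1.10):
    p = mr_power(ncase, ncontrol, r2, or_alt, alpha=0.01)
    print(f"{or_alt:<5} {p:.3f}")

# smallest OR detectable at 80% power, by bisection
lo, hi = 1.0, 1.5
for _ in range(60):
    mid = (lo + hi) / 2
    if mr_power(ncase, ncontrol, r2, mid, alpha=0.01) < 0.8:
        lo = mid
    else:
        hi = mid
print(f"\nOR detectable at 80% power: {hi:.3f}")
print("Power rises steeply with the odds ratio; ORs near 1.06 are "
      "detectable with ~80% power at these sample sizes.")
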