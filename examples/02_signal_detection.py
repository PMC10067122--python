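"""Disproportionality screening of one planted drug-event association.

Builds the 2x2 contingency table for nivolumab x atrial fibrillation against
the whole synthetic database and prints the three statistics with their
composite signal flags, then the per-PT signal spectrum for that drug.
"""

from icivigil import (
    PTCatalog,
    build_contingency,
    compute_signal,
    default_config,
    generate_reports,
    signal_spectrum,
)

# multiplier 3 on (nivolumab, atrial fibrillation): a planted true signal
cfg = default_config(
    n_reports=20_000, multipliers={("nivolumab", "Atrial fibrillation"): 3.0}
)
reports, truth = generate_reports(cfg, seed=7)

table = build_contingency(reports, "nivolumab", "Atrial fibrillation", unit="record")
res = compute_signal(table)
print(f"2x2 table: a={table.a} b={table.b} c={table.c} d={table.d}")
print(f"expected a from the generator: "
      f"{truth.expected_counts[('nivolumab', 'Atrial fibrillation')]:.1f}")
print(f"ROR  {res.ror:.2f} (95% CI {res.ror_low:.2f}-{res.ror_high:.2f})")
print(f"PRR  {res.prr:.2f} (chi2 {res.chi2:.2f})")
print(f"IC   {res.ic:.2f} (IC025 {res.ic_low:.2f})")
print(f"flags: ROR={res.ror_signal} PRR={res.prr_signal} IC={res.ic_signal} "
      f"any={res.any_signal}")

# A signal requires >= 3 reports plus ROR025 > 1, or PRR > 1 with chi2 > 4,
# or IC025 > 0.  With a multiplier of 3 all three criteria should fire.

spec = signal_spectrum(reports, ["Nivolumab"], PTCatalog.default())
print("\nnivolumab signal spectrum (cells with >= 1 co-report):")
print(spec[["pt", "n", "ror025", "ic025", "any_signal"]].to_string(index=False))
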