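"""Precision estimators over inhibitor-validation cases.

When a drug inhibits the source protein of an accepted relation, the
relation predicts a reversed change downstream.  Each validation case
records the expected direction, the observed (normalized) change, and
whether the change was significant at 0.1 FDR.  Three estimators summarize
the tally: naive (any expected-direction change counts), significant-only
(insignificant changes count as unchanged), and noise-adjusted (assume
noise symmetric around zero, so the contrary-direction count estimates the
spurious expected-direction cases and is subtracted).
"""

from pathcause import ValidationCase, precision_estimates

cases = (
    [ValidationCase(f"sig_expected_{i}", "down", -1.0, True) for i in range(18)]
    + [ValidationCase("sig_contrary_0", "down", 1.0, True)]
    + [ValidationCase(f"ins_expected_{i}", "down", -0.2, False) for i in range(11)]
    + [ValidationCase(f"ins_contrary_{i}", "down", 0.2, False) for i in range(2)]
)

est = precision_estimates(cases, fdr=0.1)
print(f"cases: {est.n_cases}  expected-direction: {est.n_expected}  "
      f"contrary: {est.n_contrary}")
print(f"naive precision:            {est.naive:.2f}  ({est.n_expected}/{est.n_cases})")
print(f"significant-only precision: {est.significant_only:.2f}  "
      f"({est.n_significant_expected}/{est.n_cases})")
print(f"noise-adjusted precision:   {est.noise_adjusted:.2f}  "
      f"({est.adjusted_changed_count}/{est.n_cases} after symmetric-noise correction)")
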