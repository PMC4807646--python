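"""Parameter recovery at the study's sample size.

Repeatedly simulate an n = 70 cohort from the calibrated generator and run
the full selection pipeline.  For each structural term: how often selection
retains it, the mean retained estimate (compare with the 'true' column),
and conditional CI coverage.  A modest number of replicates keeps this
example quick; the acceptance script uses 500.
"""

import pandas as pd

from seqreg import default_spec, recovery_experiment

pd.set_option("display.width", 120)

spec = default_spec()
rec = recovery_experiment(spec, n=70, reps=100, seed=5)

headline = [
    ("csa_dis", "lean_mass"), ("csa_dis", "height"),
    ("csa_dis", "adiponectin:ucoc"), ("fm_pct", "leptin"),
    ("csa_dia", "leptin"), ("lean_mass", "osteocalcin"),
]
print(rec.loc[headline].round(3))
print("\nspurious retained terms per replicate:",
      round(rec.attrs["mean_spurious_terms"], 1))
print("\n'retention_rate' is the fraction of replicates where backward")
print("elimination kept the term; 'mean_estimate' conditions on retention,")
print("so borderline terms (|t| ~ 2) show a small upward magnitude bias —")
print("the usual cost of significance-based selection at n = 70.")
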