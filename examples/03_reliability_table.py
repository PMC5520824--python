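"""Full pipeline run: the test-retest reliability table for every outcome.

Simulates the default cohort, fits every scan, builds V_T / SUV / SUVR /
DVR outcomes for the frontal cortex, and prints the mean / COV% / ICC /
VAR% / SEM% table. The headline pattern: V_T is variable but reliable;
ratio outcomes (DVR, SUVR) have tiny COV yet much lower ICC — dividing by
a highly correlated denominator removes signal, not noise.
"""

import petratio as pr

config = pr.RunConfig(cohort=pr.CohortSpec(seed=1))
pr.run_all(config, "example_run")
print(pr.summarize("example_run"))
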