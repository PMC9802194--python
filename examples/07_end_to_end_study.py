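"""The whole pipeline on the default synthetic scenario.

Generates every input (profiles, pigments, grain sizes, ZOTU tables,
trees, qPCR), runs indices, tests, networks and ordinations, and prints
whether the planted structure was recovered downstream.
"""

from bioturb import run_synthetic_study

report = run_synthetic_study(seed=0)
print(report.summary())
print(
    "\nEvery line above is computed from generated data: small Welch p-values\n"
    "mean the planted BL depletion was detected, pair agreement ~1 means the\n"
    "planted clusters were recovered, and the feeding peak should fall inside\n"
    "the planted window."
)
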