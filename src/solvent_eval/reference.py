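"""Published benchmark counts for the two-reactor EBPR solvent comparison.

Per solvent and ionisation mode: total detected LC-MS peaks and putatively
annotated compounds, for the five-solvent intracellular reactor (A) and the
three-solvent two-compartment reactor (B, intra- and extracellular data
combined; MW2/MW3 were not run on that biomass).  These counts serve as
inputs for annotation-proportion summaries and for sanity-checking the
capacity metrics on real-study numbers.
"""

from __future__ import annotations

# (total detected peaks, annotated compounds) per solvent label
REACTOR_A_POSITIVE = {
    "M": (6934, 3025),
    "MW1": (8183, 3188),
    "MW2": (7699, 3142),
    "MW3": (7941, 3166),
    "MCW_M": (7825, 3143),
    "MCW_C": (2595, 641),
}

REACTOR_A_NEGATIVE = {
    "M": (2804, 1429),
    "MW1": (4045, 1770),
    "MW2": (3852, 1731),
    "MW3": (3604, 1697),
    "MCW_M": (3702, 1729),
    "MCW_C": (529, 68),
}

REACTOR_B_POSITIVE = {
    "M": (1262, 957),
    "MW1": (1334, 1058),
    "MCW_M": (1364, 1024),
    "MCW_C": (3507, 1013),
}

REACTOR_B_NEGATIVE = {
    "M": (1428, 928),
    "MW1": (1816, 1104),
    "MCW_M": (1735, 1067),
    "MCW_C": (514, 117),
}

REFERENCE_COUNTS = {
    ("A", "positive"): REACTOR_A_POSITIVE,
    ("A", "negative"): REACTOR_A_NEGATIVE,
    ("B", "positive"): REACTOR_B_POSITIVE,
    ("B", "negative"): REACTOR_B_NEGATIVE,
}
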