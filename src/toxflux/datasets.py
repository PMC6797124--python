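"""Small published reference data for worked examples and tests.

The ubiquinol:ferricytochrome c reductase (cytochrome bc1) complex of the
yeast consensus genome-scale model (reaction r_0439) is the canonical
worked example for the min/sum GPR capacity rule: the complex has two
alternative quaternary configurations, each an 11-subunit conjunct, and
the lowest-expressed subunit caps the reaction's capacity.  The mean
expression values below are the published per-condition means for the
measured subunits of an MCHM-exposure RNA-Seq experiment in S. cerevisiae
(control = untreated, treated = 550 ppm MCHM), together with the fallback
means used for subunits without expression data.
"""

from __future__ import annotations

from .expression import ConditionProfile

__all__ = [
    "BC1_REACTION_ID",
    "BC1_RULE",
    "BC1_MEASURED_EXPRESSION",
    "BC1_FALLBACK_MEAN",
    "bc1_profiles",
]

BC1_REACTION_ID = "r_0439"

# two alternative complex configurations; CYC7 (YEL039C) is specific to the
# first, CYC1 (YJR048W) and QCR7's pairing to the second
BC1_RULE = (
    "(Q0105 and YBL045C and YDR529C and YEL024W and YEL039C and YFR033C and "
    "YGR183C and YHR001W-A and YJL166W and YOR065W and YPR191W) or "
    "(Q0105 and YBL045C and YDR529C and YEL024W and YFR033C and YGR183C and "
    "YHR001W-A and YJL166W and YJR048W and YOR065W and YPR191W)"
)

# gene id -> (control mean, treated mean); only measured subunits appear
BC1_MEASURED_EXPRESSION: dict[str, tuple[float, float]] = {
    "YBL045C": (134.50, 122.91),  # COR1
    "YOR065W": (122.69, 89.59),   # CYT1
    "YPR191W": (133.78, 138.20),  # QCR2
    "YFR033C": (125.40, 107.32),  # QCR6
    "YJL166W": (317.91, 552.80),  # QCR8
    "YEL024W": (160.27, 188.18),  # RIP1
    "YJR048W": (309.61, 179.50),  # CYC1
    "YDR529C": (407.45, 555.42),  # QCR7
}

# mean expression over all measured genes per condition, substituted for
# subunits without expression data (Q0105/COB, YEL039C/CYC7, YGR183C/QCR9,
# YHR001W-A/QCR10)
BC1_FALLBACK_MEAN = {"control": 472.26, "treated": 448.02}


def bc1_profiles() -> dict[str, ConditionProfile]:
    """Condition profiles for the bc1-complex worked example."""
    return {
        cond: ConditionProfile(
            condition=cond,
            mean_expression={
                g: vals[i] for g, vals in BC1_MEASURED_EXPRESSION.items()
            },
            fallback_mean=BC1_FALLBACK_MEAN[cond],
        )
        for i, cond in enumerate(("control", "treated"))
    }
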