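"""Packaged reference data.

The bundled decision system describes 30 female patients uttering a
sustained Polish vowel "A": 10 from a phoniatrically confirmed control group
(CG), 10 with a laryngeal polyp (LP) and 10 with Reinke's edema (RE). Each
patient carries the two deformation coefficients produced by the modified
Elman-Jordan analysis — ``a1`` from the normalized original signal and
``a2`` from its derivative — and the binary screening decision ``d``
(no = healthy, yes = laryngopathy). LP cannot be separated from RE in this
plane, so both pathologies share the label yes.
"""

from __future__ import annotations

from .rough import DecisionSystem

__all__ = ["load_laryngopathy_dataset"]

# (patient id, a1, a2); groups: CG -> no, LP/RE -> yes
_CASES = [
    ("w1_CG", 0.0061, 0.0228, "no"),
    ("w2_CG", 0.0111, 0.0193, "no"),
    ("w3_CG", 0.0178, 0.0347, "no"),
    ("w4_CG", 0.0115, 0.0086, "no"),
    ("w5_CG", 0.0301, 0.0537, "no"),
    ("w6_CG", 0.0166, 0.0328, "no"),
    ("w7_CG", 0.0086, 0.0201, "no"),
    ("w8_CG", 0.0068, 0.0248, "no"),
    ("w9_CG", 0.0080, 0.0204, "no"),
    ("w10_CG", 0.0087, 0.0494, "no"),
    ("w1_LP", 0.1677, 0.1042, "yes"),
    ("w2_LP", 0.3107, 0.2108, "yes"),
    ("w3_LP", 0.0542, 0.0545, "yes"),
    ("w4_LP", 0.0258, 0.0853, "yes"),
    ("w5_LP", 0.0423, 0.1716, "yes"),
    ("w6_LP", 0.2134, 0.2428, "yes"),
    ("w7_LP", 0.0877, 0.1648, "yes"),
    ("w8_LP", 0.0351, 0.1362, "yes"),
    ("w9_LP", 0.0370, 0.1050, "yes"),
    ("w10_LP", 0.1411, 0.2382, "yes"),
    ("w1_RE", 0.0395, 0.0534, "yes"),
    ("w2_RE", 0.0970, 0.0991, "yes"),
    ("w3_RE", 0.1053, 0.1583, "yes"),
    ("w4_RE", 0.0628, 0.0784, "yes"),
    ("w5_RE", 0.1596, 0.2332, "yes"),
    ("w6_RE", 0.1951, 0.1945, "yes"),
    ("w7_RE", 0.1954, 0.1669, "yes"),
    ("w8_RE", 0.1910, 0.1358, "yes"),
    ("w9_RE", 0.2810, 0.2084, "yes"),
    ("w10_RE", 0.4366, 0.3746, "yes"),
]


def load_laryngopathy_dataset() -> DecisionSystem:
    """The 30-patient (a1, a2, d) screening decision system."""
    return DecisionSystem(
        case_ids=tuple(c[0] for c in _CASES),
        attributes=("a1", "a2"),
        values=tuple((c[1], c[2]) for c in _CASES),
        decisions=tuple(c[3] for c in _CASES),
        decision_domain=("no", "yes"),
    )
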