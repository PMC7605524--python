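"""Published reference values for the D230N-Tm / L48Q-cTnC murine models.

These are measured quantities from the transgenic mouse study this
pipeline was designed around; they serve as external anchors for
consistency checks (e.g. the ratio of trabecula tension indices, or the
expected fraction of doubly-modified regulatory units given the two
transgene incorporation levels).
"""

from __future__ import annotations

__all__ = [
    "TRABECULA_TI",
    "INCORPORATION",
    "doubly_modified_ru_fraction",
]

#: tension index of intact trabeculae relative to WT, %WT T*ms
TRABECULA_TI = {
    "WT": 0.0,
    "D230N": -7.0e3,
    "DTG": -2.7e3,  # D230N-Tm + L48Q-cTnC double transgenic
}

#: fraction of the respective protein pool carrying the transgenic variant
INCORPORATION = {
    "L48Q_cTnC": 0.30,
    "D230N_Tm": 0.57,
}


def doubly_modified_ru_fraction(
    l48q: float = INCORPORATION["L48Q_cTnC"],
    d230n: float = INCORPORATION["D230N_Tm"],
) -> float:
    """Expected fraction of regulatory units containing both variants.

    Assumes independent stochastic incorporation of the two proteins into
    a regulatory unit, so the joint fraction is the product of the two
    incorporation fractions.
    """
    if not (0 <= l48q <= 1 and 0 <= d230n <= 1):
        raise ValueError("incorporation fractions must be in [0, 1]")
    return l48q * d230n
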