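"""Published reference measurements usable as package inputs.

``rdna_domain_amounts`` returns the fmole DNA amounts measured across the
purification fractions of the five chromatin domains (four rDNA subdomains
plus the single-copy PHO5 gene), as quantified by Southern blot and qPCR
in the purification study this package models.  These amounts are inputs
to the recovery arithmetic, not results of it.
"""

from __future__ import annotations

from .io import FractionAmounts

# fmoles per fraction; CE cellular extract, P pellet, SUP supernatant,
# FT/E/B flow-through, elution and beads of the IgG step, *_cam the
# calmodulin step (PHO5 only).
_AMOUNTS = {
    "E-pro": {"CE": 1234, "P": 642, "SUP": 611,
              "FT_igg": 134, "E_igg": 161, "B_igg": 37},
    "5S": {"CE": 3521, "P": 2320, "SUP": 1398,
           "FT_igg": 717, "E_igg": 248, "B_igg": 2},
    "ARS": {"CE": 4235, "P": 1716, "SUP": 2612,
            "FT_igg": 757, "E_igg": 534, "B_igg": 69},
    "35S": {"CE": 2988, "P": 2102, "SUP": 446,
            "FT_igg": 131, "E_igg": 53, "B_igg": 74},
    "PHO5": {"CE": 1678, "P": 439, "SUP": 632,
             "FT_igg": 224, "E_igg": 191, "B_igg": 16,
             "FT_cam": 119, "E_cam": 50, "B_cam": 6},
}

RDNA_DOMAINS = ("E-pro", "5S", "ARS", "35S")


def rdna_domain_amounts() -> list[FractionAmounts]:
    """Fraction amounts for all five purified domains."""
    return [FractionAmounts(name, dict(amounts))
            for name, amounts in _AMOUNTS.items()]


def domain_amounts(name: str) -> FractionAmounts:
    return FractionAmounts(name, dict(_AMOUNTS[name]))
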