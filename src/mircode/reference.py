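"""Published miTRAP interaction catalogue for the mouse Pax6 3'UTR in alpha-TC1-6 cells.

The reference pull-down study assayed 40 miRNAs with predicted recognition
elements in the Pax6 3'UTR that are also expressed in the cultured pancreatic
alpha-cell line, and placed each into one of four categories: high-confidence
interactor (NRQ > 1 with the 95% CI clear of 1), low-confidence interactor
(NRQ > 1 but CI reaching below 1), non-specific (pulled down equally with and
without the Pax6 3'UTR) and no interaction (undetectable in the 3'UTR
pull-downs).  The roster below is the transcribed catalogue, keyed by
category, with each entry ``(miRNA, MRE type)``.  Summary percentages are
always computed from the roster at run time by
:func:`summarize_catalogue`, never stored.
"""

from __future__ import annotations

__all__ = ["MITRAP_CATALOGUE", "summarize_catalogue"]

MITRAP_CATALOGUE = {
    "high_confidence": [
        ("miR-455", "8mer"),
        ("miR-127", "7mer-m8"), ("miR-7a", "7mer-m8"), ("miR-7b", "7mer-m8"),
        ("miR-196a", "7mer-m8"), ("miR-298", "7mer-m8"), ("miR-421", "7mer-m8"),
        ("miR-497", "7mer-m8"), ("miR-124a", "7mer-m8"), ("miR-16", "7mer-m8"),
        ("miR-26a", "7mer-m8"), ("miR-26b", "7mer-m8"),
        ("miR-375", "7mer-A1"), ("miR-182", "7mer-A1"),
        ("miR-9", "6mer"), ("miR-186", "6mer"), ("miR-183", "6mer"),
    ],
    "low_confidence": [
        ("miR-494", "8mer"),
        ("miR-132", "7mer-m8"), ("miR-15b", "7mer-m8"), ("miR-195", "7mer-m8"),
        ("miR-376c", "7mer-m8"),
        ("miR-212", "6mer"), ("miR-340", "6mer"), ("miR-203", "6mer"),
    ],
    "non_specific": [
        ("miR-187", "7mer-m8"),
    ],
    "no_interaction": [
        ("miR-335-3p", "8mer"),
        ("miR-1187", "7mer-m8"), ("miR-15a", "7mer-m8"), ("miR-196b", "7mer-m8"),
        ("miR-365", "7mer-m8"), ("miR-466k", "7mer-m8"), ("miR-501-3p", "7mer-m8"),
        ("miR-96", "7mer-A1"),
        ("miR-101", "6mer"), ("miR-144", "6mer"), ("miR-362-3p", "6mer"),
        ("miR-410", "6mer"), ("miR-466f", "6mer"), ("miR-495", "6mer"),
    ],
}


def summarize_catalogue(catalogue: dict | None = None) -> dict:
    """Category counts and percentages over the assayed miRNAs.

    Interactors are the high- plus low-confidence rosters.  Percentages are
    relative to the total number of assayed miRNAs.
    """
    cat = MITRAP_CATALOGUE if catalogue is None else catalogue
    counts = {k: len(v) for k, v in cat.items()}
    total = sum(counts.values())
    pct = {k: 100.0 * n / total for k, n in counts.items()}
    n_int = counts.get("high_confidence", 0) + counts.get("low_confidence", 0)
    return {
        "n_assayed": total,
        "counts": counts,
        "percent": pct,
        "interactors": {"count": n_int, "percent": 100.0 * n_int / total},
    }
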