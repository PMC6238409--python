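"""Polyadenylation-signal and cleavage-site annotation of a 3'UTR / genomic region.

Scans the sense strand for poly(A) hexamer variants (canonically AATAAA, with
ATTAAA, TATAAA and the rarely functional AGTAAA) and, downstream of each
signal, for CA dinucleotides that are candidates for the actual cleavage
position.  Cleavage tends to occur at a CA placed 15-30 nt downstream of the
signal and ~20 nt upstream of a U/G-rich element; because observed cleavage
sites can sit closer to the signal than the textbook window, the search
window is configurable and defaults to the full [1, 30] nt downstream of the
hexamer start.

Coordinates are 1-based inclusive, position 1 being the first nucleotide
after the stop codon.  U is represented as T internally (RNA input is
transcribed on read).
"""

from __future__ import annotations

from dataclasses import dataclass

from .seed_scan import normalize_seq

__all__ = [
    "DEFAULT_VARIANTS",
    "PolyASignal",
    "CleavageCandidate",
    "scan_polya_signals",
    "find_cleavage_candidates",
    "ug_fraction",
]

#: default hexamer variant set; AGTAAA is scanned for but typically reported
#: absent in the regions of interest
DEFAULT_VARIANTS = ("AATAAA", "ATTAAA", "TATAAA", "AGTAAA")


@dataclass(frozen=True)
class PolyASignal:
    """One poly(A) hexamer occurrence (sense strand, 1-based start)."""

    position: int
    hexamer: str
    strand: str = "+"

    @property
    def end(self) -> int:
        return self.position + 5


@dataclass(frozen=True)
class CleavageCandidate:
    """A CA dinucleotide downstream of a poly(A) signal, with its U/G context.

    ``ug_fraction`` is the T/G fraction of the ``ug_window_width``-nt window
    beginning ``ug_offset`` nt after the C of the CA; if that window runs past
    the sequence end the candidate is flagged ``truncated`` (and the fraction
    is computed over the available bases, or ``None`` when none remain).
    """

    ca_position: int
    signal_position: int
    distance_from_signal: int
    ug_window_start: int
    ug_window_width: int
    ug_fraction: float | None
    truncated: bool = False

    def __post_init__(self):
        if self.ca_position <= self.signal_position:
            raise ValueError("cleavage CA must lie downstream of its signal")
        if self.ug_fraction is not None and not (0.0 <= self.ug_fraction <= 1.0):
            raise ValueError("ug_fraction outside [0, 1]")


def scan_polya_signals(seq: str, variants=None, region_end: int | None = None) -> list[PolyASignal]:
    """Report every occurrence (overlapping included) of any hexamer variant.

    Only hits whose 1-based start is <= ``region_end`` are returned, sorted by
    position.  ``N`` never matches; case and RNA/DNA alphabet are normalized.
    An empty sequence yields an empty result.
    """
    if variants is None:
        variants = DEFAULT_VARIANTS
    variants = {normalize_seq(v, allow_n=False) for v in variants}
    if any(len(v) != 6 for v in variants):
        raise ValueError("poly(A) signal variants must be hexamers")
    dna = normalize_seq(seq, allow_n=True)
    if region_end is None:
        region_end = len(dna)
    if region_end > len(dna):
        raise ValueError("region_end extends past the sequence")
    hits = []
    for start in range(0, min(region_end, len(dna) - 5)):
        if dna[start:start + 6] in variants:
            hits.append(PolyASignal(start + 1, dna[start:start + 6]))
    return hits


def ug_fraction(seq: str, start: int, width: int) -> float:
    """(#T + #G) / width over the 1-based window [start, start+width-1].

    T stands for U on the mRNA.  The window must lie fully inside the
    sequence; truncation is handled (and flagged) by the caller.
    """
    if width <= 0:
        raise ValueError("window width must be positive")
    dna = normalize_seq(seq, allow_n=True)
    if start < 1 or start + width - 1 > len(dna):
        raise ValueError("U/G window not fully inside the sequence")
    window = dna[start - 1:start + width - 1]
    return (window.count("T") + window.count("G")) / width


def find_cleavage_candidates(seq: str, signal: PolyASignal,
                             window: tuple[int, int] = (1, 30),
                             ug_width: int = 16, ug_offset: int = 17) -> list[CleavageCandidate]:
    """One candidate per CA dinucleotide inside ``window`` nt downstream of a signal.

    Distance is measured from the signal hexamer start to the C of the CA.
    Each candidate carries the U/G fraction of the ``ug_width``-nt window
    beginning ``ug_offset`` nt after the CA; candidates whose U/G window is
    truncated by the sequence end are flagged, not dropped.
    """
    lo, hi = window
    if lo < 1 or hi < lo:
        raise ValueError("search window must satisfy 1 <= lo <= hi")
    dna = normalize_seq(seq, allow_n=True)
    out = []
    for dist in range(lo, hi + 1):
        p = signal.position + dist  # 1-based position of the C
        if p + 1 > len(dna):
            break
        if dna[p - 1:p + 1] != "CA":
            continue
        ug_start = p + ug_offset
        avail = len(dna) - ug_start + 1
        if avail <= 0:
            frac, width, trunc = None, 0, True
        elif avail < ug_width:
            frac, width, trunc = ug_fraction(dna, ug_start, avail), avail, True
        else:
            frac, width, trunc = ug_fraction(dna, ug_start, ug_width), ug_width, False
        out.append(CleavageCandidate(
            ca_position=p, signal_position=signal.position,
            distance_from_signal=dist, ug_window_start=ug_start,
            ug_window_width=width, ug_fraction=frac, truncated=trunc))
    return out
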