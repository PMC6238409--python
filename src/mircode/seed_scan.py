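"""Exhaustive seed-match enumeration and classification of miRNA recognition elements.

A miRNA recognizes a target site mostly through its *seed*, nucleotides 2-7 of
the mature sequence counted from the 5' end.  Four canonical site types are
distinguished by which positions pair with the target:

* ``6mer``     -- Watson-Crick match to the seed (miRNA nt 2-7) only;
* ``7mer-m8``  -- seed match extended by pairing at miRNA nt 8;
* ``7mer-A1``  -- seed match plus an adenine in the target opposite miRNA nt 1
  (the target A counts regardless of the identity of miRNA nt 1);
* ``8mer``     -- both the m8 extension and the A1 adenine.

Relaxed definitions additionally tolerate at most one G:U wobble pair
(target G opposite miRNA U, or target U opposite miRNA G) and/or at most one
mismatched pair among the pairing positions.  The A1 position is not a pairing
position and can carry neither wobble nor mismatch.

All coordinates are 1-based on the UTR; a site's ``start`` is the 5'-most
target nucleotide of the site, so for 7mer-m8/8mer it is the nucleotide
opposite miRNA nt 8 while for 6mer/7mer-A1 it is the first seed-paired
nucleotide.  RNA input is transcribed to the DNA alphabet internally
(U -> T); ``N`` never pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "SITE_TYPES",
    "SITE_LENGTH",
    "TYPE_STRENGTH",
    "MiRNARecord",
    "MRESite",
    "SeedMatchConfig",
    "SiteMatch",
    "normalize_seq",
    "pair_class",
    "classify_window",
    "scan_mres",
]

#: site types ordered strongest first (precedence for strongest-only reporting)
SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")

SITE_LENGTH = {"6mer": 6, "7mer-A1": 7, "7mer-m8": 7, "8mer": 8}

#: larger means stronger; used for "equal-or-stronger" conservation checks
TYPE_STRENGTH = {"6mer": 0, "7mer-A1": 1, "7mer-m8": 2, "8mer": 3}

_VALID = set("ACGTN")
_WC = {"AT", "TA", "GC", "CG"}
# (target, miRNA) with U stored as T: target G : miRNA U, target U : miRNA G
_WOBBLE = {"GT", "TG"}

#: sentinel used to pad classification windows that run off the UTR ends
SENTINEL = "."


def normalize_seq(seq: str, allow_n: bool = True) -> str:
    """Uppercase, transcribe U->T and validate against the DNA alphabet."""
    s = seq.upper().replace("U", "T")
    allowed = _VALID if allow_n else _VALID - {"N"}
    bad = set(s) - allowed
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    return s


def pair_class(target: str, mirna_base: str) -> str:
    """Classify one target/miRNA base pair: 'wc', 'wobble', 'mismatch' or 'invalid'.

    Bases are DNA-normalized; anything outside ACGT (N, gap, sentinel) is
    'invalid' and makes the position unusable for any site type.
    """
    if target not in "ACGT" or mirna_base not in "ACGT":
        return "invalid"
    p = target + mirna_base
    if p in _WC:
        return "wc"
    if p in _WOBBLE:
        return "wobble"
    return "mismatch"


@dataclass(frozen=True)
class MiRNARecord:
    """A mature miRNA: name, 5'->3' sequence and the species it is annotated in."""

    name: str
    sequence: str
    species: frozenset = frozenset()

    def __post_init__(self):
        if len(self.sequence) < 8:
            raise ValueError(f"{self.name}: mature sequence shorter than 8 nt")
        object.__setattr__(self, "species", frozenset(self.species))
        # internal DNA-alphabet copy; validation happens here
        object.__setattr__(self, "_dna", normalize_seq(self.sequence, allow_n=False))

    @property
    def dna(self) -> str:
        return self._dna  # type: ignore[attr-defined]

    @property
    def seed6(self) -> str:
        """Seed core, miRNA nt 2-7."""
        return self.dna[1:7]

    @property
    def seed7(self) -> str:
        """Extended seed, miRNA nt 2-8."""
        return self.dna[1:8]


@dataclass(frozen=True)
class MRESite:
    """One predicted miRNA recognition element on the UTR.

    ``(mirna, start, site_type)`` is the unique-hit key; two miRNAs sharing a
    seed give two distinct hits at the same coordinates.  ``conservation`` is
    an optional externally supplied fraction (e.g. from an imported prediction
    table) and does not take part in identity.
    """

    mirna: str
    start: int
    site_type: str
    n_wobble: int = 0
    n_mismatch: int = 0
    conservation: float | None = field(default=None, compare=False)

    def __post_init__(self):
        if self.site_type not in SITE_LENGTH:
            raise ValueError(f"unknown site type {self.site_type!r}")
        if self.start < 1:
            raise ValueError("site start must be >= 1 (1-based)")
        if not (0 <= self.n_wobble <= 1 and 0 <= self.n_mismatch <= 1):
            raise ValueError("at most one wobble and one mismatch per site")

    @property
    def length(self) -> int:
        return SITE_LENGTH[self.site_type]

    @property
    def end(self) -> int:
        """1-based inclusive end."""
        return self.start + self.length - 1

    @property
    def canonical(self) -> bool:
        return self.n_wobble == 0 and self.n_mismatch == 0

    @property
    def strength(self) -> int:
        return TYPE_STRENGTH[self.site_type]


@dataclass(frozen=True)
class SeedMatchConfig:
    """What the scanner tolerates and how it reports.

    Defaults give strict canonical Watson-Crick sites with strongest-only
    reporting; :meth:`universe` gives the fully relaxed enumeration (every
    satisfiable type at every position, one wobble and one mismatch allowed)
    used to build the unfiltered hit universe.
    """

    allow_wobble: bool = False
    allow_mismatch: bool = False
    report_all_types: bool = False

    @classmethod
    def universe(cls) -> "SeedMatchConfig":
        return cls(allow_wobble=True, allow_mismatch=True, report_all_types=True)


@dataclass(frozen=True)
class SiteMatch:
    """Type annotation for one classified window (no coordinates)."""

    site_type: str
    n_wobble: int
    n_mismatch: int


def classify_window(window: str, mirna: MiRNARecord,
                    config: SeedMatchConfig = SeedMatchConfig()) -> tuple[SiteMatch, ...]:
    """Classify one 8-nt target window against a miRNA seed region.

    ``window`` is 5'->3' on the target; its last nucleotide lies opposite
    miRNA nt 1 (the A1 position) and its first opposite miRNA nt 8.  Windows
    at UTR edges are padded with the sentinel character, which can satisfy no
    pairing requirement.  Returns the satisfiable types strongest-first
    (precedence 8mer > 7mer-m8 > 7mer-A1 > 6mer); with
    ``report_all_types=False`` only the strongest is returned.  An empty tuple
    means no type is satisfiable within the config limits.
    """
    if len(window) != 8:
        raise ValueError("classification window must be exactly 8 nt")
    w = window.upper().replace("U", "T")
    mdna = mirna.dna
    # window index 8-i (1-based: position 9-i) pairs with miRNA nt i
    cls = {i: pair_class(w[8 - i], mdna[i - 1]) for i in range(2, 9)}
    a1 = w[7] == "A"
    max_w = 1 if config.allow_wobble else 0
    max_m = 1 if config.allow_mismatch else 0

    matches = []
    for st in SITE_TYPES:
        positions = range(2, 9) if st in ("8mer", "7mer-m8") else range(2, 8)
        pcls = [cls[i] for i in positions]
        if "invalid" in pcls:
            continue
        nw = pcls.count("wobble")
        nm = pcls.count("mismatch")
        if nw > max_w or nm > max_m:
            continue
        if st in ("8mer", "7mer-A1") and not a1:
            continue
        matches.append(SiteMatch(st, nw, nm))
    if not config.report_all_types:
        matches = matches[:1]
    return tuple(matches)


def scan_mres(utr: str, mirnas: list[MiRNARecord],
              config: SeedMatchConfig = SeedMatchConfig()) -> list[MRESite]:
    """Enumerate MRE sites for every miRNA at every UTR position.

    Applies :func:`classify_window` at every seed-core placement; with the
    :meth:`SeedMatchConfig.universe` config the result is the full unique-hit
    universe keyed by ``(mirna, start, type)``.  The scan is deterministic and
    independent of miRNA input order; output is sorted by start, then miRNA
    name, then type.
    """
    dna = normalize_seq(utr, allow_n=True)
    if not dna:
        raise ValueError("UTR sequence is empty")
    L = len(dna)
    sites: list[MRESite] = []
    for m in mirnas:
        # seed core occupies target positions s..s+5 (opposite miRNA nt 7..2)
        for s in range(1, L - 4):
            t1 = dna[s - 2] if s >= 2 else SENTINEL
            t8 = dna[s + 5] if s + 5 < L else SENTINEL
            window = t1 + dna[s - 1:s + 5] + t8
            for match in classify_window(window, m, config):
                start = s - 1 if match.site_type in ("8mer", "7mer-m8") else s
                sites.append(MRESite(m.name, start, match.site_type,
                                     match.n_wobble, match.n_mismatch))
    sites.sort(key=lambda x: (x.start, x.mirna, x.site_type))
    return sites
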