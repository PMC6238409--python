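"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive everything from first principles
(Biopython complements, explicit per-position pair tables, naive substring
scans) so they share no code path with the implementation they check.
"""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Seq import Seq

from mircode.seed_scan import MiRNARecord
from mircode import synthetic_data as synth


@pytest.fixture
def mirnas():
    return synth.gen_mirnas(4, rng_seed=11)


@pytest.fixture
def mir375():
    return MiRNARecord("mmu-miR-375", "UUUGUUCGUUCGGCUCGCGUGA", frozenset({"mouse", "human"}))


def random_dna(rng, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


# ---------------------------------------------------------------------------
# brute-force oracles


def oracle_polya_hits(seq: str, variants, region_end: int) -> list:
    """Naive sliding-window substring equality over every position."""
    s = seq.upper().replace("U", "T")
    hits = []
    for i in range(len(s) - 5):
        if i + 1 > region_end:
            break
        if s[i:i + 6] in variants:
            hits.append((i + 1, s[i:i + 6]))
    return hits


def oracle_ca_candidates(seq: str, signal_pos: int, lo: int, hi: int) -> list:
    """Every CA dinucleotide with signal-start distance in [lo, hi]."""
    s = seq.upper().replace("U", "T")
    out = []
    for p in range(1, len(s)):
        d = p - signal_pos
        if lo <= d <= hi and s[p - 1:p + 1] == "CA":
            out.append(p)
    return out


def _oracle_pair(t: str, r: str):
    if t not in "ACGT" or r not in "ACGT":
        return None
    if t == str(Seq(r).complement()):
        return "wc"
    if (t, r) in (("G", "T"), ("T", "G")):
        return "wobble"
    return "mm"


def oracle_mre_sites(utr: str, mirna, allow_wobble: bool, allow_mismatch: bool) -> set:
    """Exhaustive (position, type, wobble/mismatch) enumeration from scratch.

    Site-type geometry is rebuilt independently: for a seed core starting at
    target position s, miRNA nt i (2..7) faces target s + (7 - i), nt 8 faces
    s - 1, and the A1 adenine sits at s + 6.  Returns the all-types hit set
    as (name, start, type, n_wobble, n_mismatch) tuples.
    """
    u = utr.upper().replace("U", "T")
    m = mirna.sequence.upper().replace("U", "T")
    L = len(u)
    specs = {"6mer": (range(2, 8), False), "7mer-A1": (range(2, 8), True),
             "7mer-m8": (range(2, 9), False), "8mer": (range(2, 9), True)}
    hits = set()
    for st, (positions, need_a1) in specs.items():
        for s in range(1, L - 4):
            counts = {"wc": 0, "wobble": 0, "mm": 0}
            ok = True
            for i in positions:
                tp = s + (7 - i) if i <= 7 else s - 1
                if not (1 <= tp <= L):
                    ok = False
                    break
                c = _oracle_pair(u[tp - 1], m[i - 1])
                if c is None:
                    ok = False
                    break
                counts[c] += 1
            if not ok:
                continue
            if counts["wobble"] > (1 if allow_wobble else 0):
                continue
            if counts["mm"] > (1 if allow_mismatch else 0):
                continue
            if need_a1 and (s + 6 > L or u[s + 5] != "A"):
                continue
            start = s - 1 if st in ("7mer-m8", "8mer") else s
            hits.add((mirna.name, start, st, counts["wobble"], counts["mm"]))
    return hits


def oracle_coop_pairs(positions: list, lo: int, hi: int) -> set:
    """All-pairs center spacing check (no sharing information)."""
    out = set()
    for i, a in enumerate(positions):
        for j, b in enumerate(positions):
            if i < j and lo <= abs(a - b) <= hi:
                out.add((min(i, j), max(i, j)))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
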