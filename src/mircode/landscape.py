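"""NRQ-weighted positional interaction landscape of a 3'UTR.

Each interacting miRNA contributes one peak per recognition element: a
rectangular interval of ``half_width`` nt (default 25) on either side of the
MRE position, at a height equal to the miRNA's mean pull-down NRQ.  The
per-nucleotide track composites peaks with max (not sum), so track values
stay interpretable as NRQs; stretches covered by two or more peaks are
reported separately as overlap intervals.

Closely spaced recognition elements can act cooperatively; pairs of sites
whose spacing falls in ``[coop_min, coop_max]`` nt (default 8-50,
center-to-center) are called cooperative, except where the two miRNAs share
common or overlapping MREs (simultaneous occupancy is then impossible).
Peaks whose intervals overlap merge (single linkage) into maximal cluster
regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LandscapeConfig",
    "LandscapeSite",
    "LandscapePeak",
    "CooperativeCluster",
    "Landscape",
    "build_landscape",
    "cooperative_pairs",
    "cluster_regions",
]


@dataclass(frozen=True)
class LandscapeConfig:
    half_width: int = 25
    coop_min: int = 8
    coop_max: int = 50
    spacing_mode: str = "center"  # or "edge_gap"

    def __post_init__(self):
        if self.half_width <= 0:
            raise ValueError("half_width must be positive")
        if not self.coop_min < self.coop_max:
            raise ValueError("cooperative spacing bounds must satisfy min < max")
        if self.spacing_mode not in ("center", "edge_gap"):
            raise ValueError("spacing_mode must be 'center' or 'edge_gap'")


@dataclass(frozen=True)
class LandscapeSite:
    """An MRE with the mean NRQ of its miRNA.

    ``position`` is the representative MRE position used for peaks and
    center-to-center spacing; ``start``/``end`` give the site footprint for
    overlap and shared-MRE logic (defaulting to the single position).
    """

    mirna: str
    position: int
    nrq: float
    start: int | None = None
    end: int | None = None

    def __post_init__(self):
        if self.nrq <= 0:
            raise ValueError("peak height (NRQ) must be positive")
        object.__setattr__(self, "start", self.position if self.start is None else self.start)
        object.__setattr__(self, "end", self.position if self.end is None else self.end)


@dataclass(frozen=True)
class LandscapePeak:
    mirna: str
    mre_position: int
    interval: tuple  # (lo, hi) 1-based inclusive, clipped to the UTR
    height: float
    site: LandscapeSite | None = field(default=None, compare=False)


@dataclass
class CooperativeCluster:
    interval: tuple
    peaks: list
    mirnas: list
    has_cooperative_pair: bool
    contains_shared_mres: bool


@dataclass
class Landscape:
    track: np.ndarray          # index 0 = UTR position 1; max-composited heights
    peaks: list
    overlap_intervals: list    # stretches covered by >= 2 peaks


def build_landscape(sites: list[LandscapeSite], utr_length: int,
                    config: LandscapeConfig = LandscapeConfig()) -> Landscape:
    """One peak per (miRNA, MRE position); max-composited per-nucleotide track."""
    track = np.zeros(utr_length)
    cover = np.zeros(utr_length, dtype=int)
    peaks = []
    for s in sorted(sites, key=lambda s: (s.position, s.mirna)):
        if not (1 <= s.position <= utr_length):
            raise ValueError(f"site at {s.position} outside the UTR [1, {utr_length}]")
        lo = max(1, s.position - config.half_width)
        hi = min(utr_length, s.position + config.half_width)
        track[lo - 1:hi] = np.maximum(track[lo - 1:hi], s.nrq)
        cover[lo - 1:hi] += 1
        peaks.append(LandscapePeak(s.mirna, s.position, (lo, hi), s.nrq, site=s))
    overlaps = _runs(cover >= 2)
    return Landscape(track, peaks, overlaps)


def _runs(mask: np.ndarray) -> list:
    """Merged 1-based inclusive intervals where ``mask`` is True."""
    out = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i + 1
        elif not v and start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, len(mask)))
    return out


def _mirnas_share_mre(a: LandscapeSite, b: LandscapeSite, by_mirna: dict) -> bool:
    """Do the two sites' miRNAs have any common or overlapping MREs?"""
    if a.mirna == b.mirna:
        return False
    for sa in by_mirna[a.mirna]:
        for sb in by_mirna[b.mirna]:
            if min(sa.end, sb.end) - max(sa.start, sb.start) + 1 >= 1:
                return True
    return False


def _spacing(a: LandscapeSite, b: LandscapeSite, mode: str) -> int:
    if mode == "center":
        return abs(a.position - b.position)
    lo, hi = (a, b) if a.start <= b.start else (b, a)
    return max(0, hi.start - lo.end - 1)


def cooperative_pairs(sites: list[LandscapeSite],
                      config: LandscapeConfig = LandscapeConfig()) -> list:
    """All unordered site pairs spaced within the cooperative window.

    Pairs whose miRNAs share common or overlapping MREs are excluded, as are
    pairs of directly overlapping footprints.  The relation is symmetric and
    anti-reflexive; shrinking the spacing window never adds pairs.
    """
    by_mirna: dict = {}
    for s in sites:
        by_mirna.setdefault(s.mirna, []).append(s)
    pairs = []
    ordered = sorted(sites, key=lambda s: (s.position, s.mirna))
    for i, a in enumerate(ordered):
        for b in ordered[i + 1:]:
            if a == b:
                continue
            if min(a.end, b.end) - max(a.start, b.start) + 1 >= 1:
                continue  # overlapping footprints cannot co-occupy
            if _mirnas_share_mre(a, b, by_mirna):
                continue
            d = _spacing(a, b, config.spacing_mode)
            if config.coop_min <= d <= config.coop_max:
                pairs.append((a, b))
    return pairs


def cluster_regions(peaks: list[LandscapePeak],
                    config: LandscapeConfig = LandscapeConfig()) -> list:
    """Single-linkage merge of peaks with overlapping intervals.

    Each maximal region reports its interval, members, whether it contains at
    least one cooperative site pair, and whether any members share MREs.
    """
    if not peaks:
        return []
    ordered = sorted(peaks, key=lambda p: p.interval)
    clusters = []
    cur = [ordered[0]]
    lo, hi = ordered[0].interval
    for p in ordered[1:]:
        if p.interval[0] <= hi:
            cur.append(p)
            hi = max(hi, p.interval[1])
        else:
            clusters.append(_make_cluster((lo, hi), cur, config))
            cur = [p]
            lo, hi = p.interval
    clusters.append(_make_cluster((lo, hi), cur, config))
    return clusters


def _make_cluster(interval, members, config) -> CooperativeCluster:
    sites = [p.site for p in members if p.site is not None]
    coop = bool(cooperative_pairs(sites, config)) if len(sites) > 1 else False
    by_mirna: dict = {}
    for s in sites:
        by_mirna.setdefault(s.mirna, []).append(s)
    shared = any(_mirnas_share_mre(a, b, by_mirna)
                 for i, a in enumerate(sites) for b in sites[i + 1:])
    return CooperativeCluster(
        interval=interval, peaks=members,
        mirnas=sorted({p.mirna for p in members}),
        has_cooperative_pair=coop, contains_shared_mres=shared)
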