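"""Hierarchical candidate-selection funnel over a seed-match site universe.

The funnel narrows an exhaustively enumerated MRE universe to a tractable
candidate set in fixed stage order:

1. the input universe;
2. drop sites whose seed match contains a mismatch;
3. drop 6mer sites whose seed match contains a G:U wobble;
4. keep sites conserved in at least ``conservation_threshold`` (default 85%)
   of clade orthologs in a multiple alignment;
5. keep sites whose miRNA is annotated in every required species
   (default: human).

Surviving hits are then collapsed to *unique MREs* -- genomic sites merged
when their footprints overlap by at least 6 nt (a shared seed core) -- and to
unique miRNAs, with a redundancy summary (MREs targeted by multiple miRNAs,
miRNAs with multiple MREs).

Conservation of a site in an ortholog is operationalized as the presence of
an equal-or-stronger site type for the same miRNA inside the gap-stripped
orthologous window (strictness is configurable down to exact sequence
identity).  Species whose window is mostly gaps are excluded from the
denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .seed_scan import (MiRNARecord, MRESite, SeedMatchConfig, TYPE_STRENGTH,
                        classify_window, normalize_seq, scan_mres)

__all__ = [
    "OrthologAlignment",
    "FilterConfig",
    "FunnelReport",
    "RedundancySummary",
    "site_conservation",
    "apply_funnel",
    "redundancy_summary",
    "unique_mre_groups",
    "collapse_sites_per_mirna",
    "import_prediction_table",
]

#: minimum footprint overlap (nt) for two hits to count as the same MRE
SHARED_MRE_OVERLAP = 6


@dataclass
class OrthologAlignment:
    """Gapped ortholog UTR sequences keyed by species, with a reference species.

    All gapped sequences must have equal column count; ungapping the reference
    row reproduces the input UTR.
    """

    sequences: dict
    reference: str

    def __post_init__(self):
        if self.reference not in self.sequences:
            raise ValueError(f"reference species {self.reference!r} not in alignment")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ValueError("aligned sequences differ in column count")
        self.sequences = {sp: s.upper().replace("U", "T") for sp, s in self.sequences.items()}
        ref = self.sequences[self.reference]
        # column index (0-based) of each ungapped reference position (0-based)
        self._ref_cols = [i for i, c in enumerate(ref) if c != "-"]

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.sequences.values())))

    def ungapped(self, species: str) -> str:
        return self.sequences[species].replace("-", "")

    def column_span(self, start: int, end: int) -> tuple[int, int]:
        """Alignment column span (0-based, inclusive) of 1-based reference
        positions ``start..end``, including any inserted gap columns between."""
        if start < 1 or end > len(self._ref_cols):
            raise ValueError("site outside the ungapped reference coordinates")
        return self._ref_cols[start - 1], self._ref_cols[end - 1]


@dataclass(frozen=True)
class FilterConfig:
    """Funnel thresholds and switches.

    ``conservation_clade`` restricts the ortholog set used for the >=85%
    computation (e.g. placental mammals); ``None`` means every non-reference
    species in the alignment.  ``conservation_mode`` is ``"type"``
    (equal-or-stronger site for the same miRNA in the orthologous window) or
    ``"identity"`` (exact gap-stripped sequence identity).
    """

    conservation_threshold: float = 0.85
    conservation_clade: frozenset | None = None
    required_species: frozenset = frozenset({"human"})
    drop_mismatch: bool = True
    drop_6mer_wobble: bool = True
    max_gap_fraction: float = 0.5
    conservation_mode: str = "type"
    ortholog_allow_wobble: bool = True

    def __post_init__(self):
        if not (0.0 < self.conservation_threshold <= 1.0):
            raise ValueError("conservation_threshold must be in (0, 1]")
        if self.conservation_mode not in ("type", "identity"):
            raise ValueError("conservation_mode must be 'type' or 'identity'")
        if self.conservation_clade is not None:
            object.__setattr__(self, "conservation_clade", frozenset(self.conservation_clade))
        object.__setattr__(self, "required_species", frozenset(self.required_species))


@dataclass
class RedundancySummary:
    """Shared-MRE and multi-MRE book-keeping over a deduplicated site set."""

    multi_mirna_mres: int
    multi_mre_mirnas: int
    mre_groups: list
    per_mirna_mres: dict


@dataclass
class FunnelReport:
    """Per-stage survivor counts plus unique-MRE/unique-miRNA collapse."""

    stages: list = field(default_factory=list)  # [(stage name, surviving count)]
    unique_mre_count: int = 0
    unique_mirna_count: int = 0
    redundancy: RedundancySummary | None = None
    undefined_conservation: list = field(default_factory=list)
    notes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "stages": [{"name": n, "count": c} for n, c in self.stages],
            "unique_mre_count": self.unique_mre_count,
            "unique_mirna_count": self.unique_mirna_count,
            "redundancy": None if self.redundancy is None else {
                "multi_mirna_mres": self.redundancy.multi_mirna_mres,
                "multi_mre_mirnas": self.redundancy.multi_mre_mirnas,
                "per_mirna_mres": {k: [list(iv) for iv in v]
                                   for k, v in sorted(self.redundancy.per_mirna_mres.items())},
            },
            "undefined_conservation": self.undefined_conservation,
            "notes": self.notes,
        }


def site_conservation(site: MRESite, aln: OrthologAlignment, mirna: MiRNARecord,
                      config: FilterConfig = FilterConfig()) -> float | None:
    """Fraction of clade orthologs retaining the site; ``None`` when undefined.

    For every clade species other than the reference, the alignment columns of
    the reference site are extracted; species with a gap fraction above
    ``max_gap_fraction`` in that window are excluded from the denominator.
    The remaining species count as conserved when their gap-stripped window
    contains a site of equal-or-stronger type for the same miRNA (or is
    sequence-identical, in identity mode).  A site whose external
    ``conservation`` field is set is evaluated on that value upstream and
    never reaches this function through the funnel.
    """
    ref_utr = aln.ungapped(aln.reference)
    if site.end > len(ref_utr):
        raise ValueError("site outside the reference ungapped coordinates")
    c0, c1 = aln.column_span(site.start, site.end)
    ref_window = aln.sequences[aln.reference][c0:c1 + 1].replace("-", "")
    clade = config.conservation_clade or (set(aln.sequences) - {aln.reference})
    ortho_cfg = SeedMatchConfig(allow_wobble=config.ortholog_allow_wobble,
                                allow_mismatch=False, report_all_types=True)
    n_den = 0
    n_cons = 0
    for sp in sorted(clade):
        if sp == aln.reference or sp not in aln.sequences:
            continue
        window = aln.sequences[sp][c0:c1 + 1]
        gap_frac = window.count("-") / len(window)
        if gap_frac > config.max_gap_fraction:
            continue
        n_den += 1
        stripped = window.replace("-", "")
        if config.conservation_mode == "identity":
            conserved = stripped == ref_window
        else:
            conserved = _window_has_site(stripped, mirna, site, ortho_cfg)
        if conserved:
            n_cons += 1
    if n_den == 0:
        return None
    return n_cons / n_den


def _window_has_site(window: str, mirna: MiRNARecord, site: MRESite,
                     cfg: SeedMatchConfig) -> bool:
    """Does ``window`` contain a site of equal-or-stronger type for ``mirna``?"""
    if len(window) < 6 or "N" in window:
        return False
    try:
        hits = scan_mres(window, [mirna], cfg)
    except ValueError:
        return False
    want = TYPE_STRENGTH[site.site_type]
    return any(TYPE_STRENGTH[h.site_type] >= want and
               h.n_wobble <= max(site.n_wobble, 1 if cfg.allow_wobble else 0)
               for h in hits)


def unique_mre_groups(sites: list[MRESite]) -> list[tuple[tuple[int, int], list[MRESite]]]:
    """Single-linkage merge of sites whose footprints overlap by >= 6 nt.

    Returns ``[(interval, member sites), ...]`` sorted by interval start; the
    groups are the "unique MREs" irrespective of which miRNA targets them.
    """
    if not sites:
        return []
    ordered = sorted(sites, key=lambda s: (s.start, s.end, s.mirna, s.site_type))
    groups = []
    cur = [ordered[0]]
    cur_lo, cur_hi = ordered[0].start, ordered[0].end
    for s in ordered[1:]:
        overlap = min(cur_hi, s.end) - max(cur_lo, s.start) + 1
        if overlap >= SHARED_MRE_OVERLAP:
            cur.append(s)
            cur_lo, cur_hi = min(cur_lo, s.start), max(cur_hi, s.end)
        else:
            groups.append(((cur_lo, cur_hi), cur))
            cur = [s]
            cur_lo, cur_hi = s.start, s.end
    groups.append(((cur_lo, cur_hi), cur))
    return groups


def collapse_sites_per_mirna(sites: list[MRESite]) -> list[MRESite]:
    """One representative site per miRNA per overlapping locus.

    An all-types enumeration reports every satisfiable type at a position;
    for positional analyses each miRNA should contribute one site per locus.
    Within each miRNA's >=6-nt-overlap groups the strongest (then longest,
    then 5'-most) site is kept.
    """
    by_mirna: dict = {}
    for s in sites:
        by_mirna.setdefault(s.mirna, []).append(s)
    out = []
    for name in sorted(by_mirna):
        for _, members in unique_mre_groups(by_mirna[name]):
            out.append(max(members,
                           key=lambda s: (TYPE_STRENGTH[s.site_type], s.length, -s.start)))
    out.sort(key=lambda s: (s.start, s.mirna, s.site_type))
    return out


def redundancy_summary(sites: list[MRESite]) -> RedundancySummary:
    """Count MREs shared by multiple miRNAs and miRNAs with multiple MREs."""
    groups = unique_mre_groups(sites)
    multi_mirna = sum(1 for _, members in groups
                      if len({m.mirna for m in members}) > 1)
    per_mirna: dict = {}
    for interval, members in groups:
        for name in {m.mirna for m in members}:
            per_mirna.setdefault(name, []).append(interval)
    multi_mre = sum(1 for ivs in per_mirna.values() if len(ivs) > 1)
    return RedundancySummary(multi_mirna, multi_mre, groups, per_mirna)


#: the published recount of this taxonomy is internally inconsistent; carried
#: verbatim into every report rather than silently resolved
RECOUNT_NOTE = ("Published recounts of the 6mer+G:U exclusion stage for the Pax6 "
                "3'UTR universe disagree (190 vs 191 survivors); both figures are "
                "carried, neither is resolved here.")


def apply_funnel(sites: list[MRESite], aln: OrthologAlignment | None,
                 mirnas: list[MiRNARecord] | None,
                 config: FilterConfig = FilterConfig(),
                 species_map: dict | None = None) -> tuple[list[MRESite], FunnelReport]:
    """Run the hierarchical selection funnel and return survivors plus a report.

    Conservation (stage 4) uses each site's external ``conservation`` value
    when present, otherwise it is computed from the alignment (which must then
    be provided along with the miRNA records).  Stage 5 needs species
    annotations for every surviving miRNA, either on the records or through
    ``species_map`` (e.g. from an imported prediction table); missing
    annotations raise an error naming the miRNAs.
    """
    report = FunnelReport(notes=[RECOUNT_NOTE])
    by_name = {m.name: m for m in (mirnas or [])}
    species_map = species_map or {}

    def _species_of(name: str) -> frozenset:
        if name in species_map:
            return frozenset(species_map[name])
        if name in by_name:
            return by_name[name].species
        return frozenset()

    stage = list(sites)
    report.stages.append(("all_hits", len(stage)))

    if config.drop_mismatch:
        stage = [s for s in stage if s.n_mismatch == 0]
    report.stages.append(("no_mismatch", len(stage)))

    if config.drop_6mer_wobble:
        stage = [s for s in stage if not (s.site_type == "6mer" and s.n_wobble >= 1)]
    report.stages.append(("no_6mer_wobble", len(stage)))

    kept = []
    for s in stage:
        frac = s.conservation
        if frac is None:
            if aln is None:
                raise ValueError("no alignment provided and site carries no "
                                 "precomputed conservation")
            if s.mirna not in by_name:
                raise ValueError(f"no miRNA record for {s.mirna}")
            frac = site_conservation(s, aln, by_name[s.mirna], config)
        if frac is None or (isinstance(frac, float) and math.isnan(frac)):
            report.undefined_conservation.append([s.mirna, s.start, s.site_type])
            continue
        if frac >= config.conservation_threshold:
            kept.append(s)
    stage = kept
    report.stages.append(("conserved", len(stage)))

    if config.required_species:
        missing = sorted({s.mirna for s in stage if not _species_of(s.mirna)})
        if missing:
            raise ValueError(f"missing species annotations for miRNAs: {missing}")
        stage = [s for s in stage
                 if config.required_species <= _species_of(s.mirna)]
    report.stages.append(("required_species", len(stage)))

    groups = unique_mre_groups(stage)
    report.unique_mre_count = len(groups)
    report.unique_mirna_count = len({s.mirna for s in stage})
    report.redundancy = redundancy_summary(stage)
    return stage, report


# ---------------------------------------------------------------------------
# prediction-table import (column contract for externally enumerated universes)

#: required columns of an imported prediction table
TABLE_COLUMNS = ("mirna", "start", "type", "n_wobble", "n_mismatch")


def import_prediction_table(path) -> tuple[list[MRESite], dict]:
    """Read a TSV prediction table into MRESites plus a species map.

    Required columns: mirna, start, type, n_wobble, n_mismatch.  Optional:
    ``conservation`` (fraction, used instead of alignment-derived values) and
    ``species_flags`` (semicolon-separated species tags for the miRNA).
    Returns ``(sites, {mirna: set-of-species})``.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"prediction table missing columns: {missing}")
    sites = []
    species: dict = {}
    for row in df.itertuples(index=False):
        cons = getattr(row, "conservation", None)
        if cons is not None and isinstance(cons, float) and math.isnan(cons):
            cons = None
        sites.append(MRESite(str(row.mirna), int(row.start), str(row.type),
                             int(row.n_wobble), int(row.n_mismatch),
                             conservation=None if cons is None else float(cons)))
        flags = getattr(row, "species_flags", None)
        if isinstance(flags, str) and flags:
            species.setdefault(str(row.mirna), set()).update(flags.split(";"))
    return sites, species
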