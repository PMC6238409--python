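"""Synthetic inputs with the statistical structure every pipeline stage assumes.

Generators for the four input classes the pipeline consumes, each
deterministic under a fixed seed and each emitting a truth table sufficient to
score downstream precision/recall:

* random mature miRNAs with distinct seeds;
* UTRs with planted MREs of specified types and wobble/mismatch edits, on a
  background *rejection-sampled* to contain no spurious sites at the
  requested scan strictness (masking would bias composition; resampling
  guarantees a clean negative space);
* ortholog multiple alignments in which each non-reference species retains
  each planted site with a configured probability (disruption is a single
  seed substitution that breaks both Watson-Crick and wobble pairing) and
  accumulates background substitutions and gaps elsewhere;
* qPCR Ct plate tables drawn from configured fold enrichments, efficiencies
  and replicate noise, with minus-RT wells and undetermined-Ct dropout;
* ten-fold dilution standard curves, ``Ct_k = c0 + k / log10(E)``, for
  efficiency round-trips.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .qpcr_quant import CtRecord, DilutionSeries
from .mre_filter import OrthologAlignment
from .seed_scan import (MiRNARecord, MRESite, SeedMatchConfig, SITE_LENGTH,
                        normalize_seq, pair_class, scan_mres)

__all__ = [
    "Plant",
    "PlantSpec",
    "CtSimSpec",
    "gen_mirnas",
    "gen_utr_with_planted_sites",
    "gen_ortholog_alignment",
    "gen_ct_experiment",
    "gen_dilution_series",
    "gen_polya_region",
]

_BASES = "ACGT"
_WC_TARGET = {"A": "T", "C": "G", "G": "C", "T": "A"}  # miRNA base -> WC target


def _nonpairing_targets(mirna_base: str) -> str:
    """Target bases that pair with ``mirna_base`` neither WC nor wobble."""
    return "".join(b for b in _BASES if pair_class(b, mirna_base) == "mismatch")


@dataclass(frozen=True)
class Plant:
    """One site to plant: miRNA index, site start (MRE convention) and type."""

    mirna_index: int
    start: int
    site_type: str
    n_wobble: int = 0
    n_mismatch: int = 0

    def __post_init__(self):
        if self.site_type not in SITE_LENGTH:
            raise ValueError(f"unknown site type {self.site_type!r}")
        if not (0 <= self.n_wobble <= 1 and 0 <= self.n_mismatch <= 1):
            raise ValueError("at most one wobble and one mismatch edit per plant")


@dataclass
class PlantSpec:
    """What to plant and how clean the background must be.

    ``clean_config`` sets the strictness at which the background is scrubbed
    of spurious hits; it defaults to the scan configuration whose truth the
    plants define (canonical, strongest-only).
    """

    plants: list = field(default_factory=list)
    gc_content: float = 0.45
    allow_overlap: bool = False
    clean_config: SeedMatchConfig = field(default_factory=SeedMatchConfig)

    def __post_init__(self):
        if not (0.0 < self.gc_content < 1.0):
            raise ValueError("gc_content must be in (0, 1)")


def gen_mirnas(n: int, rng_seed: int, species=frozenset({"mouse", "human"}),
               length: int = 22, name_prefix: str = "syn-miR") -> list[MiRNARecord]:
    """``n`` random 22-nt mature miRNAs with pairwise distinct seed cores."""
    if n < 1:
        raise ValueError("need at least one miRNA")
    rng = np.random.default_rng(rng_seed)
    seen = set()
    out = []
    while len(out) < n:
        seq = "".join(rng.choice(list("ACGU"), size=length))
        seed = seq[1:7]
        if seed in seen:
            continue
        seen.add(seed)
        out.append(MiRNARecord(f"{name_prefix}-{len(out) + 1}", seq, frozenset(species)))
    return out


def _core_start(plant: Plant) -> int:
    """1-based UTR position of the seed core (target opposite miRNA nt 7)."""
    return plant.start + 1 if plant.site_type in ("8mer", "7mer-m8") else plant.start


def _build_window(plant: Plant, mirna: MiRNARecord, rng) -> str:
    """The 8-nt target window (positions core_start-1 .. core_start+6).

    Core pairs WC with miRNA nt 2-7; the m8 flank pairs or mismatches per
    type; the A1 flank is adenine exactly for the A1 types.  Wobble and
    mismatch edits are then applied at wobble-capable / free pairing
    positions.
    """
    mdna = mirna.dna
    # window index 8-i (0-based) pairs miRNA nt i; build canonical core
    w = [""] * 8
    for i in range(2, 8):
        w[8 - i] = _WC_TARGET[mdna[i - 1]]
    m8 = mdna[7]
    if plant.site_type in ("8mer", "7mer-m8"):
        w[0] = _WC_TARGET[m8]
    else:
        w[0] = str(rng.choice(list(_nonpairing_targets(m8))))
    if plant.site_type in ("8mer", "7mer-A1"):
        w[7] = "A"
    else:
        w[7] = str(rng.choice(list("CGT")))

    pairing = list(range(2, 9)) if plant.site_type in ("8mer", "7mer-m8") else list(range(2, 8))
    free = list(pairing)
    if plant.n_wobble:
        capable = [i for i in free if mdna[i - 1] in "TG"]
        if not capable:
            raise ValueError(f"{mirna.name}: no wobble-capable seed position for plant")
        i = int(rng.choice(capable))
        w[8 - i] = "G" if mdna[i - 1] == "T" else "T"
        free.remove(i)
    if plant.n_mismatch:
        if not free:
            raise ValueError("no free pairing position left for a mismatch edit")
        i = int(rng.choice(free))
        w[8 - i] = str(rng.choice(list(_nonpairing_targets(mdna[i - 1]))))
    return "".join(w)


def gen_utr_with_planted_sites(length: int, spec: PlantSpec, rng_seed: int,
                               mirnas: list[MiRNARecord]) -> tuple[str, list[MRESite]]:
    """A UTR containing exactly the planted sites at the scrub strictness.

    Returns the sequence and the truth table of planted ``MRESite`` records.
    The background is resampled/remediated until a strongest-only scan at
    ``spec.clean_config`` recovers the planted truth with no extras.  Raises
    on infeasible specs (overlapping windows without ``allow_overlap``,
    windows outside the UTR, or unresolvable plant/background conflicts).
    """
    rng = np.random.default_rng(rng_seed)
    windows = []  # (0-based window start, 8-nt string)
    truth = []
    for plant in spec.plants:
        mirna = mirnas[plant.mirna_index]
        cs = _core_start(plant)
        if cs < 2 or cs + 6 > length:
            raise ValueError(f"plant at start {plant.start} does not fit the UTR "
                             "(full 8-nt window with flanks required)")
        w0 = cs - 2  # window occupies w0 .. w0+7 (0-based)
        if not spec.allow_overlap:
            for prev0, _ in windows:
                if not (w0 + 7 < prev0 or prev0 + 7 < w0):
                    raise ValueError("planted windows overlap; set allow_overlap")
        windows.append((w0, _build_window(plant, mirna, rng)))
        truth.append(MRESite(mirna.name, plant.start, plant.site_type,
                             plant.n_wobble, plant.n_mismatch))

    planted_positions = {w0 + k for w0, _ in windows for k in range(8)}
    probs = [(1 - spec.gc_content) / 2, spec.gc_content / 2,
             spec.gc_content / 2, (1 - spec.gc_content) / 2]
    truth_keys = {(t.mirna, t.start, t.site_type) for t in truth}
    scan_cfg = SeedMatchConfig(allow_wobble=spec.clean_config.allow_wobble,
                               allow_mismatch=spec.clean_config.allow_mismatch,
                               report_all_types=False)

    for _restart in range(50):
        seq = list("".join(rng.choice(list(_BASES), size=length, p=probs)))
        for w0, w in windows:
            seq[w0:w0 + 8] = list(w)
        ok = _scrub_background(seq, mirnas, scan_cfg, truth_keys,
                               planted_positions, rng)
        if ok:
            return "".join(seq), truth
    raise ValueError("could not build a clean background for the plant spec")


def _scrub_background(seq: list, mirnas, scan_cfg, truth_keys,
                      planted_positions, rng, max_rounds: int = 200) -> bool:
    """Mutate spurious hits away; False when a hit is pinned inside a plant."""
    for _ in range(max_rounds):
        extras = [s for s in scan_mres("".join(seq), mirnas, scan_cfg)
                  if (s.mirna, s.start, s.site_type) not in truth_keys]
        if not extras:
            return True
        for s in extras:
            mutable = [p for p in range(s.start - 1, s.end)  # 0-based footprint
                       if p not in planted_positions]
            if not mutable:
                return False  # spurious hit fully inside a planted window
            p = int(rng.choice(mutable))
            seq[p] = str(rng.choice([b for b in _BASES if b != seq[p]]))
    return False


def gen_ortholog_alignment(utr: str, truth: list[MRESite], n_species: int,
                           conservation_probs, rng_seed: int,
                           mirnas: list[MiRNARecord] | None = None,
                           background_sub_rate: float = 0.02,
                           gap_rate: float = 0.01,
                           reference_name: str = "reference") -> tuple[OrthologAlignment, dict]:
    """Alignment of ``n_species`` non-reference orthologs over a planted UTR.

    Each species retains each planted site with its conservation probability;
    a non-retained site is disrupted by one substitution in the seed-paired
    window chosen to break both Watson-Crick and wobble pairing (exact when
    the miRNA records are supplied, complement-derived otherwise).  Outside
    planted footprints, bases substitute at ``background_sub_rate`` and drop
    to gaps at ``gap_rate``.  Returns the alignment and the realized retention
    truth ``{(species, (mirna, start, type)): bool}``.
    """
    rng = np.random.default_rng(rng_seed)
    dna = normalize_seq(utr)
    probs = np.broadcast_to(np.asarray(conservation_probs, dtype=float), (n_species,))
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("conservation probabilities must lie in [0, 1]")
    by_name = {m.name: m for m in (mirnas or [])}
    protected = set()
    for t in truth:
        protected.update(range(t.start - 1, t.end))

    sequences = {reference_name: dna}
    retention: dict = {}
    for k in range(n_species):
        sp = f"sp{k + 1:02d}"
        row = list(dna)
        for t in truth:
            keep = bool(rng.random() < probs[k])
            retention[(sp, (t.mirna, t.start, t.site_type))] = keep
            if not keep:
                _disrupt_site(row, t, by_name.get(t.mirna), rng)
        for p in range(len(row)):
            if p in protected or row[p] == "-":
                continue
            r = rng.random()
            if r < gap_rate:
                row[p] = "-"
            elif r < gap_rate + background_sub_rate:
                row[p] = str(rng.choice([b for b in _BASES if b != row[p]]))
        sequences[sp] = "".join(row)
    return OrthologAlignment(sequences, reference_name), retention


def _disrupt_site(row: list, site: MRESite, mirna: MiRNARecord | None, rng) -> None:
    """One substitution in the seed-paired core that kills the site."""
    # core = seed-paired positions (excludes the A1 adenine)
    if site.site_type in ("8mer", "7mer-A1"):
        core = list(range(site.start - 1, site.end - 1))
    else:
        core = list(range(site.start - 1, site.end))
    p = int(rng.choice(core))
    old = row[p]
    if mirna is not None:
        # the 5'-most core position pairs miRNA nt 7 and the m8 flank nt 8
        core_start0 = site.start - 1 + (1 if site.site_type in ("8mer", "7mer-m8") else 0)
        i = 7 - (p - core_start0)  # p == core_start0 - 1 gives i == 8
        choices = _nonpairing_targets(mirna.dna[i - 1])
    else:
        # canonical plants pair WC: the miRNA base is the WC partner of old
        choices = _nonpairing_targets(_WC_TARGET.get(old, "A"))
    choices = [b for b in choices if b != old] or [b for b in _BASES if b != old]
    row[p] = str(rng.choice(choices))


# ---------------------------------------------------------------------------
# Ct plate simulation


@dataclass
class CtSimSpec:
    """True enrichments, efficiencies and noise for a simulated miTRAP plate.

    ``enrichments`` maps miRNA assay names to the true wild-type over control
    pull-down fold enrichment.  Ct values follow
    ``Ct = baseline - log(abundance) / log(E)`` plus Gaussian replicate noise;
    computed Cts at or above ``dropout_ct`` are emitted as undetermined.
    ``lysate_rel_abundance`` (relative to U6) adds lysate wells for miTRAP
    ratios and profiling.
    """

    enrichments: dict = field(default_factory=dict)
    lysate_rel_abundance: dict | None = None
    e_bait: float = 1.952
    e_taqman: float = 2.0
    mirna_baseline_ct: float = 24.0
    bait_baseline_ct: float = 18.0
    u6_ct: float = 20.0
    control_abundance: float = 1.0
    noise_sd: float = 0.0
    dropout_ct: float | None = 40.0
    pulldown_replicates: int = 4
    profiling_replicates: int = 3
    include_rt_controls: bool = True
    no_rt_offset: float = 12.0

    def __post_init__(self):
        if any(e <= 0 for e in self.enrichments.values()):
            raise ValueError("enrichments must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")


def _ct_from_abundance(baseline: float, abundance: float, efficiency: float) -> float:
    return baseline - np.log(abundance) / np.log(efficiency)


def gen_ct_experiment(spec: CtSimSpec, rng_seed: int) -> list[CtRecord]:
    """A miTRAP plate table honouring the configured contrast structure.

    Emits wild-type and control pull-down wells (miRNA assays plus the GFP
    bait), optional lysate wells (miRNA assays plus U6), and minus-RT
    controls.  With zero noise the pipeline NRQ equals the configured
    enrichment exactly (generator inversion).
    """
    rng = np.random.default_rng(rng_seed)
    records: list[CtRecord] = []

    def emit(sample, assay, condition, true_ct):
        ct = true_ct + (rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0)
        dropped = spec.dropout_ct is not None and ct >= spec.dropout_ct
        records.append(CtRecord(sample, assay, condition, 1,
                                None if dropped else float(ct)))
        if spec.include_rt_controls:
            rt_ct = None if dropped else float(ct + spec.no_rt_offset)
            if rt_ct is not None and spec.dropout_ct is not None and rt_ct >= spec.dropout_ct:
                rt_ct = None
            records.append(CtRecord(sample, assay, condition, 1, rt_ct, rt_control=True))

    for i in range(spec.pulldown_replicates):
        wt, ctl = f"wt{i + 1}", f"ctl{i + 1}"
        emit(wt, "GFP", "wt_utr", _ct_from_abundance(spec.bait_baseline_ct, 1.0, spec.e_bait))
        emit(ctl, "GFP", "control_utr", _ct_from_abundance(spec.bait_baseline_ct, 1.0, spec.e_bait))
        for name, enr in sorted(spec.enrichments.items()):
            emit(wt, name, "wt_utr",
                 _ct_from_abundance(spec.mirna_baseline_ct,
                                    spec.control_abundance * enr, spec.e_taqman))
            emit(ctl, name, "control_utr",
                 _ct_from_abundance(spec.mirna_baseline_ct,
                                    spec.control_abundance, spec.e_taqman))

    if spec.lysate_rel_abundance is not None:
        for i in range(spec.profiling_replicates):
            lys = f"lys{i + 1}"
            emit(lys, "U6", "lysate", spec.u6_ct)
            for name, rel in sorted(spec.lysate_rel_abundance.items()):
                emit(lys, name, "lysate", spec.u6_ct - np.log2(rel))
    return records


def gen_polya_region(length: int, signals: dict, rng_seed: int,
                     scrub_variants=None, gc_content: float = 0.45) -> str:
    """A synthetic genomic region with poly(A) hexamers planted at given positions.

    ``signals`` maps 1-based positions to hexamer strings.  The background is
    scrubbed of every other occurrence of the scrub variants (default: the
    standard poly(A) hexamer set), so a scan recovers exactly the planted
    signals.  This is a synthetic stand-in for a real genomic reference, not
    any actual locus.
    """
    from .utr_annotation import DEFAULT_VARIANTS, scan_polya_signals

    variants = set(scrub_variants) if scrub_variants is not None else set(DEFAULT_VARIANTS)
    rng = np.random.default_rng(rng_seed)
    planted = set()
    for pos, hexamer in signals.items():
        if len(hexamer) != 6 or pos < 1 or pos + 5 > length:
            raise ValueError(f"signal {hexamer!r} at {pos} does not fit")
        planted.update(range(pos - 1, pos + 5))
    probs = [(1 - gc_content) / 2, gc_content / 2, gc_content / 2, (1 - gc_content) / 2]
    seq = list("".join(rng.choice(list(_BASES), size=length, p=probs)))
    for pos, hexamer in signals.items():
        seq[pos - 1:pos + 5] = list(hexamer.upper())
    for _ in range(500):
        extras = [s for s in scan_polya_signals("".join(seq), variants)
                  if s.position not in signals]
        if not extras:
            return "".join(seq)
        for s in extras:
            mutable = [p for p in range(s.position - 1, s.position + 5)
                       if p not in planted]
            if not mutable:
                raise ValueError("spurious hexamer pinned inside a planted signal")
            p = int(rng.choice(mutable))
            seq[p] = str(rng.choice([b for b in _BASES if b != seq[p]]))
    raise ValueError("could not scrub the background of spurious hexamers")


def gen_dilution_series(efficiency: float, n_points: int = 5, c0: float = 15.0,
                        noise_sd: float = 0.0, rng_seed: int = 0) -> DilutionSeries:
    """Ten-fold dilution standard curve: ``Ct_k = c0 + k / log10(E)``."""
    if not (1.0 < efficiency <= 2.0):
        raise ValueError("efficiency must satisfy 1 < E <= 2")
    rng = np.random.default_rng(rng_seed)
    pts = []
    for k in range(n_points):
        ct = c0 + k / np.log10(efficiency)
        if noise_sd > 0:
            ct += rng.normal(0.0, noise_sd)
        pts.append((float(k), float(ct)))
    return DilutionSeries(pts)
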