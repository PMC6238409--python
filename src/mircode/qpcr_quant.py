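"""qPCR quantification arithmetic for miRNA pull-down (miTRAP) experiments.

Implements the whole quantification chain:

* standard-curve amplification efficiency, ``E = 10^(1/slope)`` with the
  slope of Ct regressed on log10 fold-dilution;
* QC filtering of Ct plates: minus-RT margin, technical-replicate SD,
  detection at Ct < 40, and the substitution of undetermined control-condition
  Cts by 40 when a miRNA is detected in every wild-type pull-down;
* relative expression vs the U6 reference (``2^(Ct_U6 - Ct_target)``);
* efficiency-corrected fold differences and the Pfaffl normalized relative
  quantity, ``NRQ = E_miRNA^dCt_miRNA / E_bait^dCt_bait`` with the bait (GFP)
  primer efficiency 1.952;
* the miTRAP ratio (pull-down relative abundance over lysate relative
  abundance);
* interaction classification into high-confidence / low-confidence /
  non-specific / no-interaction categories from per-replicate NRQs;
* an exact two-sided Mann-Whitney U test by full enumeration (midranks for
  ties), with a flagged normal approximation for larger samples.

Undetermined Cts propagate as ``None`` everywhere except under the explicit
substitution rule.
"""

from __future__ import annotations

import itertools
import math
import statistics
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

__all__ = [
    "CtRecord",
    "QpcrConfig",
    "DilutionSeries",
    "EfficiencyEstimate",
    "QcResult",
    "NRQResult",
    "MannWhitneyResult",
    "estimate_efficiency",
    "qc_filter",
    "relative_expression",
    "fold_difference",
    "pfaffl_nrq",
    "mitrap_ratio",
    "classify_interaction",
    "mitrap_nrq_table",
    "classification_summary",
    "mann_whitney_exact",
]

CATEGORIES = ("high_confidence", "low_confidence", "non_specific", "no_interaction")


@dataclass(frozen=True)
class CtRecord:
    """One qPCR well: (sample, assay, condition, technical replicate)."""

    sample: str
    assay: str
    condition: str
    replicate: int
    ct: float | None
    rt_control: bool = False

    def __post_init__(self):
        if self.ct is not None and not self.ct > 0:
            raise ValueError("defined Ct values must be positive")


@dataclass(frozen=True)
class QpcrConfig:
    """Efficiencies, QC thresholds and plate layout conventions."""

    e_bait: float = 1.952
    e_taqman: float = 2.0
    detect_ct_max: float = 40.0
    no_rt_margin: float = 10.0
    replicate_sd_max: float = 0.5
    undefined_ct_substitute: float = 40.0
    pulldown_replicates: int = 4
    profiling_replicates: int = 3
    nonspecific_nrq_max: float = 1.0
    exact_mw_limit: int = 12
    missing_rt_partner: str = "warn"  # or "error"
    wt_condition: str = "wt_utr"
    control_condition: str = "control_utr"
    bait_assay: str = "GFP"
    reference_assay: str = "U6"

    def __post_init__(self):
        for e in (self.e_bait, self.e_taqman):
            if not (1.0 < e <= 2.0):
                raise ValueError("amplification efficiencies must satisfy 1 < E <= 2")


@dataclass
class DilutionSeries:
    """A standard curve: (log10 fold-dilution, Ct) points."""

    points: list

    def __post_init__(self):
        if len(self.points) < 3:
            raise ValueError("a standard curve needs at least 3 points")
        dils = [p[0] for p in self.points]
        if any(b <= a for a, b in zip(dils, dils[1:])):
            raise ValueError("fold-dilutions must be strictly increasing")


@dataclass(frozen=True)
class EfficiencyEstimate:
    efficiency: float
    slope: float
    r2: float
    low_r2_warning: bool


def estimate_efficiency(series: DilutionSeries) -> EfficiencyEstimate:
    """Amplification efficiency from a dilution series via ``10^(1/slope)``.

    Least-squares slope of Ct on log10(fold-dilution).  An r-squared below
    0.99 raises a warning flag (the curve is suspect), not an error.
    """
    x = [p[0] for p in series.points]
    y = [p[1] for p in series.points]
    fit = stats.linregress(x, y)
    if fit.slope == 0 or math.isnan(fit.slope):
        raise ValueError("standard curve has zero slope")
    eff = 10.0 ** (1.0 / fit.slope)
    r2 = fit.rvalue ** 2
    return EfficiencyEstimate(eff, fit.slope, r2, low_r2_warning=r2 < 0.99)


# ---------------------------------------------------------------------------
# QC filtering


@dataclass
class QcResult:
    kept: list
    discarded: list  # [(CtRecord, reason)]
    detected: dict   # assay -> bool
    substituted: list
    warnings: list


def qc_filter(records: list[CtRecord], config: QpcrConfig = QpcrConfig()) -> QcResult:
    """Apply the plate QC rules in fixed order, tagging every discard.

    (a) a (sample, assay) whose minus-RT Ct is within ``no_rt_margin`` cycles
    of its +RT Ct is excluded (reason ``no_rt_margin``); (b) a technical
    replicate group with Ct SD above ``replicate_sd_max`` is discarded
    (reason ``replicate_sd``); (c) an assay is flagged detected only when
    every well of the detection (wild-type pull-down) condition has
    Ct < ``detect_ct_max``; (d) undetermined control-condition Cts of detected
    assays are substituted by ``undefined_ct_substitute``.  Minus-RT wells are
    consumed by rule (a) and are not part of ``kept``; the filter is
    idempotent on its own output.
    """
    warnings: list = []
    discarded: list = []
    rt_wells: dict = {}
    plus: list = []
    for r in records:
        if r.rt_control:
            rt_wells.setdefault((r.sample, r.assay), []).append(r)
        else:
            plus.append(r)

    # (a) minus-RT margin
    kept_a: list = []
    bad_pairs = set()
    by_pair: dict = {}
    for r in plus:
        by_pair.setdefault((r.sample, r.assay), []).append(r)
    for pair, group in by_pair.items():
        minus = rt_wells.get(pair)
        if not minus:
            if config.missing_rt_partner == "error":
                raise ValueError(f"no minus-RT partner for {pair}")
            if rt_wells:  # plates with no -RT wells at all stay silent
                warnings.append(f"no minus-RT partner for {pair}; margin rule skipped")
            continue
        plus_cts = [g.ct for g in group if g.ct is not None]
        minus_cts = [m.ct for m in minus if m.ct is not None]
        if not plus_cts or not minus_cts:
            continue  # no amplification on one side: margin rule cannot fail
        if statistics.fmean(minus_cts) - statistics.fmean(plus_cts) < config.no_rt_margin:
            bad_pairs.add(pair)
    for r in plus:
        if (r.sample, r.assay) in bad_pairs:
            discarded.append((r, "no_rt_margin"))
        else:
            kept_a.append(r)

    # (b) technical replicate SD
    kept_b: list = []
    by_group: dict = {}
    for r in kept_a:
        by_group.setdefault((r.sample, r.assay, r.condition), []).append(r)
    for group in by_group.values():
        cts = [g.ct for g in group if g.ct is not None]
        if len(cts) >= 2 and statistics.stdev(cts) > config.replicate_sd_max:
            discarded.extend((g, "replicate_sd") for g in group)
        else:
            kept_b.extend(group)

    # (c) detection in the wild-type pull-down condition
    detected: dict = {}
    for assay in sorted({r.assay for r in kept_b}):
        wt = [r for r in kept_b if r.assay == assay and r.condition == config.wt_condition]
        if wt:
            detected[assay] = all(r.ct is not None and r.ct < config.detect_ct_max
                                  for r in wt)
        else:
            others = [r for r in kept_b if r.assay == assay]
            detected[assay] = all(r.ct is not None and r.ct < config.detect_ct_max
                                  for r in others)

    # (d) substitute undetermined control-condition Cts of detected assays
    kept: list = []
    substituted: list = []
    for r in kept_b:
        if (r.ct is None and r.condition == config.control_condition
                and detected.get(r.assay, False)):
            r = replace(r, ct=config.undefined_ct_substitute)
            substituted.append(r)
        kept.append(r)

    kept.sort(key=lambda r: (r.condition, r.sample, r.assay, r.replicate))
    return QcResult(kept, discarded, detected, substituted, warnings)


# ---------------------------------------------------------------------------
# quantification arithmetic


def relative_expression(ct_target: float | None, ct_u6: float | None) -> float | None:
    """Expression relative to U6: ``2^(Ct_U6 - Ct_target)``; None propagates."""
    if ct_target is None or ct_u6 is None:
        return None
    return 2.0 ** (ct_u6 - ct_target)


def fold_difference(e: float, ct_ref_condition: float | None,
                    ct_test_condition: float | None) -> float | None:
    """Efficiency-corrected fold difference ``E^(Ct_ref - Ct_test)``."""
    if e <= 1.0:
        raise ValueError("amplification efficiency must exceed 1")
    if ct_ref_condition is None or ct_test_condition is None:
        return None
    return e ** (ct_ref_condition - ct_test_condition)


def pfaffl_nrq(dct_mirna: float | None, dct_bait: float | None,
               config: QpcrConfig = QpcrConfig()) -> float | None:
    """Pfaffl normalized relative quantity ``E_miRNA^dCt / E_bait^dCt_bait``.

    With both efficiencies equal to 2 this reduces to the classic 2^ddCt.
    """
    if dct_mirna is None or dct_bait is None:
        return None
    return (config.e_taqman ** dct_mirna) / (config.e_bait ** dct_bait)


def mitrap_ratio(mean_ct_gfp_pulldown: float | None, mean_ct_mirna_pulldown: float | None,
                 rel_abundance_lysate: float | None,
                 config: QpcrConfig = QpcrConfig()) -> float | None:
    """Pull-down relative abundance over lysate relative abundance.

    Pull-down abundance is ``E_bait^meanCt[GFP] / E_miRNA^meanCt[miRNA]``
    over the pull-down replicates; the lysate abundance comes from
    :func:`relative_expression` against U6.
    """
    if (mean_ct_gfp_pulldown is None or mean_ct_mirna_pulldown is None
            or rel_abundance_lysate is None or rel_abundance_lysate == 0):
        return None
    pulldown = (config.e_bait ** mean_ct_gfp_pulldown) / (config.e_taqman ** mean_ct_mirna_pulldown)
    return pulldown / rel_abundance_lysate


# ---------------------------------------------------------------------------
# interaction classification


@dataclass(frozen=True)
class NRQResult:
    """Point NRQ (geometric mean over replicates), its 95% CI and category."""

    mirna: str
    nrq: float | None
    ci95: tuple | None
    detected: bool
    category: str

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.detected and self.nrq is not None and not self.nrq > 0:
            raise ValueError("NRQ of a detected miRNA must be positive")


def classify_interaction(mirna: str, nrq_replicates, detected: bool,
                         config: QpcrConfig = QpcrConfig()) -> NRQResult:
    """Classify a miRNA's pull-down interaction from per-replicate NRQs.

    Undetected (any wild-type replicate at or above the detection ceiling)
    gives ``no_interaction``.  Otherwise the point NRQ is the geometric mean;
    the 95% CI is a t-interval on log2 NRQs back-transformed to the ratio
    scale.  ``high_confidence`` needs NRQ > 1 with the CI clear of 1;
    ``low_confidence`` has NRQ > 1 with the CI reaching 1;
    ``non_specific`` has NRQ <= 1.
    """
    if not detected:
        return NRQResult(mirna, None, None, False, "no_interaction")
    nrqs = list(nrq_replicates)
    if len(nrqs) < config.pulldown_replicates:
        raise ValueError(f"{mirna}: {len(nrqs)} replicates, "
                         f"{config.pulldown_replicates} required")
    if any(v is None or v <= 0 for v in nrqs):
        raise ValueError(f"{mirna}: undefined or non-positive replicate NRQ")
    logs = np.log2(nrqs)
    n = len(logs)
    mean = float(np.mean(logs))
    point = 2.0 ** mean
    sd = float(np.std(logs, ddof=1))
    half = stats.t.ppf(0.975, n - 1) * sd / math.sqrt(n)
    ci = (2.0 ** (mean - half), 2.0 ** (mean + half))
    if point > config.nonspecific_nrq_max:
        category = "high_confidence" if ci[0] > 1.0 else "low_confidence"
    else:
        category = "non_specific"
    return NRQResult(mirna, point, ci, True, category)


def mitrap_nrq_table(records: list[CtRecord],
                     config: QpcrConfig = QpcrConfig()) -> dict:
    """Full QC + per-replicate NRQ + classification for a miTRAP plate table.

    Technical replicates are collapsed to mean Ct after QC; biological
    replicates (samples) of the wild-type and control conditions are paired
    in sorted sample order.  The per-replicate NRQ contrast is
    ``dCt = Ct[control] - Ct[wild-type]`` for both the miRNA and the bait.
    Returns ``{mirna: NRQResult}``.
    """
    qc = qc_filter(records, config)

    def mean_ct(sample, assay, condition):
        cts = [r.ct for r in qc.kept
               if r.sample == sample and r.assay == assay and r.condition == condition]
        if not cts or any(c is None for c in cts):
            return None
        return statistics.fmean(cts)

    wt_samples = sorted({r.sample for r in qc.kept if r.condition == config.wt_condition})
    ctl_samples = sorted({r.sample for r in qc.kept if r.condition == config.control_condition})
    n_rep = min(len(wt_samples), len(ctl_samples))
    assays = sorted({r.assay for r in qc.kept
                     if r.assay not in (config.bait_assay, config.reference_assay)
                     and r.condition in (config.wt_condition, config.control_condition)})
    dct_bait = [fold_ct(mean_ct(ctl_samples[i], config.bait_assay, config.control_condition),
                        mean_ct(wt_samples[i], config.bait_assay, config.wt_condition))
                for i in range(n_rep)]
    results = {}
    for assay in assays:
        if not qc.detected.get(assay, False):
            results[assay] = classify_interaction(assay, [], False, config)
            continue
        nrqs = []
        for i in range(n_rep):
            dct_m = fold_ct(mean_ct(ctl_samples[i], assay, config.control_condition),
                            mean_ct(wt_samples[i], assay, config.wt_condition))
            nrqs.append(pfaffl_nrq(dct_m, dct_bait[i], config))
        results[assay] = classify_interaction(assay, nrqs, True, config)
    return results


def fold_ct(ct_ref: float | None, ct_test: float | None) -> float | None:
    """dCt = Ct[reference condition] - Ct[test condition]; None propagates."""
    if ct_ref is None or ct_test is None:
        return None
    return ct_ref - ct_test


def classification_summary(results: dict) -> dict:
    """Counts and percentages per interaction category (plus total interactors).

    Percentages are over all assayed miRNAs and sum to 100 within rounding;
    *interactors* are the high- plus low-confidence calls.
    """
    total = len(results)
    counts = {c: sum(1 for r in results.values() if r.category == c) for c in CATEGORIES}
    pct = {c: (100.0 * counts[c] / total if total else 0.0) for c in CATEGORIES}
    n_int = counts["high_confidence"] + counts["low_confidence"]
    return {
        "n_assayed": total,
        "counts": counts,
        "percent": pct,
        "interactors": {"count": n_int,
                        "percent": 100.0 * n_int / total if total else 0.0},
    }


# ---------------------------------------------------------------------------
# exact Mann-Whitney U


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p_two_sided: float
    p_less: float
    p_greater: float
    exact: bool


def mann_whitney_exact(group_a, group_b, exact_limit: int | None = None) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test, exact by full enumeration for small n.

    Midranks handle ties; the exact path enumerates every assignment of the
    pooled (mid)ranks to group A, so with ties it is the exact permutation
    null of the U statistic.  Above ``exact_limit`` pooled observations
    (default 12) the scipy normal approximation is used and flagged.  The
    two-sided p is twice the smaller one-sided tail, capped at 1.
    """
    a = [float(v) for v in group_a]
    b = [float(v) for v in group_b]
    if not a or not b:
        raise ValueError("both groups must be non-empty")
    if any(math.isnan(v) for v in a + b):
        raise ValueError("undefined values in input")
    limit = 12 if exact_limit is None else exact_limit
    n_a, n_b = len(a), len(b)
    pooled = a + b
    ranks = stats.rankdata(pooled)
    u_obs = float(np.sum(ranks[:n_a])) - n_a * (n_a + 1) / 2.0

    if n_a + n_b <= limit:
        total = math.comb(n_a + n_b, n_a)
        n_le = n_ge = 0
        base = n_a * (n_a + 1) / 2.0
        eps = 1e-9
        for idx in itertools.combinations(range(n_a + n_b), n_a):
            u = float(sum(ranks[i] for i in idx)) - base
            if u <= u_obs + eps:
                n_le += 1
            if u >= u_obs - eps:
                n_ge += 1
        p_less = n_le / total
        p_greater = n_ge / total
        p_two = min(1.0, 2.0 * min(p_less, p_greater))
        return MannWhitneyResult(u_obs, p_two, p_less, p_greater, True)

    res_less = stats.mannwhitneyu(a, b, alternative="less", method="asymptotic")
    res_greater = stats.mannwhitneyu(a, b, alternative="greater", method="asymptotic")
    p_less, p_greater = float(res_less.pvalue), float(res_greater.pvalue)
    p_two = min(1.0, 2.0 * min(p_less, p_greater))
    return MannWhitneyResult(u_obs, p_two, p_less, p_greater, False)
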