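"""End-to-end orchestration: scan -> filter -> quantify -> classify -> landscape.

A single YAML config names the inputs and parameter blocks; every stage is
also runnable standalone through its module (or the CLI subcommands).  The
run emits a versioned, machine-readable JSON report whose content is a pure
function of the config and inputs: rerunning with the same config and seed
reproduces it byte for byte.

A missing or empty plate table skips the quantification and landscape stages
with a warning; the sequence-level stages still complete.  When a
planted-truth site table is supplied (synthetic runs), the report scores the
scan against it (precision/recall).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as mio
from .landscape import LandscapeConfig, LandscapeSite, build_landscape, cluster_regions, cooperative_pairs
from .mre_filter import FilterConfig, apply_funnel, collapse_sites_per_mirna
from .qpcr_quant import QpcrConfig, classification_summary, mitrap_nrq_table
from .seed_scan import SeedMatchConfig, scan_mres

__all__ = ["RunConfig", "run_pipeline", "REPORT_SCHEMA_VERSION"]

REPORT_SCHEMA_VERSION = 1

log = logging.getLogger("mircode")


@dataclass
class RunConfig:
    """Paths and parameter blocks for one pipeline run."""

    utr_fasta: str
    mirna_fasta: str
    alignment_fasta: str | None = None
    plates_csv: str | None = None
    truth_sites_tsv: str | None = None
    outdir: str = "mircode_out"
    seed: int = 0
    utr_length: int | None = None
    scan: SeedMatchConfig = field(default_factory=SeedMatchConfig.universe)
    filter: FilterConfig = field(default_factory=FilterConfig)
    qpcr: QpcrConfig = field(default_factory=QpcrConfig)
    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        for key, klass in (("scan", SeedMatchConfig), ("filter", FilterConfig),
                           ("qpcr", QpcrConfig), ("landscape", LandscapeConfig)):
            if key in kwargs and isinstance(kwargs[key], dict):
                block = dict(kwargs[key])
                for fs in ("required_species", "conservation_clade"):
                    if fs in block and block[fs] is not None:
                        block[fs] = frozenset(block[fs])
                kwargs[key] = klass(**block)
        cfg = cls(**kwargs)
        for p in (cfg.utr_fasta, cfg.mirna_fasta, cfg.alignment_fasta, cfg.plates_csv,
                  cfg.truth_sites_tsv):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        return cfg


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return (and write) the run report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"schema_version": REPORT_SCHEMA_VERSION, "seed": config.seed,
                    "warnings": []}

    utr = next(iter(mio.read_fasta(config.utr_fasta).values()))
    mirnas = mio.read_mirna_fasta(config.mirna_fasta)
    utr_length = config.utr_length or len(utr)

    # --- scan
    log.info("scanning %d nt UTR against %d miRNAs", len(utr), len(mirnas))
    sites = scan_mres(utr, mirnas, config.scan)
    mio.write_sites_tsv(outdir / "sites.tsv", sites)
    report["scan"] = {"n_sites": len(sites), "n_mirnas": len(mirnas),
                      "utr_length": len(utr)}

    if config.truth_sites_tsv:
        truth = mio.read_sites_tsv(config.truth_sites_tsv)
        truth_keys = {(t.mirna, t.start, t.site_type) for t in truth}
        found = {(s.mirna, s.start, s.site_type) for s in sites}
        tp = len(found & truth_keys)
        report["scan"]["planted_truth"] = {
            "precision": tp / len(found) if found else 0.0,
            "recall": tp / len(truth_keys) if truth_keys else 0.0,
        }

    # --- funnel
    aln = mio.read_alignment_fasta(config.alignment_fasta) if config.alignment_fasta else None
    survivors, funnel = apply_funnel(sites, aln, mirnas, config.filter)
    for name, count in funnel.stages:
        log.info("funnel %-16s %6d hits", name, count)
    mio.write_sites_tsv(outdir / "survivors.tsv", survivors)
    report["funnel"] = funnel.to_dict()

    # --- quantify + classify
    records = mio.read_plate_table(config.plates_csv) if config.plates_csv else []
    if not records:
        msg = "plate table missing or empty; quantification and landscape skipped"
        log.warning(msg)
        report["warnings"].append(msg)
        _write_report(outdir, report)
        return report

    results = mitrap_nrq_table(records, config.qpcr)
    summary = classification_summary(results)
    report["classification"] = {
        "summary": summary,
        "per_mirna": {name: {
            "category": r.category, "detected": r.detected,
            "nrq": r.nrq, "ci95": None if r.ci95 is None else list(r.ci95),
        } for name, r in sorted(results.items())},
    }
    log.info("classified %d assayed miRNAs: %s", summary["n_assayed"], summary["counts"])

    # --- landscape over the interacting miRNAs' surviving sites
    interactors = {n for n, r in results.items()
                   if r.category in ("high_confidence", "low_confidence")}
    lsites = [LandscapeSite(s.mirna, (s.start + s.end) // 2, results[s.mirna].nrq,
                            start=s.start, end=s.end)
              for s in collapse_sites_per_mirna(survivors) if s.mirna in interactors]
    scape = build_landscape(lsites, utr_length, config.landscape)
    clusters = cluster_regions(scape.peaks, config.landscape)
    pairs = cooperative_pairs(lsites, config.landscape)
    mio.write_bedgraph(outdir / "landscape.bedgraph", "utr", scape.track)
    mio.write_bed6(outdir / "clusters.bed", "utr", [c.interval for c in clusters],
                   names=["/".join(c.mirnas) for c in clusters])
    report["landscape"] = {
        "n_peaks": len(scape.peaks),
        "n_overlap_intervals": len(scape.overlap_intervals),
        "n_cooperative_pairs": len(pairs),
        "clusters": [{"interval": list(c.interval), "mirnas": c.mirnas,
                      "has_cooperative_pair": c.has_cooperative_pair}
                     for c in clusters],
    }
    _write_report(outdir, report)
    return report


def _write_report(outdir: Path, report: dict) -> None:
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
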