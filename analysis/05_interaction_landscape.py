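#!/usr/bin/env python
"""Positional interaction landscape and cooperative-site clustering.

Joins the funnel survivors (03) with the classified NRQs (04): each
interacting miRNA contributes a peak at its MRE position(s), 25 nt wide on
either side and as tall as its mean NRQ.  Reports cooperative pairs (8-50 nt
spacing, excluding miRNAs sharing overlapping MREs) and merged cluster
regions.  Writes bedGraph/BED under results/landscape/.
"""

import sys
from pathlib import Path

import pandas as pd

from mircode import io as mio
from mircode.landscape import (LandscapeConfig, LandscapeSite, build_landscape,
                               cluster_regions, cooperative_pairs)
from mircode.mre_filter import collapse_sites_per_mirna

BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "landscape"
UTR_LENGTH = 876


def main() -> None:
    survivors_path = BASE / "funnel" / "survivors.tsv"
    nrq_path = BASE / "mitrap" / "nrq.tsv"
    if not survivors_path.exists() or not nrq_path.exists():
        print("run analysis/03_candidate_funnel.py and 04_mitrap_quantification.py first",
              file=sys.stderr)
        return 1
    OUT.mkdir(parents=True, exist_ok=True)

    survivors = mio.read_sites_tsv(survivors_path)
    nrq = pd.read_csv(nrq_path, sep="\t")
    heights = {str(r.mirna): float(r.nrq) for r in nrq.itertuples(index=False)
               if r.category in ("high_confidence", "low_confidence")}

    sites = [LandscapeSite(s.mirna, (s.start + s.end) // 2, heights[s.mirna],
                           start=s.start, end=s.end)
             for s in collapse_sites_per_mirna(survivors) if s.mirna in heights]
    print(f"{len(sites)} MREs for {len({s.mirna for s in sites})} interacting miRNAs")

    cfg = LandscapeConfig()
    scape = build_landscape(sites, UTR_LENGTH, cfg)
    pairs = cooperative_pairs(sites, cfg)
    clusters = cluster_regions(scape.peaks, cfg)

    mio.write_bedgraph(OUT / "landscape.bedgraph", "utr", scape.track)
    mio.write_bed6(OUT / "peaks.bed", "utr", [p.interval for p in scape.peaks],
                   names=[p.mirna for p in scape.peaks],
                   scores=[p.height for p in scape.peaks])
    mio.write_bed6(OUT / "overlaps.bed", "utr", scape.overlap_intervals)
    mio.write_bed6(OUT / "clusters.bed", "utr", [c.interval for c in clusters],
                   names=["/".join(c.mirnas) for c in clusters])

    print(f"cooperative pairs (8-50 nt spacing): {len(pairs)}")
    for a, b in pairs:
        print(f"  {a.mirna}@{a.position} -- {b.mirna}@{b.position} "
              f"(spacing {abs(a.position - b.position)} nt)")
    print(f"cluster regions: {len(clusters)}")
    for c in clusters:
        coop = "cooperative" if c.has_cooperative_pair else "isolated"
        print(f"  [{c.interval[0]}, {c.interval[1]}] {','.join(c.mirnas)} ({coop})")
    print(f"wrote {OUT}/landscape.bedgraph, peaks.bed, overlaps.bed, clusters.bed")
    return 0


if __name__ == "__main__":
    sys.exit(main())
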