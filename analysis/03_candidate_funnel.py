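#!/usr/bin/env python
"""Run the hierarchical candidate funnel over the enumerated site universe.

Consumes the universe from 02_scan_sites.py, simulates a 12-ortholog
alignment in which the planted sites are retained in 95% of species (and the
background drifts), then applies the stage filters: mismatch exclusion,
6mer+wobble exclusion, >=85% clade conservation, and the required-species
(human) filter.  Writes the funnel report and survivors under
results/funnel/.
"""

import json
import sys
from pathlib import Path

from mircode import io as mio
from mircode.mre_filter import FilterConfig, apply_funnel
from mircode import synthetic_data as synth

SITES = Path(__file__).resolve().parent.parent / "results" / "sites"
OUT = Path(__file__).resolve().parent.parent / "results" / "funnel"
SEED = 30


def main() -> None:
    if not (SITES / "universe.tsv").exists():
        print("run analysis/02_scan_sites.py first", file=sys.stderr)
        return 1
    OUT.mkdir(parents=True, exist_ok=True)

    utr = next(iter(mio.read_fasta(SITES / "utr.fa").values()))
    mirnas = mio.read_mirna_fasta(SITES / "mirnas.fa")
    truth = mio.read_sites_tsv(SITES / "truth_sites.tsv")
    universe = mio.read_sites_tsv(SITES / "universe.tsv")

    aln, _ = synth.gen_ortholog_alignment(utr, truth, 12, 0.95, SEED, mirnas=mirnas)
    mio.write_fasta(OUT / "orthologs.afa", aln.sequences)

    survivors, report = apply_funnel(universe, aln, mirnas, FilterConfig())
    for name, count in report.stages:
        print(f"  {name:<18} {count:>6}")
    print(f"unique MREs: {report.unique_mre_count}; "
          f"unique miRNAs: {report.unique_mirna_count}")
    r = report.redundancy
    print(f"redundancy: {r.multi_mirna_mres} MREs with multiple miRNAs, "
          f"{r.multi_mre_mirnas} miRNAs with multiple MREs")

    mio.write_sites_tsv(OUT / "survivors.tsv", survivors)
    with open(OUT / "funnel.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
    print(f"wrote {OUT}/funnel.json and survivors.tsv")
    return 0


if __name__ == "__main__":
    sys.exit(main())
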