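#!/usr/bin/env python
"""Poly(A)-signal and cleavage-site annotation of a 3'UTR-proximal region.

Builds a synthetic stand-in genomic region (2.2 kb) with the three hexamer
signals planted at positions 688, 861 and 1930 downstream of the stop codon,
scans the first 2000 nt for the common poly(A) variants, and annotates CA
cleavage candidates downstream of each signal together with the U/G richness
of their downstream windows.  Writes BED/TSV output under results/polya/.
"""

import sys
from pathlib import Path

from mircode import io as mio
from mircode.synthetic_data import gen_polya_region
from mircode.utr_annotation import find_cleavage_candidates, scan_polya_signals

OUT = Path(__file__).resolve().parent.parent / "results" / "polya"
SEED = 97


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    region = gen_polya_region(2200, {688: "ATTAAA", 861: "AATAAA", 1930: "TATAAA"},
                              rng_seed=SEED)
    # give the functional 861 signal a realistic cleavage context: a CA 9 nt
    # downstream and, 17 nt after the CA, a 16-nt window that is 87.5% U/G
    region = region[:869] + "CA" + region[871:]
    region = region[:886] + "TGTGTGTGTGTGTGAA" + region[902:]
    mio.write_fasta(OUT / "synthetic_region.fa", {"synthetic_region": region})

    signals = scan_polya_signals(region, {"AATAAA", "ATTAAA", "TATAAA"},
                                 region_end=2000)
    if [s.position for s in signals] != [688, 861, 1930]:
        raise RuntimeError("cleavage-context splice disturbed the planted signals")
    mio.write_bed6(OUT / "signals.bed", "synthetic_region",
                   [(s.position, s.end) for s in signals],
                   names=[s.hexamer for s in signals])
    print(f"poly(A) signals within 2000 nt: "
          f"{', '.join(f'{s.hexamer}@{s.position}' for s in signals)}")

    with open(OUT / "cleavage_candidates.tsv", "w") as fh:
        fh.write("signal_position\tca_position\tdistance\tug_window_start\t"
                 "ug_fraction\ttruncated\n")
        for s in signals:
            cands = find_cleavage_candidates(region, s)
            for c in cands:
                frac = "" if c.ug_fraction is None else f"{c.ug_fraction:.4f}"
                fh.write(f"{c.signal_position}\t{c.ca_position}\t"
                         f"{c.distance_from_signal}\t{c.ug_window_start}\t"
                         f"{frac}\t{c.truncated}\n")
            best = max((c for c in cands if c.ug_fraction is not None),
                       key=lambda c: c.ug_fraction, default=None)
            if best is None:
                print(f"  signal @{s.position}: no CA candidate within 30 nt")
            else:
                print(f"  signal @{s.position}: best CA @{best.ca_position} "
                      f"(+{best.distance_from_signal} nt), downstream window "
                      f"{best.ug_fraction:.1%} U/G")
    print(f"wrote {OUT}/signals.bed and cleavage_candidates.tsv")


if __name__ == "__main__":
    sys.exit(main())
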