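"""Readers and writers for the standard formats the pipeline consumes and emits.

FASTA (plain and aligned) goes through Biopython; plate tables through
pandas.  Interval output is BED6 / bedGraph with the 1-based inclusive
internal coordinates converted to 0-based half-open here, in the writers,
and nowhere else.
"""

from __future__ import annotations

import csv
import math

import pandas as pd
from Bio import SeqIO

from .mre_filter import OrthologAlignment
from .qpcr_quant import CtRecord
from .seed_scan import MiRNARecord, MRESite

__all__ = [
    "read_fasta",
    "read_mirna_fasta",
    "read_alignment_fasta",
    "write_fasta",
    "read_plate_table",
    "write_plate_table",
    "write_sites_tsv",
    "read_sites_tsv",
    "write_bed6",
    "write_bedgraph",
]


def read_fasta(path) -> dict:
    """FASTA file as an ordered ``{record id: sequence}`` mapping."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: dict) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


#: common-name tags for the binomials that matter to the species filters
_COMMON_NAMES = {"Homo sapiens": "human", "Mus musculus": "mouse",
                 "Rattus norvegicus": "rat"}


def read_mirna_fasta(path) -> list[MiRNARecord]:
    """Mature-miRNA FASTA in the miRBase dialect.

    Headers look like ``mmu-miR-375-3p MIMAT0004729 Mus musculus miR-375-3p``;
    the species tag is taken from the binomial (words 3-4) when present, with
    a lowercase common-name alias added for the species the filters name
    (human, mouse, rat).  Records sharing an id have their species sets
    merged; if no species can be parsed the set is left empty for the caller
    to assign.
    """
    species_by_name: dict = {}
    seq_by_name: dict = {}
    order = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.description.split()
        tags = set()
        if len(parts) >= 4:
            binomial = f"{parts[2]} {parts[3]}"
            tags.add(binomial)
            if binomial in _COMMON_NAMES:
                tags.add(_COMMON_NAMES[binomial])
        if rec.id not in seq_by_name:
            order.append(rec.id)
            seq_by_name[rec.id] = str(rec.seq)
            species_by_name[rec.id] = set()
        species_by_name[rec.id] |= tags
    return [MiRNARecord(n, seq_by_name[n], frozenset(species_by_name[n]))
            for n in order]


def read_alignment_fasta(path, reference: str | None = None) -> OrthologAlignment:
    """Aligned FASTA (gap '-'), species = record id; first record is the
    reference unless named explicitly."""
    seqs = read_fasta(path)
    if not seqs:
        raise ValueError(f"empty alignment file {path}")
    ref = reference if reference is not None else next(iter(seqs))
    return OrthologAlignment(seqs, ref)


# ---------------------------------------------------------------------------
# qPCR plate tables

PLATE_COLUMNS = ("sample", "assay", "condition", "replicate", "ct", "rt_control")


def read_plate_table(path) -> list[CtRecord]:
    """CSV/TSV plate table; empty or 'undetermined' Ct means undetermined."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"plate table missing columns: {missing}")
    records = []
    for row in df.itertuples(index=False):
        ct = row.ct
        if ct is None or (isinstance(ct, float) and math.isnan(ct)):
            ct_val = None
        elif isinstance(ct, str):
            ct_val = None if ct.strip().lower() in ("", "undetermined", "undefined", "na") \
                else float(ct)
        else:
            ct_val = float(ct)
        rt = row.rt_control
        rt_val = rt if isinstance(rt, bool) else str(rt).strip().lower() in ("1", "true", "yes")
        records.append(CtRecord(str(row.sample), str(row.assay), str(row.condition),
                                int(row.replicate), ct_val, rt_val))
    return records


def write_plate_table(path, records: list[CtRecord]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(PLATE_COLUMNS)
        for r in records:
            w.writerow([r.sample, r.assay, r.condition, r.replicate,
                        "undetermined" if r.ct is None else f"{r.ct:.6g}",
                        str(r.rt_control).lower()])


# ---------------------------------------------------------------------------
# MRE site tables and interval formats

SITE_COLUMNS = ("mirna", "start", "end", "type", "n_wobble", "n_mismatch", "conservation")


def write_sites_tsv(path, sites: list[MRESite]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(SITE_COLUMNS)
        for s in sites:
            w.writerow([s.mirna, s.start, s.end, s.site_type, s.n_wobble, s.n_mismatch,
                        "" if s.conservation is None else f"{s.conservation:.4f}"])


def read_sites_tsv(path) -> list[MRESite]:
    df = pd.read_csv(path, sep="\t")
    sites = []
    for row in df.itertuples(index=False):
        cons = getattr(row, "conservation", None)
        if cons is not None and isinstance(cons, float) and math.isnan(cons):
            cons = None
        sites.append(MRESite(str(row.mirna), int(row.start), str(row.type),
                             int(row.n_wobble), int(row.n_mismatch),
                             conservation=None if cons is None else float(cons)))
    return sites


def write_bed6(path, chrom: str, intervals, names=None, scores=None) -> None:
    """1-based inclusive ``(lo, hi)`` intervals as BED6 (0-based half-open)."""
    ivs = list(intervals)
    names = list(names) if names is not None else [f"iv{i + 1}" for i in range(len(ivs))]
    scores = list(scores) if scores is not None else [0] * len(ivs)
    with open(path, "w") as fh:
        for (lo, hi), name, score in zip(ivs, names, scores):
            fh.write(f"{chrom}\t{lo - 1}\t{hi}\t{name}\t{score:g}\t+\n")


def write_bedgraph(path, chrom: str, track) -> None:
    """Per-nucleotide track (index 0 = position 1) as run-length bedGraph."""
    with open(path, "w") as fh:
        run_start = 0
        for i in range(1, len(track) + 1):
            if i == len(track) or track[i] != track[run_start]:
                v = track[run_start]
                if v != 0:
                    fh.write(f"{chrom}\t{run_start}\t{i}\t{v:g}\n")
                run_start = i
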