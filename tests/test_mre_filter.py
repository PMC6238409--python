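"""Conservation scoring, the hierarchical candidate funnel and redundancy."""

import numpy as np
import pytest

from mircode.mre_filter import (FilterConfig, OrthologAlignment, apply_funnel,
                                collapse_sites_per_mirna, import_prediction_table,
                                redundancy_summary, site_conservation,
                                unique_mre_groups)
from mircode.seed_scan import MiRNARecord, MRESite, scan_mres
from mircode import synthetic_data as synth


@pytest.fixture
def planted(mirnas):
    spec = synth.PlantSpec(plants=[
        synth.Plant(0, 60, "8mer"), synth.Plant(1, 150, "7mer-m8"),
        synth.Plant(2, 260, "7mer-A1"), synth.Plant(3, 380, "6mer")])
    utr, truth = synth.gen_utr_with_planted_sites(500, spec, 31, mirnas)
    return utr, truth


class TestSiteConservation:
    def test_two_of_ten_species_disrupted_gives_0_8(self, mirnas, planted):
        utr, truth = planted
        aln, retention = synth.gen_ortholog_alignment(
            utr, truth, 10, [1.0] * 8 + [0.0] * 2, rng_seed=5, mirnas=mirnas,
            background_sub_rate=0.0, gap_rate=0.0)
        by = {m.name: m for m in mirnas}
        for t in truth:
            assert site_conservation(t, aln, by[t.mirna]) == pytest.approx(0.8)

    def test_identical_orthologs_give_1(self, mirnas, planted):
        utr, truth = planted
        aln = OrthologAlignment({"ref": utr, "a": utr, "b": utr}, "ref")
        by = {m.name: m for m in mirnas}
        assert site_conservation(truth[0], aln, by[truth[0].mirna]) == 1.0

    def test_all_gap_windows_give_undefined(self, mirnas, planted):
        utr, truth = planted
        t = truth[0]
        gapped = utr[:t.start - 1] + "-" * t.length + utr[t.end:]
        aln = OrthologAlignment({"ref": utr, "a": gapped, "b": gapped}, "ref")
        by = {m.name: m for m in mirnas}
        assert site_conservation(t, aln, by[t.mirna]) is None

    def test_gap_fraction_controls_the_denominator(self, mirnas, planted):
        utr, truth = planted
        t = truth[0]
        half_gapped = utr[:t.start - 1] + "-" * 4 + utr[t.start + 3:]
        aln = OrthologAlignment({"ref": utr, "intact": utr, "gappy": half_gapped}, "ref")
        by = {m.name: m for m in mirnas}
        strict = FilterConfig(max_gap_fraction=0.1)
        loose = FilterConfig(max_gap_fraction=0.9)
        # gappy species excluded under the strict cap: 1/1; included (and
        # broken) under the loose cap: 1/2
        assert site_conservation(t, aln, by[t.mirna], strict) == 1.0
        assert site_conservation(t, aln, by[t.mirna], loose) == 0.5

    def test_site_outside_reference_rejected(self, mirnas, planted):
        utr, truth = planted
        aln = OrthologAlignment({"ref": utr, "a": utr}, "ref")
        far = MRESite(truth[0].mirna, len(utr) - 2, "8mer")
        with pytest.raises(ValueError):
            site_conservation(far, aln, mirnas[0])

    def test_identity_mode_is_stricter_than_type_mode(self, mirnas, planted):
        utr, truth = planted
        t = truth[0]
        # a silent change right next to the site leaves type-mode untouched
        aln_same = OrthologAlignment({"ref": utr, "a": utr}, "ref")
        by = {m.name: m for m in mirnas}
        cfg = FilterConfig(conservation_mode="identity")
        assert site_conservation(t, aln_same, by[t.mirna], cfg) == 1.0


def _universe():
    """A hand-built site universe with exactly known per-stage attributes."""
    sites = [
        MRESite("hsa-1", 10, "8mer", 0, 0, conservation=0.9),      # survives all
        MRESite("hsa-2", 40, "7mer-m8", 1, 0, conservation=0.9),   # survives all
        MRESite("hsa-1", 70, "6mer", 1, 0, conservation=0.9),      # dropped: 6mer+wobble
        MRESite("hsa-3", 100, "7mer-m8", 0, 1, conservation=0.9),  # dropped: mismatch
        MRESite("hsa-2", 130, "8mer", 0, 0, conservation=0.5),     # dropped: conservation
        MRESite("mmu-1", 160, "8mer", 0, 0, conservation=0.9),     # dropped: not in human
    ]
    species = {"hsa-1": {"human", "mouse"}, "hsa-2": {"human", "mouse"},
               "hsa-3": {"human"}, "mmu-1": {"mouse"}}
    return sites, species


class TestApplyFunnel:
    def test_stage_counts_match_planted_bookkeeping(self):
        sites, species = _universe()
        survivors, rep = apply_funnel(sites, None, None, FilterConfig(),
                                      species_map=species)
        assert rep.stages == [("all_hits", 6), ("no_mismatch", 5),
                              ("no_6mer_wobble", 4), ("conserved", 3),
                              ("required_species", 2)]
        assert {s.mirna for s in survivors} == {"hsa-1", "hsa-2"}
        assert rep.unique_mre_count == 2 and rep.unique_mirna_count == 2

    def test_empty_universe_gives_zero_counts(self):
        _, rep = apply_funnel([], None, None, FilterConfig(), species_map={})
        assert all(c == 0 for _, c in rep.stages)

    def test_funnel_monotone_and_nested_on_random_universes(self, rng):
        types = ["6mer", "7mer-A1", "7mer-m8", "8mer"]
        for _ in range(25):
            n = int(rng.integers(1, 60))
            sites = [MRESite(f"m{int(rng.integers(8))}", int(rng.integers(1, 800)),
                             types[int(rng.integers(4))], int(rng.integers(2)),
                             int(rng.integers(2)), conservation=float(rng.random()))
                     for _ in range(n)]
            species = {f"m{i}": ({"human"} if rng.random() < 0.7 else {"mouse"})
                       for i in range(8)}
            survivors, rep = apply_funnel(sites, None, None, FilterConfig(),
                                          species_map=species)
            counts = [c for _, c in rep.stages]
            assert counts == sorted(counts, reverse=True)
            assert set(survivors) <= set(sites)

    def test_mismatch_and_wobble_stages_commute(self):
        sites, species = _universe()
        a, _ = apply_funnel(sites, None, None,
                            FilterConfig(drop_6mer_wobble=False), species_map=species)
        ab, _ = apply_funnel(a, None, None,
                             FilterConfig(drop_mismatch=False), species_map=species)
        b, _ = apply_funnel(sites, None, None,
                            FilterConfig(drop_mismatch=False), species_map=species)
        ba, _ = apply_funnel(b, None, None,
                             FilterConfig(drop_6mer_wobble=False), species_map=species)
        assert set(ab) == set(ba)

    def test_missing_species_annotation_names_the_mirna(self):
        sites = [MRESite("mystery", 10, "8mer", conservation=0.9)]
        with pytest.raises(ValueError, match="mystery"):
            apply_funnel(sites, None, None, FilterConfig(), species_map={})

    def test_undefined_conservation_fails_and_is_flagged(self, mirnas, planted):
        utr, truth = planted
        t = truth[0]
        gapped = utr[:t.start - 1] + "-" * t.length + utr[t.end:]
        aln = OrthologAlignment({"ref": utr, "a": gapped}, "ref")
        survivors, rep = apply_funnel([t], aln, mirnas,
                                      FilterConfig(required_species=frozenset()))
        assert survivors == []
        assert rep.undefined_conservation == [[t.mirna, t.start, t.site_type]]

    def test_end_to_end_with_alignment_conservation(self, mirnas, planted):
        utr, truth = planted
        sites = scan_mres(utr, mirnas)
        aln, _ = synth.gen_ortholog_alignment(utr, truth, 10, 1.0, rng_seed=9,
                                              mirnas=mirnas)
        survivors, rep = apply_funnel(sites, aln, mirnas, FilterConfig())
        assert {(s.mirna, s.start) for s in survivors} == \
            {(t.mirna, t.start) for t in truth}


class TestRedundancy:
    def test_planted_shared_and_multi_site_counts(self):
        sites = [
            MRESite("A", 100, "8mer"), MRESite("B", 100, "8mer"),
            MRESite("A", 200, "8mer"), MRESite("C", 200, "8mer"),
            MRESite("B", 300, "8mer"), MRESite("D", 300, "8mer"),
            MRESite("C", 400, "8mer"), MRESite("D", 500, "8mer"),
        ]
        summary = redundancy_summary(sites)
        assert summary.multi_mirna_mres == 3
        assert summary.multi_mre_mirnas == 4
        assert sorted(len(v) for v in summary.per_mirna_mres.values()) == [2, 2, 2, 2]

    def test_single_site_single_mirna(self):
        summary = redundancy_summary([MRESite("A", 50, "7mer-m8")])
        assert (summary.multi_mirna_mres, summary.multi_mre_mirnas) == (0, 0)

    def test_collapse_keeps_strongest_site_per_locus_and_mirna(self):
        sites = [MRESite("A", 100, "6mer"), MRESite("A", 99, "8mer"),
                 MRESite("A", 100, "7mer-A1"),       # same locus, three types
                 MRESite("A", 300, "6mer"),           # distinct locus
                 MRESite("B", 99, "7mer-m8")]         # other miRNA, same locus
        collapsed = collapse_sites_per_mirna(sites)
        assert [(s.mirna, s.start, s.site_type) for s in collapsed] == \
            [("A", 99, "8mer"), ("B", 99, "7mer-m8"), ("A", 300, "6mer")]

    def test_overlap_below_6nt_keeps_mres_distinct(self):
        near = [MRESite("A", 100, "8mer"), MRESite("B", 104, "8mer")]   # 4 nt overlap
        shared = [MRESite("A", 100, "8mer"), MRESite("B", 102, "8mer")]  # 6 nt overlap
        assert len(unique_mre_groups(near)) == 2
        assert len(unique_mre_groups(shared)) == 1


class TestPredictionTableImport:
    def test_round_trip_with_conservation_and_species(self, tmp_path):
        p = tmp_path / "pred.tsv"
        p.write_text(
            "mirna\tstart\ttype\tn_wobble\tn_mismatch\tconservation\tspecies_flags\n"
            "miR-x\t10\t8mer\t0\t0\t0.95\thuman;mouse\n"
            "miR-y\t40\t6mer\t1\t0\t0.50\tmouse\n")
        sites, species = import_prediction_table(p)
        assert sites[0] == MRESite("miR-x", 10, "8mer", 0, 0)
        assert sites[0].conservation == pytest.approx(0.95)
        assert species == {"miR-x": {"human", "mouse"}, "miR-y": {"mouse"}}
        survivors, rep = apply_funnel(sites, None, None, FilterConfig(),
                                      species_map=species)
        assert [c for _, c in rep.stages] == [2, 2, 1, 1, 1]

    def test_missing_columns_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("mirna\tstart\n" "x\t1\n")
        with pytest.raises(ValueError, match="missing columns"):
            import_prediction_table(p)
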