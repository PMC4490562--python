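import pytest

from dsbscars import (DeletionEvent, Genome, LocusUnevaluable,
                      TransposonCall, TransposonLibrary,
                      catalog_unique_sites, classify_footprint,
                      detect_excision_footprint, detect_insertion_hallmark,
                      element_less_locus, normalize_indel, revcomp,
                      scan_insertion_locus, simulate_genome,
                      simulate_transposon_events)
from conftest import random_seq


def _mk_locus(rng, flank=60, tsd="TA"):
    left = random_seq(rng, flank)
    right = random_seq(rng, flank)
    return left + tsd + right


class TestInsertionHallmark:
    def test_identical_locus_gives_no_call(self, tc_library, rng):
        ref = _mk_locus(rng)
        assert detect_insertion_hallmark(ref, ref, tc_library) is None
        assert scan_insertion_locus(ref, ref, tc_library).status == "no_change"

    @pytest.mark.parametrize("tsd", ["TA", "TCA"])
    def test_constructed_tsd_duplication_called(self, tc_library, rng, tsd):
        ref = _mk_locus(rng, tsd=tsd)
        elem = tc_library.entries["TcSim1"]
        j = 60 + len(tsd)
        sample = ref[:j] + elem + tsd + ref[j:]
        call = detect_insertion_hallmark(ref, sample, tc_library)
        assert call is not None
        assert call.tsd == tsd and call.kind == "insertion"
        assert call.candidate_elements == ("TcSim1",)
        assert call.site == 60

    def test_reverse_orientation_and_truncation(self, tc_library, rng):
        ref = _mk_locus(rng)
        elem = revcomp(tc_library.entries["TcSim2"])[200:]  # truncated, '-'
        sample = ref[:62] + elem + "TA" + ref[62:]
        call = detect_insertion_hallmark(ref, sample, tc_library)
        assert call is not None and "TcSim2" in call.candidate_elements

    def test_ambiguous_element_lists_all_candidates(self, rng):
        shared_start, shared_end = random_seq(rng, 30), random_seq(rng, 30)
        lib = TransposonLibrary({
            "Tc1": shared_start + random_seq(rng, 900) + shared_end,
            "Tc3": shared_start + random_seq(rng, 700) + shared_end,
        })
        ref = _mk_locus(rng)
        # novel segment consisting only of the shared ends matches both
        segment = shared_start + shared_end
        sample = ref[:62] + segment + "TA" + ref[62:]
        call = detect_insertion_hallmark(ref, sample, lib)
        assert call is not None
        assert set(call.candidate_elements) == {"Tc1", "Tc3"}

    def test_insertion_without_tsd_not_called(self, tc_library, rng):
        ref = _mk_locus(rng)
        elem = tc_library.entries["TcSim1"]
        # insert the element *without* duplicating the target site, away
        # from any TA in the flank
        pos = 30
        while ref[pos - 1:pos + 1] in ("TA",) or ref[pos:pos + 2] == "TA":
            pos += 1
        sample = ref[:pos] + "CC" + elem + "GG" + ref[pos:]
        scan = scan_insertion_locus(ref, sample, tc_library)
        assert scan.status in ("insertion_without_hallmark", "no_library_match")
        assert scan.call is None

    def test_unanchorable_flanks_unevaluable(self, tc_library):
        with pytest.raises(LocusUnevaluable):
            scan_insertion_locus("TTTTACCCC", "GGGGTAGGGG", tc_library)

    def test_reported_tsd_literally_flanks_insert_in_sample(self, tc_library,
                                                            rng):
        for _ in range(20):
            tsd = "TCA" if rng.random() < 0.3 else "TA"
            ref = _mk_locus(rng, tsd=tsd)
            elem = tc_library.entries["TcSim3"]
            j = 60 + len(tsd)
            sample = ref[:j] + elem + tsd + ref[j:]
            scan = scan_insertion_locus(ref, sample, tc_library)
            call, novel = scan.call, scan.novel_segment
            t = len(call.tsd)
            k = call.site + t  # insertion point in both coordinate systems
            assert sample[call.site:k] == call.tsd
            assert sample[k + len(novel):k + len(novel) + t] == call.tsd
            assert sample[k:k + len(novel)] == novel


class TestExcisionFootprint:
    def _setup(self, rng, element):
        ref_less = _mk_locus(rng, flank=80)
        j = 82
        ref_with = ref_less[:j] + element + "TA" + ref_less[j:]
        return ref_less, ref_with, j

    def test_precise_excision_zero_change(self, tc_library, rng):
        elem = tc_library.entries["TcSim1"]
        less, with_el, _ = self._setup(rng, elem)
        ev = detect_excision_footprint(with_el, less, elem)
        assert ev.size == 0 and ev.insert == ""

    def test_lost_flanking_bases_sized_correctly(self, tc_library, rng):
        elem = tc_library.entries["TcSim1"]
        less, with_el, j = self._setup(rng, elem)
        sample = less[:j - 2] + less[j + 2:]  # 4 bp lost around the break
        ev = detect_excision_footprint(with_el, sample, elem)
        assert ev.size == 4 and ev.insert == ""

    def test_element_less_locus_retains_one_tsd(self, tc_library, rng):
        elem = tc_library.entries["TcSim2"]
        less, with_el, j = self._setup(rng, elem)
        got, tsd_pos = element_less_locus(with_el, elem)
        assert got == less
        assert got[tsd_pos:tsd_pos + 2] == "TA"

    def test_simulated_roundtrip_recovers_planted_footprints(self, tc_library):
        genome = simulate_genome(60_000, seed=61)
        sim = simulate_transposon_events(genome, tc_library, n_insertions=0,
                                         n_excisions=80,
                                         footprint_model="tmej", seed=62)
        ok = 0
        for loc in sim.loci:
            elem = tc_library.entries[loc.element]
            ev = detect_excision_footprint(loc.ref_locus, loc.sample_locus,
                                           elem, contig="L")
            less, _ = element_less_locus(loc.ref_locus, elem)
            lg = Genome({"L": less})
            planted = DeletionEvent("L", loc.footprint_start,
                                    loc.footprint_end, loc.footprint_insert)
            if normalize_indel(lg, ev) == normalize_indel(lg, planted):
                ok += 1
        assert ok / len(sim.loci) >= 0.99

    def test_footprint_classification_roundtrip(self, tc_library):
        """Blunt-model footprints must classify as no-homology after the
        detect -> classify round trip."""
        genome = simulate_genome(60_000, seed=63)
        sim = simulate_transposon_events(genome, tc_library, n_insertions=0,
                                         n_excisions=40,
                                         footprint_model="nhej_blunt", seed=64)
        for loc in sim.loci:
            elem = tc_library.entries[loc.element]
            ev = detect_excision_footprint(loc.ref_locus, loc.sample_locus,
                                           elem, contig="L")
            if ev.size == 0 and not ev.insert:
                continue
            less, _ = element_less_locus(loc.ref_locus, elem)
            ann = classify_footprint(Genome({"L": less}), ev)
            assert ann.mh_total == 0 and ann.repair_class.value == "no_homology"


class TestCatalog:
    def _call(self, site, isolate, kind="insertion", contig="chrI"):
        return TransposonCall(contig, site, "TA", kind,
                              ("Tc1",) if kind == "insertion" else (), isolate)

    def test_shared_site_grouped_not_unique(self):
        cat = catalog_unique_sites([self._call(100, "iso1"),
                                    self._call(100, "iso2")])
        assert len(cat.sites) == 1
        row = cat.sites.iloc[0]
        assert row["isolate_count"] == 2 and not row["unique"]
        assert cat.n_unique_insertions == 0

    def test_three_singleton_sites_counted_unique(self):
        cat = catalog_unique_sites([self._call(10, "iso1"),
                                    self._call(300, "iso2"),
                                    self._call(900, "iso1")])
        assert cat.n_unique_insertions == 3
        counts = dict(zip(cat.per_isolate["isolate"],
                          cat.per_isolate["n_unique_insertions"]))
        assert counts == {"iso1": 2, "iso2": 1}

    def test_shared_deletions_excluded_from_catalog(self):
        calls = [self._call(10, "iso1"),
                 self._call(500, "iso1", kind="deletion"),
                 self._call(500, "iso2", kind="deletion"),
                 self._call(700, "iso3", kind="deletion")]
        cat = catalog_unique_sites(calls)
        dels = cat.sites[cat.sites["kind"] == "deletion"]
        assert list(dels["site"]) == [700]
        assert cat.insertion_deletion_ratio == 1.0

    def test_simulated_multi_isolate_truth(self, tc_library):
        genome = simulate_genome(150_000, seed=65)
        sim = simulate_transposon_events(
            genome, tc_library, n_insertions=60, n_excisions=0, seed=66,
            isolates=("isoA", "isoB", "isoC"))
        calls = []
        for loc in sim.loci:
            call = detect_insertion_hallmark(loc.ref_locus, loc.sample_locus,
                                             tc_library, contig=loc.label,
                                             isolate=loc.isolate)
            assert call is not None
            calls.append(call)
        cat = catalog_unique_sites(calls)
        # loci are distinct, so every site is unique to its isolate
        assert cat.n_unique_insertions == len(sim.loci)
        want = sim.truth.groupby("isolate").size().to_dict()
        got = dict(zip(cat.per_isolate["isolate"],
                       cat.per_isolate["n_unique_insertions"]))
        assert got == want
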