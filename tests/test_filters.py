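import numpy as np

from dsbscars import (CoverageProfile, DeletionEvent, Genome,
                      VariantSupportRecord, filter_isolate_deletion,
                      filter_ma_variants, filter_phylo_snvs,
                      filter_shared_transposon_deletions,
                      is_microsatellite_context,
                      simulate_isolate_deletion_table, simulate_variant_table)
from dsbscars.filters import (REASON_COVERAGE, REASON_COVERAGE_DROP,
                              REASON_OTHERS_NOT_NORMAL, REASON_RESIDUAL_REF,
                              REASON_SHARED_IN_GROUP, REASON_STRAND,
                              REASON_SUPPORT, REASON_NOT_UNIQUE,
                              REASON_UNEVALUABLE, REASON_QUALITY,
                              REASON_ALT_FRACTION)
from conftest import microsatellite_oracle

COHORT = {"g": ["a", "b", "c"]}


def _rec(sample="a", fwd=3, rev=3, ref=0, cov=6, pos=100, qual=150.0, **kw):
    return VariantSupportRecord(sample, "g", "chrI", pos, "snv",
                                fwd, rev, ref, cov, qual, **kw)


def _context(pos=100):
    """Reference-supporting evidence for the other cohort samples."""
    return [_rec(s, fwd=0, rev=0, ref=10, cov=10, pos=pos) for s in "bc"]


class TestMaFilter:
    def test_all_clauses_met_accepted(self):
        (d,) = filter_ma_variants([_rec()] + _context(), COHORT)
        assert d.accepted and d.reason == "pass"

    def test_low_coverage_rejected(self):
        (d,) = filter_ma_variants([_rec(fwd=2, rev=2, cov=4)] + _context(), COHORT)
        assert not d.accepted and d.reason == REASON_COVERAGE

    def test_single_strand_rejected(self):
        (d,) = filter_ma_variants([_rec(fwd=10, rev=0, cov=10)] + _context(), COHORT)
        assert not d.accepted and d.reason == REASON_STRAND

    def test_residual_reference_reads_rejected(self):
        (d,) = filter_ma_variants([_rec(ref=1, cov=7)] + _context(), COHORT)
        assert not d.accepted and d.reason == REASON_RESIDUAL_REF

    def test_shared_within_genotype_group_rejected(self):
        sharer = _rec("b", fwd=2, rev=2, cov=5)
        other = _rec("c", fwd=0, rev=0, ref=9, cov=9)
        decisions = filter_ma_variants([_rec(), sharer, other], COHORT)
        mine = next(d for d in decisions if d.record.sample == "a")
        assert not mine.accepted and mine.reason == REASON_SHARED_IN_GROUP

    def test_missing_cohort_evidence_unevaluable(self):
        decisions = filter_ma_variants([_rec()] + _context()[:1], COHORT)
        (d,) = decisions
        assert not d.accepted and d.reason == REASON_UNEVALUABLE

    def test_coverage_on_alt_configuration(self):
        # depth clause read as variant-supporting reads instead of site depth
        rec = _rec(fwd=2, rev=2, cov=10)
        (d,) = filter_ma_variants([rec] + _context(), COHORT, coverage_on_alt=True)
        assert not d.accepted and d.reason == REASON_COVERAGE

    def test_planted_truth_contract(self):
        """Each planted artifact class is rejected for exactly its clause and
        clean calls pass losslessly."""
        records, truth = simulate_variant_table(
            n_true=15, n_false_per_class=6, seed=97)
        cohort = {}
        for r in records:
            cohort.setdefault(r.group, [])
            if r.sample not in cohort[r.group]:
                cohort[r.group].append(r.sample)
        decisions = filter_ma_variants(records, cohort)
        expected = {"clean": "pass", "strand": REASON_STRAND,
                    "lowcov": REASON_COVERAGE,
                    "residual_ref": REASON_RESIDUAL_REF,
                    "shared": REASON_SHARED_IN_GROUP}
        truth_by_pos = truth.set_index("pos")
        for d in decisions:
            cls = truth_by_pos.loc[d.record.pos, "planted_class"]
            assert d.reason == expected[cls], (cls, d)
            assert d.accepted == (cls == "clean")


class TestIsolateDeletionFilter:
    def _case(self, sup=9, ref=0, own_ratio=0.2, n_normal=7, carriers=("iso1",)):
        isolates = [f"iso{i+1}" for i in range(8)]
        prof = CoverageProfile({i: 30.0 for i in isolates})
        interval = ("chrI", 1000, 1400)
        prof.set_interval("iso1", "chrI", 1000, 1400, own_ratio * 30.0)
        for k, iso in enumerate(i for i in isolates if i != "iso1"):
            prof.set_interval(iso, "chrI", 1000, 1400,
                              30.0 if k < n_normal else 9.0)
        rec = VariantSupportRecord("iso1", "nat", "chrI", 1000, "deletion",
                                   sup // 2, sup - sup // 2, ref, sup + ref,
                                   0.0, sup)
        return rec, prof, interval, carriers, isolates

    def test_all_clauses_met_accepted(self):
        rec, prof, interval, carriers, isolates = self._case()
        d = filter_isolate_deletion(rec, prof, interval, carriers, isolates)
        assert d.accepted

    def test_insufficient_supporting_reads(self):
        rec, prof, interval, carriers, isolates = self._case(sup=7)
        d = filter_isolate_deletion(rec, prof, interval, carriers, isolates)
        assert d.reason == REASON_SUPPORT

    def test_coverage_drop_not_deep_enough(self):
        rec, prof, interval, carriers, isolates = self._case(own_ratio=0.5)
        d = filter_isolate_deletion(rec, prof, interval, carriers, isolates)
        assert d.reason == REASON_COVERAGE_DROP

    def test_too_few_normal_isolates(self):
        rec, prof, interval, carriers, isolates = self._case(n_normal=3)
        d = filter_isolate_deletion(rec, prof, interval, carriers, isolates)
        assert d.reason == REASON_OTHERS_NOT_NORMAL

    def test_shared_site_not_unique(self):
        rec, prof, interval, _, isolates = self._case()
        d = filter_isolate_deletion(rec, prof, interval, ("iso1", "iso2"), isolates)
        assert d.reason == REASON_NOT_UNIQUE

    def test_planted_truth_contract(self):
        cases, prof, isolates = simulate_isolate_deletion_table(
            n_per_class=5, seed=33)
        expected = {"clean": "pass", "support": REASON_SUPPORT,
                    "residual_ref": REASON_RESIDUAL_REF,
                    "not_unique": REASON_NOT_UNIQUE,
                    "coverage_drop": REASON_COVERAGE_DROP,
                    "others_not_normal": REASON_OTHERS_NOT_NORMAL}
        for case in cases:
            d = filter_isolate_deletion(case.record, prof, case.interval,
                                        case.carriers, isolates)
            assert d.reason == expected[case.planted_class]
            assert d.accepted == (case.planted_class == "clean")


class TestSharedDeletions:
    def test_multi_isolate_site_excluded(self):
        calls = [("siteA", "iso1"), ("siteA", "iso2"), ("siteB", "iso1")]
        kept = filter_shared_transposon_deletions(
            calls, site_of=lambda c: c[0], isolate_of=lambda c: c[1])
        assert kept == [("siteB", "iso1")]

    def test_empty_input(self):
        assert filter_shared_transposon_deletions([]) == []


class TestPhyloSnvFilter:
    def test_quality_boundary(self):
        (d,) = filter_phylo_snvs([_rec(qual=99.0, fwd=5, rev=4, cov=9)])
        assert d.reason == REASON_QUALITY
        (d,) = filter_phylo_snvs([_rec(qual=100.0, fwd=5, rev=4, cov=9)])
        assert d.accepted

    def test_alt_fraction_strictly_greater_than_80(self):
        (d,) = filter_phylo_snvs([_rec(fwd=4, rev=4, cov=10)])  # exactly 80%
        assert d.reason == REASON_ALT_FRACTION
        (d,) = filter_phylo_snvs([_rec(fwd=5, rev=4, cov=10)])  # 90%
        assert d.accepted

    def test_depth_and_strand_clauses(self):
        (d,) = filter_phylo_snvs([_rec(fwd=2, rev=2, cov=4)])
        assert d.reason == REASON_COVERAGE
        (d,) = filter_phylo_snvs([_rec(fwd=9, rev=0, cov=9)])
        assert d.reason == REASON_STRAND

    def test_filters_return_subset_and_idempotent(self):
        records, _ = simulate_variant_table(n_true=10, n_false_per_class=3,
                                            seed=55)
        snvs = [r for r in records if r.alt_support > 0]
        acc1 = [d.record for d in filter_phylo_snvs(snvs) if d.accepted]
        assert set(id(r) for r in acc1) <= set(id(r) for r in snvs)
        acc2 = [d.record for d in filter_phylo_snvs(acc1) if d.accepted]
        assert acc2 == acc1


class TestMicrosatelliteContext:
    def test_deletion_inside_homopolymer(self):
        g = Genome({"c": "GGCC" + "A" * 10 + "GGCC"})
        assert is_microsatellite_context(g, DeletionEvent("c", 6, 7))

    def test_nonrepetitive_deletion_clean(self, worm_genome):
        contig = worm_genome.contigs[0]
        # a fixed, verified non-repetitive site: check many and demand the
        # large majority clean (worm-like sequence has occasional short tracts)
        rng = np.random.default_rng(8)
        flags = []
        for _ in range(200):
            s = int(rng.integers(1000, 90_000))
            flags.append(is_microsatellite_context(
                worm_genome, DeletionEvent(contig, s, s + 50)))
        assert np.mean(flags) < 0.5

    def test_agrees_with_bruteforce_scan(self, rng):
        for _ in range(60):
            seq = "".join(rng.choice(list("ACGT"), p=[.35, .15, .15, .35],
                                     size=200))
            g = Genome({"c": seq})
            s = int(rng.integers(10, 180))
            e = s + int(rng.integers(1, 15))
            e = min(e, 199)
            ev = DeletionEvent("c", s, e)
            from dsbscars import canonicalize
            c = canonicalize(g, ev)
            got = is_microsatellite_context(g, ev)
            want = microsatellite_oracle(seq, {c.start, c.end})
            assert got == want, (seq, s, e)
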