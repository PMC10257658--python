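"""Site-variant intersection, hit classification, on-target
confirmation and the three-way site-set comparison."""

import random

import pytest

from otaudit.audit import (
    attribution_scores,
    classify_hit,
    classify_hits,
    compare_site_sets,
    confirm_on_target,
    intersect_sites_variants,
    summarize_hits,
)
from otaudit.formats import Annotation, Genome, Guide, Interval
from otaudit.search import OfftargetSite
from test_filters import mksv, mkvar


def mksite(guide_id="g1", contig="chr1", start=1000, mismatches=2, strand="+",
           pam_class="NGG", on_target=False, bulge="none"):
    return OfftargetSite(
        guide_id=guide_id,
        contig=contig,
        strand=strand,
        site_interval=Interval(contig, start, start + 23),
        aligned_target="A" * (20 if bulge != "DNA" else 21),
        mismatches=mismatches,
        bulge_type=bulge,
        bulge_size=0 if bulge == "none" else 1,
        pam_seq="AGG" if pam_class == "NGG" else "AAG",
        pam_class=pam_class,
        is_on_target=on_target,
    )


class TestIntersection:
    def test_indel_at_cut_position_hits(self):
        site = mksite(start=1000)
        v = mkvar(sample="F1", pos=1018, ref="ATTT", alt="A")
        hits = intersect_sites_variants({"g1": [site]}, {"F1": ["g1"]},
                                        {"F1": [v]})
        assert len(hits) == 1
        assert hits[0].variant_class == "indel"
        assert hits[0].mismatch_bin == "<=4"

    def test_half_open_boundary_misses(self):
        site = mksite(start=1000)  # site spans [1000, 1023)
        v = mkvar(sample="F1", pos=1024, ref="A", alt="T")  # 0-based [1023,1024)
        hits = intersect_sites_variants({"g1": [site]}, {"F1": ["g1"]},
                                        {"F1": [v]})
        assert hits == []

    def test_scoped_to_own_guides(self):
        site = mksite(guide_id="g2")
        v = mkvar(sample="F1", pos=1010)
        hits = intersect_sites_variants({"g2": [site]}, {"F1": ["g1"]},
                                        {"F1": [v]})
        assert hits == []

    def test_on_target_sites_excluded(self):
        site = mksite(on_target=True, mismatches=0)
        v = mkvar(sample="F1", pos=1010)
        assert intersect_sites_variants({"g1": [site]}, {"F1": ["g1"]},
                                        {"F1": [v]}) == []

    def test_sv_del_and_small_del_deduplicated(self):
        site = mksite(start=1000)
        small = mkvar(sample="F1", pos=1010, ref="ATTTT", alt="A")
        sv = mksv(sample="F1", start=1005, end=1600)  # contains the small del
        hits = intersect_sites_variants({"g1": [site]}, {"F1": ["g1"]},
                                        {"F1": [small]}, {"F1": [sv]})
        assert len(hits) == 1 and hits[0].variant_class == "SV:del"

    def test_unknown_contig_rejected(self):
        genome = Genome({"chr1": "ACGT" * 10})
        site = mksite(contig="chrZ")
        v = mkvar(sample="F1", contig="chrZ", pos=1010)
        with pytest.raises(ValueError, match="absent"):
            intersect_sites_variants({"g1": [site]}, {"F1": ["g1"]},
                                     {"F1": [v]}, genome=genome)

    def test_injected_edits_attributed(self, small_cohort, small_run):
        truth = small_cohort.truth.edits_frame()
        expected = truth[truth.expected_recovered]
        scores = attribution_scores(
            small_run["hits"],
            expected.to_dict("records"),
        )
        assert scores["recall"] == 1.0


@pytest.fixture(scope="module")
def annotation():
    genes = [Interval("chr1", 1000, 5000, "geneA")]
    exons = [Interval("chr1", 1200, 1400, "e1"), Interval("chr1", 3000, 3200, "e2")]
    return Annotation(exons, genes)


class TestClassification:
    def test_exonic_intronic_intergenic(self, annotation):
        site = mksite()
        for pos, expected in [(1250, "exonic"), (2000, "intronic"), (8000, "intergenic")]:
            hit = intersect_sites_variants(
                {"g1": [mksite(start=pos - 10)]}, {"F1": ["g1"]},
                {"F1": [mkvar(sample="F1", pos=pos)]}
            )[0]
            assert classify_hit(hit, annotation).genic_context == expected

    def test_against_per_base_oracle(self, annotation):
        rng = random.Random(6)
        exonic = set()
        for iv in annotation.exon_intervals:
            exonic.update(range(iv.start, iv.end))
        genic = set()
        for iv in annotation.gene_body_intervals:
            genic.update(range(iv.start, iv.end))
        for _ in range(50):
            pos0 = rng.randrange(0, 10_000)
            iv = Interval("chr1", pos0, pos0 + 1)
            got = annotation.classify(iv)
            want = ("exonic" if pos0 in exonic
                    else "intronic" if pos0 in genic else "intergenic")
            assert got == want


class TestSummaries:
    def test_empty_hit_list(self):
        out = summarize_hits([], 6)
        assert out["n_hits"] == 0 and out["table"].empty

    def test_hand_built_crosstab(self, annotation):
        hits = []
        for i in range(3):
            hits.append(intersect_sites_variants(
                {"g1": [mksite(start=2000 + 40 * i, mismatches=3)]}, {"F1": ["g1"]},
                {"F1": [mkvar(sample="F1", pos=2010 + 40 * i, ref="AT", alt="A")]}
            )[0])
        for i in range(2):
            hits.append(intersect_sites_variants(
                {"g1": [mksite(start=4000 + 40 * i, mismatches=5, pam_class="NAG")]},
                {"F1": ["g1"]},
                {"F1": [mkvar(sample="F1", pos=4010 + 40 * i)]}
            )[0])
        hits = classify_hits(hits, annotation)
        table = summarize_hits(hits, 6)["table"]
        lookup = {(r.variant_class, r.pam_class, r.mismatch_bin): r.count
                  for r in table.itertuples()}
        assert lookup == {("indel", "NGG", "<=4"): 3, ("SNV", "NAG", "5"): 2}

    @pytest.mark.parametrize("ceiling", [4, 5, 6])
    def test_marginals_conserved(self, annotation, ceiling):
        rng = random.Random(2)
        hits = []
        for i in range(12):
            mm = rng.randrange(0, 7)
            hits.append(intersect_sites_variants(
                {"g1": [mksite(start=1000 + 30 * i, mismatches=mm)]}, {"F1": ["g1"]},
                {"F1": [mkvar(sample="F1", pos=1010 + 30 * i)]}
            )[0])
        out = summarize_hits(classify_hits(hits, annotation), ceiling)
        assert out["table"]["count"].sum() == out["n_hits"]
        assert out["n_hits"] == sum(1 for h in hits if h.site.mismatches <= ceiling)

    def test_hit_counts_monotone_in_ceiling(self, default_run):
        ns = [default_run["hit_summaries"][c]["n_hits"] for c in (4, 5, 6)]
        assert ns == sorted(ns)


class TestOnTarget:
    def _setup(self, n_callers):
        rng = random.Random(9)
        protoA = "".join(rng.choice("ACGT") for _ in range(20))
        protoB = "".join(rng.choice("ACGT") for _ in range(20))
        gA, gB = Guide("gA", protoA), Guide("gB", protoB)
        siteA = mksite(guide_id="gA", start=1000, mismatches=0, on_target=True)
        siteB = mksite(guide_id="gB", start=2000, mismatches=0, on_target=True)
        callers = ["lumpy", "manta", "wham"][:n_callers]
        sv = mksv(sample="F1", start=1010, end=2010, callers=tuple(callers))
        return [gA, gB], {"gA": siteA, "gB": siteB}, [sv]

    def test_two_caller_deletion_confirmed(self):
        guides, on_sites, svs = self._setup(2)
        call = confirm_on_target("F1", guides, on_sites, svs, [])
        assert call.confirmed and call.n_supporting_callers == 2

    def test_single_caller_not_confirmed(self):
        """Mirrors a deletion seen by one program only: consensus fails."""
        guides, on_sites, svs = self._setup(1)
        call = confirm_on_target("F1", guides, on_sites, svs, [])
        assert not call.confirmed

    def test_small_deletion_covering_half_confirms(self):
        guides, on_sites, _ = self._setup(2)
        big_del = mkvar(sample="F1", pos=1100, ref="A" * 600, alt="A")
        call = confirm_on_target("F1", guides, on_sites, [], [big_del])
        assert call.confirmed

    def test_fewer_than_two_guides_rejected(self):
        guides, on_sites, svs = self._setup(2)
        with pytest.raises(ValueError, match="2 flanking guides"):
            confirm_on_target("F1", guides[:1], on_sites, svs, [])


class TestSiteSetComparison:
    def test_identical_singletons(self):
        s = mksite()
        assert compare_site_sets([s], [s], [s])["ABC"] == 1

    def test_disjoint_singletons(self):
        a, b, c = (mksite(start=p) for p in (1000, 2000, 3000))
        counts = compare_site_sets([a], [b], [c])
        assert (counts["A"], counts["B"], counts["C"]) == (1, 1, 1)
        assert counts["ABC"] == 0

    def test_tolerance_window(self):
        a = mksite(start=1000)
        b = mksite(start=1030)  # separated by 7 bases < 10 tolerance
        counts = compare_site_sets([a], [b], [], tolerance=10)
        assert counts["AB"] == 1
        counts = compare_site_sets([a], [b], [], tolerance=3)
        assert counts["A"] == 1 and counts["B"] == 1

    def test_against_quadratic_oracle(self):
        rng = random.Random(13)

        def rand_sites(n):
            return [mksite(start=rng.randrange(0, 4000),
                           contig=rng.choice(["chr1", "chr2"])) for _ in range(n)]

        A, B, C = rand_sites(15), rand_sites(12), rand_sites(10)
        got = compare_site_sets(A, B, C, tolerance=10)

        # brute force: all-pairs matching, then connected components
        labelled = [("A", s) for s in A] + [("B", s) for s in B] + [("C", s) for s in C]
        n = len(labelled)
        adj = {i: set() for i in range(n)}
        for i in range(n):
            for j in range(i + 1, n):
                si, sj = labelled[i][1], labelled[j][1]
                if si.contig == sj.contig and (
                    max(si.site_interval.start, sj.site_interval.start)
                    - min(si.site_interval.end, sj.site_interval.end) <= 10
                ):
                    adj[i].add(j)
                    adj[j].add(i)
        seen, want = set(), {k: 0 for k in ("A", "B", "C", "AB", "AC", "BC", "ABC")}
        for i in range(n):
            if i in seen:
                continue
            stack, comp = [i], set()
            while stack:
                x = stack.pop()
                if x in comp:
                    continue
                comp.add(x)
                stack.extend(adj[x] - comp)
            seen |= comp
            labels = "".join(sorted({labelled[x][0] for x in comp}))
            want[labels] += 1
        assert got == want
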