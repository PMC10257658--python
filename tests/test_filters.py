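"""Filter cascade: strict thresholds, repeat padding, known-variant and
shared-variant removal, callable intersection, SV consensus."""

import random

import pytest

from otaudit.filters import (
    FilterConfig,
    callable_intersection,
    filter_callable,
    known_variant_set,
    primary_filter,
    secondary_filter,
    sv_consensus_filter,
)
from otaudit.formats import Interval, SVRecord, VariantRecord


def mkvar(sample="S1", contig="chr1", pos=500, ref="A", alt="T", genotype="het",
          qual=200.0, depth=30, gq=80.0, ad_alt=None, ad_ref=None):
    if ad_alt is None:
        ad_alt = depth // 2
    if ad_ref is None:
        ad_ref = depth - ad_alt
    af = ad_alt / (ad_ref + ad_alt)
    vtype = "SNV" if len(ref) == 1 and len(alt) == 1 else "indel"
    return VariantRecord(sample, contig, pos, ref, alt, vtype, genotype,
                         qual, depth, gq, af, ad_ref, ad_alt)


def mksv(sample="S1", contig="chr1", start=1000, end=2000, svtype="DEL",
         callers=("lumpy", "manta"), su=5, genotype="het", length=None):
    if length is None:
        length = end - start + 1
    return SVRecord(sample, contig, start, end, svtype, frozenset(callers),
                    su, length, genotype)


class TestPrimaryQuality:
    def test_boundary_passing_values_retained(self):
        v = mkvar(qual=31, depth=10, gq=31, ad_alt=2, ad_ref=8)  # af=0.2
        out, rep = primary_filter({"S1": [v]}, set(), [], FilterConfig())
        assert out["S1"] == [v]

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(qual=30.0),                      # QUAL must be > 30
            dict(depth=9, ad_alt=4, ad_ref=5),    # DP must be > 9
            dict(gq=30.0),                        # GQ must be > 30
            dict(ad_alt=1, ad_ref=9),             # AF must be > 0.1 (af=0.1)
        ],
    )
    def test_boundary_failing_values_removed(self, kwargs):
        v = mkvar(**kwargs)
        out, rep = primary_filter({"S1": [v]}, set(), [], FilterConfig())
        assert out["S1"] == []
        assert rep.totals("quality") == (1, 1, 0)


class TestPrimaryRepeats:
    def test_padding_reaches_adjacent_variant(self):
        # repeat [100,110) padded by 2 covers [98,112); variant at [110,111)
        v = mkvar(pos=111, ref="A", alt="T")
        out, _ = primary_filter({"S1": [v]}, set(), [Interval("chr1", 100, 110)],
                                FilterConfig())
        assert out["S1"] == []

    def test_beyond_pad_retained(self):
        v = mkvar(pos=113, ref="A", alt="T")  # 0-based [112,113): outside pad
        out, _ = primary_filter({"S1": [v]}, set(), [Interval("chr1", 100, 110)],
                                FilterConfig())
        assert out["S1"] == [v]


class TestPrimaryKnownAndHet:
    def test_known_truth_table(self):
        rng = random.Random(3)
        cohort = {}
        known_records = []
        planted_known = set()
        for si, s in enumerate(("A", "B", "C")):
            recs = []
            for i in range(20):
                pos = 100 + 50 * i + 12 * si + rng.randrange(10)
                v = mkvar(sample=s, pos=pos, alt="G")
                recs.append(v)
            cohort[s] = recs
        for s in ("A", "B", "C"):
            for v in cohort[s][:5] if s == "A" else []:
                known_records.append(v)
                planted_known.add((v.contig, v.pos, v.ref, v.alt))
        out, rep = primary_filter(cohort, known_variant_set(known_records), [],
                                  FilterConfig())
        removed = {(v.contig, v.pos, v.ref, v.alt)
                   for v in cohort["A"] if v not in out["A"]}
        assert removed == planted_known
        assert len(out["B"]) == 20 and len(out["C"]) == 20

    def test_low_het_ratio_excluded(self):
        bad = mkvar(ad_alt=3, ad_ref=27)   # ratio 0.1 < 0.2 but af>... af==0.1 fails quality
        # make quality pass but het-ratio fail: ratio 0.15
        bad = mkvar(depth=40, ad_alt=6, ad_ref=34)  # af/ratio = 0.15
        good = mkvar(pos=900, depth=40, ad_alt=12, ad_ref=28)
        out, rep = primary_filter({"S1": [bad, good]}, set(), [], FilterConfig())
        assert out["S1"] == [good]
        assert rep.totals("het_ratio") == (2, 1, 1)

    def test_hom_alt_exempt_from_het_ratio(self):
        v = mkvar(genotype="hom_alt", depth=40, ad_alt=6, ad_ref=34)
        out, _ = primary_filter({"S1": [v]}, set(), [], FilterConfig())
        assert out["S1"] == [v]

    def test_known_and_repeat_stages_commute(self):
        rng = random.Random(5)
        recs = [mkvar(pos=100 + 17 * i, alt="G") for i in range(40)]
        repeats = [Interval("chr1", 200, 260)]
        known = {("chr1", v.pos, v.ref, v.alt) for v in rng.sample(recs, 8)}
        out1, _ = primary_filter({"S": recs}, known, repeats, FilterConfig())
        # swapped order: remove known first by pre-stripping, then repeats
        pre = [v for v in recs if ("chr1", v.pos, v.ref, v.alt) not in known]
        out2, _ = primary_filter({"S": pre}, set(), repeats, FilterConfig())
        assert out1["S"] == out2["S"]


class TestCallable:
    def test_idempotent_on_identical_sets(self):
        ivs = [Interval("chr1", 0, 100), Interval("chr1", 200, 300)]
        assert callable_intersection([ivs, list(ivs)]) == ivs

    def test_pairwise_overlap(self):
        a = [Interval("chr1", 0, 100)]
        b = [Interval("chr1", 50, 150)]
        assert callable_intersection([a, b]) == [Interval("chr1", 50, 100)]

    def test_empty_sample_empties_intersection(self):
        assert callable_intersection([[Interval("chr1", 0, 10)], []]) == []

    def test_against_per_base_oracle(self):
        rng = random.Random(12)
        L = 1000
        sets = []
        for _ in range(5):
            ivs = []
            for _ in range(rng.randrange(3, 9)):
                s = rng.randrange(0, L - 20)
                ivs.append(Interval("chr1", s, s + rng.randrange(5, 120)))
            sets.append(ivs)
        inter = callable_intersection(sets)
        covered = set()
        for iv in inter:
            covered.update(range(iv.start, iv.end))
        expected = set(range(L))
        for ivs in sets:
            member = set()
            for iv in ivs:
                member.update(range(iv.start, iv.end))
            expected &= member
        assert covered == expected

    def test_variant_must_be_fully_inside(self):
        inter = [Interval("chr1", 100, 200)]
        inside = mkvar(pos=150, ref="ATTT", alt="A")
        straddles = mkvar(pos=198, ref="ATTT", alt="A")
        out = filter_callable({"S": [inside, straddles]}, inter)
        assert out["S"] == [inside]


class TestSecondary:
    def test_shared_across_two_samples_removed_from_both(self):
        a = mkvar(sample="A")
        b = mkvar(sample="B")
        out, shared = secondary_filter({"A": [a], "B": [b]})
        assert out == {"A": [], "B": []}
        assert len(shared) == 1

    def test_duplicate_within_one_sample_retained(self):
        a1 = mkvar(sample="A")
        a2 = mkvar(sample="A")  # same tuple, same sample (split multiallelic)
        out, shared = secondary_filter({"A": [a1, a2], "B": []})
        assert len(out["A"]) == 2 and not shared

    def test_cohort_truth_table(self, small_cohort):
        """Planted substrain-shared variants vanish; private survive."""
        out, shared = secondary_filter(small_cohort.variants,
                                       genome=small_cohort.genome)
        bg = small_cohort.truth.background_frame()
        shared_truth = bg[bg.category == "shared_substrain"]
        private_truth = bg[bg.category.isin(["private", "de_novo"])]
        final_keys = {
            s: {(v.contig, v.pos, v.ref, v.alt) for v in recs}
            for s, recs in out.items()
        }
        for t in shared_truth.itertuples():
            assert (t.contig, t.pos, t.ref, t.alt) not in final_keys[t.sample_id]
        for t in private_truth.itertuples():
            assert (t.contig, t.pos, t.ref, t.alt) in final_keys[t.sample_id]


class TestSvConsensus:
    def test_passing_record_retained(self):
        sv = mksv(length=1000, su=3)
        out, rep = sv_consensus_filter({"S1": [sv]})
        assert out["S1"] == [sv]

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(callers=("lumpy",), su=10, length=1000),   # caller floor
            dict(su=2, length=1000),                        # read floor
            dict(length=200),                               # strict > 200
            dict(length=5000),                              # strict < 5000
            dict(genotype="missing", length=1000),
            dict(genotype="hom_ref", length=1000),
        ],
    )
    def test_failing_records_removed(self, kwargs):
        sv = mksv(**kwargs)
        out, _ = sv_consensus_filter({"S1": [sv]})
        assert out["S1"] == []

    def test_no_caller_annotation_removed(self):
        sv = SVRecord("S1", "chr1", 1000, 2000, "DEL", frozenset(), 5, 1001, "het")
        out, _ = sv_consensus_filter({"S1": [sv]})
        assert out["S1"] == []

    def test_shared_breakpoint_pair_removed_across_samples(self):
        a = mksv(sample="A", start=1000, end=2000)
        b = mksv(sample="B", start=1050, end=1960)  # both ends within 100 bp
        c = mksv(sample="C", start=5000, end=6000)
        out, rep = sv_consensus_filter({"A": [a], "B": [b], "C": [c]})
        assert out["A"] == [] and out["B"] == [] and out["C"] == [c]

    def test_different_type_not_matched(self):
        a = mksv(sample="A", start=1000, end=2000, svtype="DEL")
        b = mksv(sample="B", start=1000, end=2000, svtype="DUP")
        out, _ = sv_consensus_filter({"A": [a], "B": [b]})
        assert out["A"] == [a] and out["B"] == [b]


class TestReportInvariants:
    def test_counts_reconcile_and_stages_ordered(self, small_cohort):
        cfg = FilterConfig()
        out, rep = primary_filter(small_cohort.variants, small_cohort.known,
                                  small_cohort.repeats, cfg, small_cohort.genome)
        df = rep.to_dataframe()
        assert (df.n_in - df.n_removed == df.n_out).all()
        assert rep.stage_order == ["quality", "repeats", "known", "het_ratio"]
        # anti-monotone pipeline: per-sample chain of outputs
        for sample in small_cohort.variants:
            rows = df[df["sample"] == sample]
            n_in = list(rows.n_in)
            n_out = list(rows.n_out)
            assert n_in[1:] == n_out[:-1]
            assert n_in[0] == len(small_cohort.variants[sample])
            assert n_out[-1] == len(out[sample])
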