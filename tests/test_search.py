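"""Off-target site enumeration: planted cases, the brute-force oracle,
and the search invariants (monotonicity, strand symmetry, recovery)."""

import random

import pytest

from otaudit.formats import Genome, Guide, PAM_NGG_NAG, PAM_NGG_ONLY, revcomp
from otaudit.search import (
    SearchConfig,
    cut_site,
    enumerate_sites,
    mismatch_position_profile,
    oracle_enumerate,
    read_sites,
    write_sites,
)
from conftest import plant, random_genome, random_guide


def _mutate_at(proto: str, positions, rng) -> str:
    chars = list(proto)
    for p in positions:
        chars[p] = rng.choice([b for b in "ACGT" if b != chars[p]])
    return "".join(chars)


@pytest.fixture
def planted():
    rng = random.Random(11)
    guide = random_guide(rng)
    seq = "".join(rng.choice("ACGT") for _ in range(1500))
    seq = plant(seq, 400, guide.protospacer + "TGG")
    return rng, guide, seq


class TestPlantedCases:
    def test_exact_match_found_once(self, planted):
        rng, guide, seq = planted
        sites = enumerate_sites(
            guide, Genome({"chr1": seq}),
            SearchConfig(max_mismatches=0, allow_bulge=False, pam_rule=PAM_NGG_ONLY),
        )
        assert len(sites) == 1
        (s,) = sites
        assert (s.mismatches, s.pam_class, s.is_on_target) == (0, "NGG", True)
        assert (s.site_interval.start, s.site_interval.end) == (400, 423)

    def test_mismatch_ceiling_excludes(self, planted):
        rng, guide, seq = planted
        decoy = _mutate_at(guide.protospacer, [7], rng)
        seq = plant(seq, 900, decoy + "AGG")
        sites = enumerate_sites(
            guide, Genome({"chr1": seq}),
            SearchConfig(max_mismatches=0, allow_bulge=False, pam_rule=PAM_NGG_ONLY),
        )
        assert len(sites) == 1 and sites[0].is_on_target

    @pytest.mark.parametrize("d", [1, 2, 3, 4, 5, 6])
    def test_planted_recovery_at_distance(self, d):
        """Any planted locus with d substitutions and a valid PAM is
        found with mismatches == d."""
        rng = random.Random(100 + d)
        guide = random_guide(rng)
        decoy = _mutate_at(guide.protospacer, rng.sample(range(20), d), rng)
        seq = "".join(rng.choice("ACGT") for _ in range(1200))
        seq = plant(seq, 600, decoy + "CGG")
        sites = enumerate_sites(
            guide, Genome({"chr1": seq}), SearchConfig(max_mismatches=6)
        )
        match = [s for s in sites if s.site_interval.start == 600 and s.strand == "+"]
        assert match and match[0].mismatches == d

    def test_n_in_window_skipped(self, planted):
        rng, guide, seq = planted
        seq = seq[:405] + "N" + seq[406:]  # N inside the planted protospacer
        sites = enumerate_sites(
            guide, Genome({"chr1": seq}),
            SearchConfig(max_mismatches=6, allow_bulge=False, pam_rule=PAM_NGG_ONLY),
        )
        assert all(s.site_interval.start != 400 for s in sites)

    def test_empty_contig(self):
        guide = random_guide(random.Random(1))
        assert oracle_enumerate(guide, Genome({"chr1": "ACGT"}), SearchConfig()) == []
        assert enumerate_sites(guide, Genome({"chr1": "ACGT"}), SearchConfig()) == []


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(1, 13))
    def test_random_pairs(self, seed):
        rng = random.Random(seed)
        guide = random_guide(rng)
        genome = random_genome(rng, rng.randrange(500, 2000))
        if seed % 2 == 0:  # half the trials plant a near-exact locus
            decoy = _mutate_at(guide.protospacer, rng.sample(range(20), seed % 4), rng)
            seq = plant(genome.sequences["chr1"], 200, decoy + "AGG")
            genome = Genome({"chr1": seq})
        cfg = SearchConfig(
            max_mismatches=seed % 7,
            allow_bulge=bool(seed % 2),
            pam_rule=PAM_NGG_NAG if seed % 3 else PAM_NGG_ONLY,
        )
        assert enumerate_sites(guide, genome, cfg) == oracle_enumerate(guide, genome, cfg)

    def test_oracle_refuses_large_genome(self):
        guide = random_guide(random.Random(3))
        genome = Genome({"chr1": "A" * 150_000})
        with pytest.raises(ValueError, match="100 kb"):
            oracle_enumerate(guide, genome, SearchConfig())


class TestInvariants:
    def test_mismatch_monotonicity_and_pam_subset(self):
        rng = random.Random(42)
        guide = random_guide(rng)
        genome = random_genome(rng, 3000)
        prev: set = set()
        for k in range(0, 7):
            cur = {
                (s.contig, s.strand, s.site_interval.start, s.site_interval.end)
                for s in enumerate_sites(guide, genome, SearchConfig(max_mismatches=k))
            }
            assert prev <= cur
            prev = cur
        ngg = {
            (s.strand, s.site_interval.start)
            for s in enumerate_sites(
                guide, genome, SearchConfig(max_mismatches=6, pam_rule=PAM_NGG_ONLY)
            )
        }
        nrg = {
            (s.strand, s.site_interval.start)
            for s in enumerate_sites(
                guide, genome, SearchConfig(max_mismatches=6, pam_rule=PAM_NGG_NAG)
            )
        }
        assert ngg <= nrg

    def test_strand_symmetry(self):
        """Reverse-complementing the genome mirrors the site set."""
        rng = random.Random(17)
        guide = random_guide(rng)
        genome = random_genome(rng, 2000)
        L = 2000
        cfg = SearchConfig(max_mismatches=4)
        fwd = enumerate_sites(guide, genome, cfg)
        rc = enumerate_sites(
            guide, Genome({"chr1": revcomp(genome.sequences["chr1"])}), cfg
        )
        flip = {"+": "-", "-": "+"}
        mirrored = {
            (flip[s.strand], L - s.site_interval.end, L - s.site_interval.start,
             s.mismatches, s.bulge_type)
            for s in rc
        }
        original = {
            (s.strand, s.site_interval.start, s.site_interval.end,
             s.mismatches, s.bulge_type)
            for s in fwd
        }
        assert mirrored == original


class TestCutSite:
    def test_plus_strand_offset(self):
        rng = random.Random(5)
        guide = random_guide(rng)
        seq = plant("".join(rng.choice("ACGT") for _ in range(400)),
                    100, guide.protospacer + "AGG")
        (s,) = [x for x in enumerate_sites(guide, Genome({"chr1": seq}),
                SearchConfig(max_mismatches=0, pam_rule=PAM_NGG_ONLY)) if x.is_on_target]
        # PAM starts at 0-based 120 -> cut between protospacer 17 and 18
        assert cut_site(s, guide) == 117

    def test_minus_strand_mirror(self):
        rng = random.Random(5)
        guide = random_guide(rng)
        seq = plant("".join(rng.choice("ACGT") for _ in range(400)),
                    100, revcomp(guide.protospacer + "AGG"))
        (s,) = [x for x in enumerate_sites(guide, Genome({"chr1": seq}),
                SearchConfig(max_mismatches=0, pam_rule=PAM_NGG_ONLY)) if x.is_on_target]
        assert s.strand == "-"
        # PAM occupies [100,103); cut is 3 bases into the protospacer side
        assert cut_site(s, guide) == 106

    def test_random_planted_geometry(self):
        rng = random.Random(23)
        for trial in range(10):
            guide = random_guide(rng)
            pos = rng.randrange(50, 300)
            seq = plant("".join(rng.choice("ACGT") for _ in range(500)),
                        pos, guide.protospacer + "TGG")
            hits = [x for x in enumerate_sites(guide, Genome({"chr1": seq}),
                    SearchConfig(max_mismatches=0, pam_rule=PAM_NGG_ONLY)) if x.is_on_target]
            assert hits and cut_site(hits[0], guide) == pos + 17


class TestProfile:
    def test_zero_profile(self, planted):
        rng, guide, seq = planted
        sites = enumerate_sites(guide, Genome({"chr1": seq}),
                                SearchConfig(max_mismatches=0, pam_rule=PAM_NGG_ONLY))
        prof = mismatch_position_profile(sites)
        assert all(prof[i] == 0 for i in range(1, 21)) and prof["gap"] == 0

    def test_distal_mismatch_counted_at_position_1(self):
        rng = random.Random(31)
        guide = random_guide(rng)
        decoy = _mutate_at(guide.protospacer, [0], rng)  # PAM-distal end
        seq = plant("".join(rng.choice("ACGT") for _ in range(600)),
                    300, decoy + "AGG")
        sites = [s for s in enumerate_sites(guide, Genome({"chr1": seq}),
                 SearchConfig(max_mismatches=1, allow_bulge=False))
                 if s.site_interval.start == 300]
        prof = mismatch_position_profile(sites)
        assert prof[1] == 1 and sum(prof[i] for i in range(2, 21)) == 0

    def test_profile_conserves_total_mismatches(self):
        rng = random.Random(8)
        guide = random_guide(rng)
        genome = random_genome(rng, 2000)
        sites = oracle_enumerate(guide, genome, SearchConfig(max_mismatches=6))
        prof = mismatch_position_profile(sites)
        assert sum(prof[i] for i in range(1, 21)) == sum(s.mismatches for s in sites)


def test_site_table_roundtrip(tmp_path):
    rng = random.Random(19)
    guide = random_guide(rng)
    genome = random_genome(rng, 2000)
    sites = enumerate_sites(guide, genome, SearchConfig(max_mismatches=6))
    write_sites(sites, tmp_path / "sites.tsv")
    back = read_sites(tmp_path / "sites.tsv")
    assert [(s.contig, s.site_interval.start, s.mismatches) for s in back] == [
        (s.contig, s.site_interval.start, s.mismatches) for s in sites
    ]
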