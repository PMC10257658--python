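"""Shared fixtures: generated genomes/cohorts and toy VCF builders.

All fixtures are generated programmatically at test time; the default
cohort (28 controls + 50 founders on 3 x 300 kb) is session-scoped
because its site enumeration dominates suite runtime.
"""

from __future__ import annotations

import random

import pytest

from otaudit.cohort import CohortConfig, generate_cohort
from otaudit.formats import Genome, Guide
from otaudit.pipeline import run_pipeline


@pytest.fixture(scope="session")
def default_cohort():
    """The full-scale synthetic study under default conditions."""
    return generate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def default_run(default_cohort):
    """One end-to-end audit of the default cohort (site lists reused
    from generation; they were produced by the same enumerator)."""
    return run_pipeline(default_cohort)


@pytest.fixture(scope="session")
def small_cohort():
    """A fast cohort for integration tests."""
    return generate_cohort(
        CohortConfig(
            seed=2,
            n_controls=5,
            n_founders=6,
            snv_mean=100.0,
            indel_mean=35.0,
            n_ancestral=50,
            shared_per_substrain=15,
        )
    )


@pytest.fixture(scope="session")
def small_run(small_cohort):
    return run_pipeline(small_cohort)


def random_genome(rng: random.Random, length: int, name: str = "chr1") -> Genome:
    return Genome({name: "".join(rng.choice("ACGT") for _ in range(length))})


def random_guide(rng: random.Random, guide_id: str = "g1") -> Guide:
    return Guide(guide_id, "".join(rng.choice("ACGT") for _ in range(20)))


def plant(seq: str, pos: int, insert: str) -> str:
    return seq[:pos] + insert + seq[pos + len(insert):]


@pytest.fixture
def toy_vcf(tmp_path):
    """Write a small single-sample VCF from row tuples
    (contig, pos, ref, alts, gt, dp, gq, ad)."""

    def _write(rows, sample="S1", contigs=(("chr1", 100000), ("chr2", 100000))):
        path = tmp_path / "toy.vcf"
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            for name, length in contigs:
                fh.write(f"##contig=<ID={name},length={length}>\n")
            fh.write(
                '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
                '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="DP">\n'
                '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="GQ">\n'
                '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="AD">\n'
                f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n"
            )
            for contig, pos, ref, alts, gt, dp, gq, ad in rows:
                fh.write(
                    f"{contig}\t{pos}\t.\t{ref}\t{alts}\t50\t.\t.\t"
                    f"GT:DP:GQ:AD\t{gt}:{dp}:{gq}:{ad}\n"
                )
        return path

    return _write
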