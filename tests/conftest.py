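import numpy as np
import pytest

from ampliskip.gene_model import derive_isoform, locate_snv
from ampliskip.synthetic_data import (
    AlleleSpec,
    ErrorModel,
    generate_synthetic_gene,
    simulate_sample,
)

MODEL_SEED = 7

# Patient-1-like study conditions: splice allele carries c.823C in cis with
# the splice variant and skips exons 5+6 in 85.3% of its transcripts; the
# trans allele (c.823T) never skips; allele shares 36.4% / 63.6%.
PATIENT1_SPLICE_SHARE = 0.364
PATIENT1_SPLICE_SKIP56 = 0.853


def patient1_alleles() -> list[AlleleSpec]:
    return [
        AlleleSpec(
            "splice_allele",
            {823: "C"},
            {"full": 1 - PATIENT1_SPLICE_SKIP56, "skip56": PATIENT1_SPLICE_SKIP56},
            PATIENT1_SPLICE_SHARE,
        ),
        AlleleSpec("trans_allele", {823: "T"}, {"full": 1.0}, 1 - PATIENT1_SPLICE_SHARE),
    ]


@pytest.fixture(scope="session")
def model():
    return generate_synthetic_gene(seed=MODEL_SEED)


@pytest.fixture(scope="session")
def isoforms(model):
    return [derive_isoform(model, s) for s in ((), (5, 6), (6,))]


@pytest.fixture(scope="session")
def snv823(model):
    return locate_snv(model, 823, "C", "T", splice_allele_base="C")


@pytest.fixture(scope="session")
def snv467(model):
    return locate_snv(model, 467, "C", "A", splice_allele_base="C")


@pytest.fixture(scope="session")
def patient1_sim_10k(model, isoforms, snv823):
    """10,000 patient-1-like reads at the default error model, fixed seed."""
    return simulate_sample(
        model, isoforms, patient1_alleles(), 10_000, ErrorModel(),
        snvs=[snv823], seed=1,
    )


@pytest.fixture(scope="session")
def patient1_phased_20k(model, isoforms, snv823):
    """Classified + genotyped calls for 20,000 patient-1-like reads."""
    from ampliskip.read_qc import filter_reads
    from ampliskip.classify import classify_reads
    from ampliskip.phasing import genotype_calls

    reads, truth = simulate_sample(
        model, isoforms, patient1_alleles(), 20_000, ErrorModel(),
        snvs=[snv823], seed=2,
    )
    kept, _ = filter_reads(reads)
    calls = classify_reads(kept, isoforms)
    calls = genotype_calls(kept, calls, snv823, isoforms, model)
    return kept, calls, truth


@pytest.fixture(scope="session")
def small_model():
    """A short 5-exon amplicon (reads <= 500 nt) for DP-oracle comparisons."""
    return generate_synthetic_gene(
        exon_lengths=(90, 70, 60, 80, 100),
        seed=11,
        cds_start_offset=20,
        cds_length=330,
        name="mini_amplicon",
        candidate_skips=((), (2, 3), (3,)),
    )
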