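import pytest

from radmut import (
    CohortConfig,
    read_vcf_cohort,
    run_pipeline,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def cohort_run(tmp_path_factory):
    """One full generated cohort run shared across the suite.

    Six lines, Poisson-100 mutations per line, 30x depth, four generations of
    selfing — the generator's default study conditions.
    """
    out = tmp_path_factory.mktemp("cohort")
    config = CohortConfig(seed=0)
    genome, genes, truth, paths = simulate_cohort(config, out)
    cohort = read_vcf_cohort(paths["vcf"], config.wild_type_id)
    result = run_pipeline(cohort, genome)
    return {
        "config": config,
        "genome": genome,
        "genes": genes,
        "truth": truth,
        "paths": paths,
        "cohort": cohort,
        "result": result,
    }


@pytest.fixture(scope="session")
def small_genome():
    """A tiny deterministic genome with sequence, for hand-built cases."""
    from radmut import GenomeModel

    seq = "AGTCTGCAATGGCATTAAGCCTGAACGTTACAGGTCCATGCGATAGCTTA" * 4
    return GenomeModel(chromosomes=[("chrT", len(seq))], sequence={"chrT": seq})
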