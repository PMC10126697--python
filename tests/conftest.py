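import pytest

from repcore import SimConfig, simulate_library, synthetic_reference
from repcore.simulator import full_heterozygous_genotype


@pytest.fixture(scope="session")
def recovery_dbs():
    """Reference set for recovery studies: 40 V genes (15 heterozygous-capable,
    55 alleles total), 10 D genes (15 alleles), 6 J genes (7 alleles)."""
    return {
        "V": synthetic_reference("V", 40, [1] * 25 + [2] * 15, (290, 300), 11),
        "D": synthetic_reference("D", 10, [1, 2], (16, 34), 12),
        "J": synthetic_reference("J", 6, [1, 1, 2, 1, 1, 1], (48, 60), 13),
    }


@pytest.fixture(scope="session")
def recovery_genotype(recovery_dbs):
    """Fully expressed diploid genotype over the recovery references, with one
    two-allele gene made homozygous so that its second allele is a known
    absent allele (clone-injection target)."""
    genotype = full_heterozygous_genotype(recovery_dbs)
    genotype["V"]["SIMV26"] = ("SIMV26*01", "SIMV26*01")
    return genotype


#: usage spread used in the recovery studies: ~1 order of magnitude so every
#: expressed allele draws a few hundred reads at the 20k depth the studies use
RECOVERY_USAGE_ORDERS = {"V": 1.0, "D": 1.5, "J": 1.0}


def simulate_recovery_library(genotype, dbs, seed, per_base_error, n_reads=20_000):
    config = SimConfig(
        seed=seed,
        n_reads=n_reads,
        usage_orders=dict(RECOVERY_USAGE_ORDERS),
        per_base_error=per_base_error,
    )
    return simulate_library(genotype, dbs, config)


@pytest.fixture(scope="session")
def noiseless_library(recovery_genotype, recovery_dbs):
    return simulate_recovery_library(
        recovery_genotype, recovery_dbs, seed=1, per_base_error=0.0
    )
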