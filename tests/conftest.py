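import numpy as np
import pytest

import coregenes as cg

BASES = "ACGT"


def rand_seq(rng: np.random.Generator, n: int) -> str:
    """Test-local random sequence helper, independent of the generator module."""
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


def mutate_seq(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = []
    for ch in seq:
        if rng.random() < rate:
            out.append(BASES[(BASES.index(ch) + int(rng.integers(1, 4))) % 4])
        else:
            out.append(ch)
    return "".join(out)


def gene(gene_id, genome_id, seq, product="hypothetical protein",
         replicon="unknown"):
    return cg.GeneRecord(gene_id=gene_id, genome_id=genome_id,
                         product=product, seq=seq, replicon=replicon)


@pytest.fixture(scope="session")
def sim_scenario():
    """One mid-sized synthetic scenario shared by read-only tests."""
    tax = cg.balanced_taxonomy(2, 3)
    cfg = cg.SimulationConfig(
        taxonomy=tax,
        n_core_per_clade={"root": 2, "root/clade0": 2, "root/clade1": 1},
        seed=11,
        n_accessory_per_genome=4,
        gene_len_range=(300, 600),
        divergence=0.02,
        paralog_dup_prob=0.1,
        decoy_16s_trna=True,
        plasmid_fraction=0.25,
    )
    genomes, truth, ann = cg.simulate(cfg)
    return tax, {g.genome_id: g for g in genomes}, truth, ann


@pytest.fixture(scope="session")
def sim_result(sim_scenario):
    tax, genomes, truth, ann = sim_scenario
    fcfg = cg.InputFilterConfig(min_genes=1)
    filtered = {}
    for gid in sorted(genomes):
        res, _rep = cg.apply_input_filters(genomes[gid], fcfg)
        assert res != cg.REJECTED
        filtered[gid] = res
    return cg.run_recursive(tax, filtered)
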