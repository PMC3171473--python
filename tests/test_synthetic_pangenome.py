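import json

import numpy as np
import pytest
from scipy import stats

import coregenes as cg
from coregenes.synthetic_pangenome import (ACCESSORY, _mutate, write_scenario)


def _config(**over):
    base = dict(
        taxonomy=cg.balanced_taxonomy(2, 2),
        n_core_per_clade={"root": 2, "root/clade0": 1},
        seed=3,
        n_accessory_per_genome=3,
        gene_len_range=(300, 500),
        divergence=0.02,
    )
    base.update(over)
    return cg.SimulationConfig(**base)


def test_config_validation():
    with pytest.raises(ValueError, match="divergence"):
        _config(divergence=1.0)
    with pytest.raises(ValueError, match="gene_len_range"):
        _config(gene_len_range=(50, 100))
    with pytest.raises(ValueError, match="seed"):
        _config(seed=None)


def test_simulate_shapes_and_truth_bookkeeping():
    genomes, truth, ann = cg.simulate(_config())
    assert sorted(g.genome_id for g in genomes) == \
        ["g000", "g001", "g002", "g003"]
    # root families in every genome, clade0 families only in its genomes
    assert truth.clade_families == {"root": {"F0001", "F0002"},
                                    "root/clade0": {"F0003"}}
    for fam in ("F0001", "F0002"):
        assert len(truth.family_orthologs[fam]) == 4
    assert len(truth.family_orthologs["F0003"]) == 2
    for fam, orthos in truth.family_orthologs.items():
        clade = truth.family_clade[fam]
        genomes_in = {o.split("_")[0] for o in orthos}
        assert genomes_in == cg.genomes_under(_config().taxonomy, clade)
    # every gene is accounted for
    all_ids = {g.gene_id for gs in genomes for g in gs.genes}
    assert set(truth.gene_info) == all_ids
    n_acc = sum(1 for v in truth.gene_info.values() if v[0] == ACCESSORY)
    assert n_acc == 4 * 3


def test_simulate_deterministic_same_seed():
    a, _, ann_a = cg.simulate(_config())
    b, _, ann_b = cg.simulate(_config())
    assert [(g.gene_id, g.seq, g.product, g.replicon)
            for gs in a for g in gs.genes] == \
        [(g.gene_id, g.seq, g.product, g.replicon)
         for gs in b for g in gs.genes]
    assert ann_a.entries == ann_b.entries
    c, _, _ = cg.simulate(_config(seed=4))
    assert [g.seq for gs in a for g in gs.genes] != \
        [g.seq for gs in c for g in gs.genes]


def test_mutate_rate_zero_identity_and_binomial_rate():
    rng = np.random.default_rng(0)
    seq = rng.integers(0, 4, size=1000, dtype=np.uint8)
    out = _mutate(np.random.default_rng(1), seq, 0.0)
    assert np.array_equal(out, seq)
    # observed substitutions per branch ~ Binomial(L, rate)
    diffs = []
    rng2 = np.random.default_rng(2)
    for _ in range(200):
        diffs.append(int((_mutate(rng2, seq, 0.02) != seq).sum()))
    mean = np.mean(diffs)
    expect = 1000 * 0.02
    sd = np.sqrt(1000 * 0.02 * 0.98 / 200)
    assert abs(mean - expect) < 4 * sd
    # substitutions always change the base (no silent draws)
    assert min(diffs) >= 0 and max(diffs) <= 1000


def test_mutate_rate_coupling_nested_sets():
    """Same generator state: higher rate mutates a superset of sites."""
    seq = np.random.default_rng(3).integers(0, 4, size=800, dtype=np.uint8)
    lo = _mutate(np.random.default_rng(7), seq, 0.02)
    hi = _mutate(np.random.default_rng(7), seq, 0.15)
    lo_sites = set(np.flatnonzero(lo != seq))
    hi_sites = set(np.flatnonzero(hi != seq))
    assert lo_sites <= hi_sites
    # and the substituted bases agree on the shared sites
    for s in lo_sites:
        assert lo[s] == hi[s]


def test_decoys_and_plasmids_emitted_and_filterable():
    cfg = _config(decoy_16s_trna=True, plasmid_fraction=0.34)
    genomes, truth, ann = cg.simulate(cfg)
    for gs in genomes:
        products = [g.product for g in gs.genes]
        assert products.count("16S ribosomal RNA") == 1
        assert sum("tRNA" in p for p in products) == 2
        n_plasmid = sum(g.replicon == "plasmid" for g in gs.genes)
        assert n_plasmid == 1  # round(0.34 * 3)
        filtered, _ = cg.apply_input_filters(
            gs, cg.InputFilterConfig(min_genes=1))
        assert all("16S" not in g.product and "tRNA" not in g.product
                   and g.replicon != "plasmid" for g in filtered.genes)
    # decoys are not part of the planted truth
    assert all("_rrs" not in gid and "_trna" not in gid
               for gid in truth.gene_info)


def test_decoy_16s_would_form_fake_universal_core():
    """Without the input filters, the conserved decoy becomes a root core."""
    tax = cg.balanced_taxonomy(2, 2)
    cfg = _config(taxonomy=tax, decoy_16s_trna=True,
                  n_core_per_clade={}, n_accessory_per_genome=1)
    genomes, truth, _ = cg.simulate(cfg)
    unfiltered = {g.genome_id: g for g in genomes}
    res = cg.run_recursive(tax, unfiltered)
    root_fams = res.sets["root"].retained()
    assert any(all(m.endswith("_rrs") for m in f.members) for f in root_fams)
    # with the filters applied, no root family remains
    filtered = {g.genome_id: cg.apply_input_filters(
        g, cg.InputFilterConfig(min_genes=1))[0] for g in genomes}
    res2 = cg.run_recursive(tax, filtered)
    assert res2.sets["root"].retained() == []


def test_paralogs_marked_and_extra_diverged():
    cfg = _config(paralog_dup_prob=0.999, seed=9)
    genomes, truth, _ = cg.simulate(cfg)
    paralogs = [gid for gid, (fam, is_p) in truth.gene_info.items() if is_p]
    assert paralogs
    for pid in paralogs:
        fam = truth.gene_info[pid][0]
        assert pid in truth.family_members[fam]
        assert pid not in truth.family_orthologs[fam]


def test_annotations_cover_cores_and_some_accessory():
    genomes, truth, ann = cg.simulate(_config(
        accessory_unannotated_fraction=0.5, seed=10))
    for fam, members in truth.family_members.items():
        for gid in members:
            assert gid in ann
    acc = [gid for gid, (f, _) in truth.gene_info.items() if f == ACCESSORY]
    annotated_acc = [g for g in acc if g in ann]
    assert 0 < len(annotated_acc) < len(acc)


def test_truth_eval_strictness():
    tax = cg.balanced_taxonomy(1, 2)
    cfg = cg.SimulationConfig(taxonomy=tax, n_core_per_clade={"root": 2},
                              seed=5, n_accessory_per_genome=0,
                              gene_len_range=(300, 400), divergence=0.0)
    genomes, truth, _ = cg.simulate(cfg)
    res = cg.run_recursive(tax, {g.genome_id: g for g in genomes})
    ev = cg.truth_eval(res, truth)
    assert ev["root"] == {"n_planted": 2, "n_recovered": 2, "matched": 2,
                          "precision": 1.0, "recall": 1.0}
    # corrupting one representative breaks the exact-set match
    fam = res.sets["root"].retained()[0]
    g0 = sorted(fam.representative)[0]
    fam.representative[g0] = fam.representative[g0] + ""  # no-op keeps match
    assert cg.truth_eval(res, truth)["root"]["matched"] == 2
    fam.representative[g0] = sorted(truth.gene_info)[0] \
        if sorted(truth.gene_info)[0] != fam.representative[g0] \
        else sorted(truth.gene_info)[1]
    assert cg.truth_eval(res, truth)["root"]["matched"] <= 1


def test_recall_monotone_under_divergence_sweep():
    tax = cg.balanced_taxonomy(2, 2)
    recalls = []
    for rate in (0.0, 0.05, 0.15, 0.30, 0.45):
        cfg = cg.SimulationConfig(
            taxonomy=tax, n_core_per_clade={"root": 3},
            seed=21, n_accessory_per_genome=1,
            gene_len_range=(300, 500), divergence=rate)
        genomes, truth, _ = cg.simulate(cfg)
        res = cg.run_recursive(tax, {g.genome_id: g for g in genomes})
        recalls.append(cg.truth_eval(res, truth)["root"]["recall"])
    assert recalls[0] == 1.0
    assert all(a >= b for a, b in zip(recalls, recalls[1:]))
    assert recalls[-1] < 1.0  # 45% per-branch divergence destroys homology


def test_indel_mode_changes_lengths_but_keeps_recovery():
    tax = cg.balanced_taxonomy(1, 3)
    cfg = cg.SimulationConfig(
        taxonomy=tax, n_core_per_clade={"root": 2}, seed=13,
        n_accessory_per_genome=0, gene_len_range=(400, 500),
        divergence=0.01, indel_rate=2.0)
    genomes, truth, _ = cg.simulate(cfg)
    lengths = {len(g.seq) for gs in genomes for g in gs.genes}
    assert len(lengths) > 2  # indels actually shifted gene lengths
    res = cg.run_recursive(tax, {g.genome_id: g for g in genomes})
    assert cg.truth_eval(res, truth)["root"]["recall"] == 1.0


def test_write_scenario_layout(tmp_path):
    genomes, truth, ann = cg.simulate(_config())
    write_scenario(genomes, truth, ann, _config().taxonomy, tmp_path)
    ffns = sorted(p.name for p in (tmp_path / "genomes").glob("*.ffn"))
    assert ffns == ["g000.ffn", "g001.ffn", "g002.ffn", "g003.ffn"]
    lineages = (tmp_path / "lineages.tsv").read_text().splitlines()
    assert "g000\troot\tclade0" in lineages
    payload = json.loads((tmp_path / "ground_truth.json").read_text())
    assert set(payload["clade_families"]) == {"root", "root/clade0"}
    back = cg.CogAnnotation.from_tsv(tmp_path / "cog_annotations.tsv")
    assert back.entries == ann.entries
    # round-trips through the standard loaders
    gs = cg.read_gene_fasta(tmp_path / "genomes" / "g000.ffn", "g000")
    assert {g.gene_id for g in gs.genes} == \
        {g.gene_id for g in genomes[0].genes}
    tax = cg.load_taxonomy(tmp_path / "lineages.tsv")
    assert cg.genomes_under(tax, "root") == {f"g{i:03d}" for i in range(4)}
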