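"""Synthetic pangenomes with known core families, for end-to-end testing.

Gene repertoires are evolved down a guide taxonomy: each planted core family
starts as a random ancestral nucleotide sequence at its clade and accumulates
point substitutions independently along every branch; every genome below the
clade inherits exactly one ortholog (plus optional extra-diverged paralogs).
Accessory genes are drawn fresh per genome so cross-genome accessory homology
is negligible at the simulated lengths.  Decoy 16S rRNA (a conserved
root-level family that must be excluded by the input filters to avoid a fake
universal core) and short tRNA records, plasmid-tagged accessory genes, and
synthetic COG annotations complete the emulation of annotated ``.ffn`` input.

Substitutions are coupled across divergence rates: each site carries one
uniform draw per branch and mutates when the draw falls below the rate, so
re-simulating with the same seed at a higher rate yields a superset of the
mutations.  This makes recovery-vs-divergence sweeps monotone by
construction rather than by chance.  Substitutions only by default; an indel
mode (geometric lengths) exercises gapped alignment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .functional_profiles import CogAnnotation, CogEntry
from .genome_io import GeneRecord, GenomeGeneSet, write_gene_fasta
from .guide_taxonomy import GuideTaxonomy, TaxonNode, taxonomy_from_lineages

ACCESSORY = "ACCESSORY"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

DEFAULT_CORE_CATEGORY_WEIGHTS = {
    "J": 0.20, "K": 0.13, "L": 0.13, "O": 0.12, "S": 0.12,
    "C": 0.06, "E": 0.06, "G": 0.06, "M": 0.06, "T": 0.06,
}
DEFAULT_ACCESSORY_CATEGORY_WEIGHTS = {
    c: 1.0 for c in "JKLOSCEGMTNPQRV"
}


@dataclass
class SimulationConfig:
    taxonomy: GuideTaxonomy
    n_core_per_clade: dict[str, int]
    seed: int
    n_accessory_per_genome: int = 10
    gene_len_range: tuple[int, int] = (300, 1500)
    divergence: float = 0.02          # expected substituted fraction per branch
    paralog_dup_prob: float = 0.0     # per core gene per genome
    paralog_extra_divergence: float = 0.05
    decoy_16s_trna: bool = False
    plasmid_fraction: float = 0.0     # of accessory genes
    indel_rate: float = 0.0           # per-branch indel events per gene
    accessory_unannotated_fraction: float = 0.2
    core_category_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CORE_CATEGORY_WEIGHTS))
    accessory_category_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ACCESSORY_CATEGORY_WEIGHTS))
    n_accessory_cog_pool: int = 40

    def __post_init__(self):
        for name, r in (("divergence", self.divergence),
                        ("paralog_dup_prob", self.paralog_dup_prob),
                        ("paralog_extra_divergence", self.paralog_extra_divergence),
                        ("plasmid_fraction", self.plasmid_fraction)):
            if not 0 <= r < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.gene_len_range[0] < 75:
            raise ValueError("gene_len_range minimum must allow alignments >= 75 nt")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class GroundTruth:
    clade_families: dict[str, set[str]]          # clade_id -> planted family ids
    gene_info: dict[str, tuple[str, bool]]       # gene_id -> (family|ACCESSORY, is_paralog)
    family_orthologs: dict[str, set[str]]        # family -> one ortholog per genome
    family_members: dict[str, set[str]]          # orthologs + paralogs
    family_clade: dict[str, str]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "clade_families": {k: sorted(v) for k, v in self.clade_families.items()},
            "gene_info": {k: list(v) for k, v in self.gene_info.items()},
            "family_orthologs": {k: sorted(v) for k, v in self.family_orthologs.items()},
            "family_members": {k: sorted(v) for k, v in self.family_members.items()},
            "family_clade": self.family_clade,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    """One branch of point substitutions.

    The uniform site draws and substitution offsets are consumed regardless
    of the rate, so mutation sets are nested across rates for a fixed seed.
    """
    u = rng.random(len(seq))
    offset = rng.integers(1, 4, size=len(seq), dtype=np.uint8)
    out = seq.copy()
    hit = u < rate
    out[hit] = (out[hit] + offset[hit]) % 4
    return out


def _indels(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    n_events = rng.poisson(rate)
    for _ in range(n_events):
        pos = int(rng.integers(0, len(seq)))
        length = int(rng.geometric(0.5))
        if rng.random() < 0.5 and len(seq) > length + 80:
            seq = np.concatenate([seq[:pos], seq[pos + length:]])
        else:
            seq = np.concatenate([seq[:pos],
                                  _random_seq(rng, length), seq[pos:]])
    return seq


def _decode(seq: np.ndarray) -> str:
    return _BASES[seq].tobytes().decode("ascii")


def _pick(rng: np.random.Generator, weights: dict[str, float]) -> str:
    cats = sorted(weights)
    p = np.array([weights[c] for c in cats], dtype=float)
    return cats[int(rng.choice(len(cats), p=p / p.sum()))]


def simulate(cfg: SimulationConfig):
    """Generate (genomes, ground truth, COG annotation) from the config.

    Fully reproducible: identical configs give byte-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    tax = cfg.taxonomy
    lo, hi = cfg.gene_len_range

    # plant ancestral families clade by clade, in a fixed preorder
    preorder: list[TaxonNode] = []

    def walk(n: TaxonNode):
        preorder.append(n)
        for c in n.children:
            walk(c)

    walk(tax.root)

    fam_counter = 0
    truth = GroundTruth({}, {}, {}, {}, {})
    ann_entries: dict[str, CogEntry] = {}
    genes_per_genome: dict[str, list[GeneRecord]] = {}
    for node in preorder:
        for n in node.postorder():
            for g in n.genome_ids:
                genes_per_genome.setdefault(g, [])

    decoy_specs = []
    if cfg.decoy_16s_trna:
        decoy_specs = [("rrs", 1550, "16S ribosomal RNA")]

    def evolve_family(fam_id: str, node: TaxonNode, seq: np.ndarray,
                      category: str | None, cog_id: str | None,
                      product: str, is_decoy: bool):
        """Descend from ``node``, mutating along each edge; deposit at genomes."""
        if node.is_terminal:
            for genome_id in node.genome_ids:
                leaf_seq = _mutate(rng, seq, cfg.divergence)
                if cfg.indel_rate:
                    leaf_seq = _indels(rng, leaf_seq, cfg.indel_rate)
                gid = f"{genome_id}_{fam_id}"
                genes_per_genome[genome_id].append(
                    GeneRecord(gene_id=gid, genome_id=genome_id,
                               product=product, seq=_decode(leaf_seq))
                )
                dup = rng.random()
                para_seq = _mutate(rng, leaf_seq, cfg.paralog_extra_divergence)
                if not is_decoy:
                    truth.gene_info[gid] = (fam_id, False)
                    truth.family_orthologs[fam_id].add(gid)
                    truth.family_members[fam_id].add(gid)
                    if cog_id is not None:
                        ann_entries[gid] = CogEntry(cog_id, category)
                    if dup < cfg.paralog_dup_prob:
                        pid = f"{gid}_p1"
                        genes_per_genome[genome_id].append(
                            GeneRecord(gene_id=pid, genome_id=genome_id,
                                       product=product, seq=_decode(para_seq))
                        )
                        truth.gene_info[pid] = (fam_id, True)
                        truth.family_members[fam_id].add(pid)
                        if cog_id is not None:
                            ann_entries[pid] = CogEntry(cog_id, category)
            return
        for child in node.children:
            child_seq = _mutate(rng, seq, cfg.divergence)
            evolve_family(fam_id, child, child_seq, category, cog_id,
                          product, is_decoy)

    for node in preorder:
        n_fams = cfg.n_core_per_clade.get(node.taxon_id, 0)
        if n_fams:
            truth.clade_families.setdefault(node.taxon_id, set())
        for _ in range(n_fams):
            fam_counter += 1
            fam_id = f"F{fam_counter:04d}"
            length = int(rng.integers(lo, hi + 1))
            seq = _random_seq(rng, length)
            category = _pick(rng, cfg.core_category_weights)
            cog_id = f"COG{fam_counter:04d}"
            truth.clade_families[node.taxon_id].add(fam_id)
            truth.family_clade[fam_id] = node.taxon_id
            truth.family_orthologs[fam_id] = set()
            truth.family_members[fam_id] = set()
            evolve_family(fam_id, node, seq, category, cog_id,
                          "conserved hypothetical protein", is_decoy=False)

    for name, length, product in decoy_specs:
        seq = _random_seq(rng, length)
        evolve_family(name, tax.root, seq, None, None, product, is_decoy=True)

    # accessory genes, tRNA decoys, plasmid tagging — per genome in sorted order
    genomes: list[GenomeGeneSet] = []
    n_plasmid = int(round(cfg.plasmid_fraction * cfg.n_accessory_per_genome))
    for genome_id in sorted(genes_per_genome):
        genes = genes_per_genome[genome_id]
        for i in range(cfg.n_accessory_per_genome):
            length = int(rng.integers(lo, hi + 1))
            seq = _random_seq(rng, length)
            plasmid = i < n_plasmid
            gid = f"{genome_id}_acc{i:03d}"
            product = ("plasmid-encoded protein" if plasmid
                       else "hypothetical protein")
            genes.append(
                GeneRecord(gene_id=gid, genome_id=genome_id, product=product,
                           seq=_decode(seq),
                           replicon="plasmid" if plasmid else "unknown")
            )
            truth.gene_info[gid] = (ACCESSORY, False)
            if rng.random() >= cfg.accessory_unannotated_fraction:
                pool_idx = int(rng.integers(0, cfg.n_accessory_cog_pool))
                cat = _pick(rng, cfg.accessory_category_weights)
                ann_entries[gid] = CogEntry(f"COGA{pool_idx:03d}", cat)
        if cfg.decoy_16s_trna:
            for j in range(2):
                gid = f"{genome_id}_trna{j}"
                genes.append(
                    GeneRecord(gene_id=gid, genome_id=genome_id,
                               product=f"tRNA-Ala", seq=_decode(_random_seq(rng, 76)))
                )
        genomes.append(GenomeGeneSet(genome_id=genome_id, genes=genes))

    return genomes, truth, CogAnnotation(ann_entries)


def balanced_taxonomy(n_clades: int, genomes_per_clade: int,
                      prefix: str = "g") -> GuideTaxonomy:
    """Helper: a 2-level taxonomy of ``n_clades`` clades x ``genomes_per_clade``."""
    rows = []
    idx = 0
    for c in range(n_clades):
        for _ in range(genomes_per_clade):
            rows.append((f"{prefix}{idx:03d}", ["root", f"clade{c}"]))
            idx += 1
    return taxonomy_from_lineages(rows)


def truth_eval(result, truth: GroundTruth) -> dict[str, dict[str, float]]:
    """Per-clade precision/recall of recovered core families.

    A recovered family matches a planted one iff its per-genome
    representative set equals the planted ortholog set.  Only clades with
    planted families are scored.
    """
    out: dict[str, dict[str, float]] = {}
    for clade_id, planted in truth.clade_families.items():
        planted_sets = [frozenset(truth.family_orthologs[f]) for f in planted]
        recovered = []
        if clade_id in result.sets:
            recovered = result.sets[clade_id].retained()
        rec_sets = [frozenset(f.representative.values()) for f in recovered]
        matched = sum(1 for r in rec_sets if r in planted_sets)
        out[clade_id] = {
            "n_planted": len(planted),
            "n_recovered": len(rec_sets),
            "matched": matched,
            "precision": matched / len(rec_sets) if rec_sets else 0.0,
            "recall": matched / len(planted_sets) if planted_sets else 1.0,
        }
    return out


def write_scenario(
    genomes: list[GenomeGeneSet],
    truth: GroundTruth,
    ann: CogAnnotation,
    tax: GuideTaxonomy,
    out_dir: str | Path,
) -> None:
    """Emit per-genome FASTA, lineage TSV, COG TSV and ground-truth JSON."""
    out = Path(out_dir)
    (out / "genomes").mkdir(parents=True, exist_ok=True)
    for gs in genomes:
        write_gene_fasta(gs.genes, out / "genomes" / f"{gs.genome_id}.ffn")
    lines = []

    def lineage(node, path):
        path = path + [node.name]
        if node.is_terminal:
            for g in node.genome_ids:
                lines.append(g + "\t" + "\t".join(path))
        for c in node.children:
            lineage(c, path)

    lineage(tax.root, [])
    (out / "lineages.tsv").write_text("\n".join(lines) + "\n")
    ann.to_tsv(out / "cog_annotations.tsv")
    truth.to_json(out / "ground_truth.json")
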