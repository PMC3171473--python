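"""Reading, merging and filtering per-genome gene FASTA files.

The unit of input is a ``.ffn``-style nucleotide FASTA holding one record per
annotated gene, with the description line carrying the product annotation.
Before core-gene discovery, gene sets are cleaned: plasmid-only genes are
dropped, 16S rRNA and tRNA genes are excluded by annotation (16S because it is
an already-established universal core, tRNAs because they are too short to be
phylogenetically informative), and genomes left with fewer than a minimum
number of genes (400 by default, excluding reduced parasite/endosymbiont
genomes) are rejected outright.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: marker returned by :func:`apply_input_filters` for excluded genomes
REJECTED = "REJECTED"

_VALID = set("ACGTN")
_NON_ACGT = re.compile(r"[^ACGT]")


@dataclass(frozen=True)
class GeneRecord:
    """A single annotated nucleotide gene.

    Sequences are uppercased on input and every non-ACGT IUPAC letter is
    mapped to ``N``; ``N`` never seeds homology matches downstream.
    """

    gene_id: str
    genome_id: str
    product: str
    seq: str
    replicon: str = "unknown"  # chromosome | plasmid | unknown

    def __post_init__(self):
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if len(self.seq) < 1:
            raise ValueError(f"gene {self.gene_id}: empty sequence")
        if self.replicon not in ("chromosome", "plasmid", "unknown"):
            raise ValueError(f"gene {self.gene_id}: bad replicon {self.replicon!r}")
        bad = set(self.seq) - _VALID
        if bad:
            raise ValueError(f"gene {self.gene_id}: invalid letters {sorted(bad)}")


@dataclass
class GenomeGeneSet:
    """All genes of one genome, in input order."""

    genome_id: str
    genes: list[GeneRecord] = field(default_factory=list)
    taxon_id: str = ""

    def __post_init__(self):
        if not self.taxon_id:
            self.taxon_id = self.genome_id
        seen = set()
        for g in self.genes:
            if g.genome_id != self.genome_id:
                raise ValueError(
                    f"gene {g.gene_id} carries genome {g.genome_id}, "
                    f"expected {self.genome_id}"
                )
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id}")
            seen.add(g.gene_id)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)


@dataclass(frozen=True)
class InputFilterConfig:
    """Input-preparation rules.

    ``min_genes`` keeps only genomes with at least that many genes after the
    other filters; ``exclude_product_patterns`` are case-insensitive substrings
    matched against the product annotation; ``drop_plasmid_only`` removes genes
    carried only on plasmids.
    """

    min_genes: int = 400
    exclude_product_patterns: tuple[str, ...] = (
        "16S ribosomal RNA",
        "16S rRNA",
        "tRNA",
    )
    drop_plasmid_only: bool = True

    def __post_init__(self):
        if self.min_genes < 0:
            raise ValueError("min_genes must be >= 0")
        if any(not p for p in self.exclude_product_patterns):
            raise ValueError("exclude patterns must be non-empty strings")


@dataclass(frozen=True)
class FilterReport:
    genome_id: str
    n_input: int
    n_plasmid_removed: int
    n_pattern_removed: int
    n_retained: int
    status: str  # "retained" | "REJECTED"


def _clean_seq(raw: str) -> str:
    return _NON_ACGT.sub("N", raw.upper())


def read_gene_fasta(
    path: str | Path,
    genome_id: str,
    plasmid_token: str = "plasmid",
) -> GenomeGeneSet:
    """Parse one ``.ffn``-style FASTA into a :class:`GenomeGeneSet`.

    The record id (header up to the first whitespace) is the gene id and the
    remainder of the description is the product annotation.  A header
    containing ``plasmid_token`` (case-insensitive) marks the gene as
    plasmid-borne.
    """
    path = Path(path)
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as e:  # Biopython names the offending content
        raise ValueError(f"malformed FASTA in {path}: {e}") from e
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate gene_id {rec.id!r} in {path}")
        seen.add(rec.id)
        product = rec.description[len(rec.id):].strip()
        replicon = (
            "plasmid" if plasmid_token.lower() in rec.description.lower() else "unknown"
        )
        genes.append(
            GeneRecord(
                gene_id=rec.id,
                genome_id=genome_id,
                product=product,
                seq=_clean_seq(str(rec.seq)),
                replicon=replicon,
            )
        )
    return GenomeGeneSet(genome_id=genome_id, genes=genes)


def concatenate_genome_files(
    paths: Sequence[str | Path],
    genome_id: str,
    plasmid_token: str = "plasmid",
) -> GenomeGeneSet:
    """Merge several FASTA files (e.g. multiple chromosomes) into one genome.

    Gene-id collisions across files are resolved by suffixing the colliding id
    with the (1-based) file index; each rename is logged.
    """
    if not paths:
        raise ValueError("concatenate_genome_files: need at least one path")
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    for i, p in enumerate(paths, start=1):
        part = read_gene_fasta(p, genome_id, plasmid_token=plasmid_token)
        for g in part.genes:
            if g.gene_id in seen:
                new_id = f"{g.gene_id}__f{i}"
                logger.warning(
                    "genome %s: gene id %s from file %s collides; renamed to %s",
                    genome_id, g.gene_id, p, new_id,
                )
                g = replace(g, gene_id=new_id)
            seen.add(g.gene_id)
            genes.append(g)
    return GenomeGeneSet(genome_id=genome_id, genes=genes)


def load_replicon_sidecar(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (gene_id, replicon) overriding header-derived replicons."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        gene_id, replicon = line.rstrip("\n").split("\t")[:2]
        out[gene_id] = replicon
    return out


def apply_replicon_overrides(
    genome: GenomeGeneSet, overrides: dict[str, str]
) -> GenomeGeneSet:
    genes = [
        replace(g, replicon=overrides.get(g.gene_id, g.replicon))
        for g in genome.genes
    ]
    return GenomeGeneSet(genome_id=genome.genome_id, genes=genes,
                         taxon_id=genome.taxon_id)


def apply_input_filters(
    genome: GenomeGeneSet,
    cfg: InputFilterConfig | None = None,
) -> tuple[GenomeGeneSet | str, FilterReport]:
    """Apply the input-preparation rules; return the filtered set or ``REJECTED``.

    Order: plasmid removal, then product-pattern exclusion, then the minimum
    gene count — so the count threshold applies to the analyzable gene set.
    """
    cfg = cfg or InputFilterConfig()
    genes = list(genome.genes)
    n_input = len(genes)

    n_plasmid = 0
    if cfg.drop_plasmid_only:
        kept = [g for g in genes if g.replicon != "plasmid"]
        n_plasmid = len(genes) - len(kept)
        genes = kept

    patterns = [p.lower() for p in cfg.exclude_product_patterns]
    kept = [g for g in genes if not any(p in g.product.lower() for p in patterns)]
    n_pattern = len(genes) - len(kept)
    genes = kept

    status = "retained" if len(genes) >= cfg.min_genes else REJECTED
    report = FilterReport(
        genome_id=genome.genome_id,
        n_input=n_input,
        n_plasmid_removed=n_plasmid,
        n_pattern_removed=n_pattern,
        n_retained=len(genes),
        status=status,
    )
    logger.info(
        "filter %s: %d in, %d plasmid removed, %d pattern removed, %d retained (%s)",
        genome.genome_id, n_input, n_plasmid, n_pattern, len(genes), status,
    )
    if status == REJECTED:
        return REJECTED, report
    return (
        GenomeGeneSet(genome_id=genome.genome_id, genes=genes,
                      taxon_id=genome.taxon_id),
        report,
    )


def write_filter_report(reports: Iterable[FilterReport], path: str | Path) -> None:
    lines = ["genome_id\tn_input\tn_plasmid_removed\tn_pattern_removed\tn_retained\tstatus"]
    for r in reports:
        lines.append(
            f"{r.genome_id}\t{r.n_input}\t{r.n_plasmid_removed}\t"
            f"{r.n_pattern_removed}\t{r.n_retained}\t{r.status}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_gene_fasta(genes: Iterable[GeneRecord], path: str | Path) -> None:
    """Write gene records as nucleotide FASTA (id + product on the header)."""
    with open(path, "w") as fh:
        for g in genes:
            desc = f" {g.product}" if g.product else ""
            fh.write(f">{g.gene_id}{desc}\n")
            for i in range(0, len(g.seq), 70):
                fh.write(g.seq[i:i + 70] + "\n")
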