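"""Nucleotide homology search with blastn-like thresholds.

Core-gene discovery needs one answer per gene pair: is there a significant
nucleotide-level homology hit?  The built-in backend is a seed-and-extend
search: exact ``word_size``-mer seeds locate candidate subject/diagonal pairs,
an ungapped best-segment prescreen discards chance seed matches, and
surviving candidates are scored with an affine-gap local alignment
(match +2, mismatch -3; a gap of length k costs 5 + 2k).  Significance uses
Karlin-Altschul statistics E = m * n * 2^-bits with lambda solved numerically
for the scoring scheme and K fixed at 0.41 (precomputed constant).  Hits must
satisfy both the e-value ceiling and a minimum alignment length; the defaults
(word size 10, e-value 0.001, alignment length 75) suit ortholog detection in
moderately diverged prokaryotic genes.

An adapter with the same contract drives an external ``blastn`` executable
when exact BLAST statistics are wanted.
"""

from __future__ import annotations

import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import Align
from scipy.optimize import brentq

from .genome_io import GeneRecord, write_gene_fasta

MATCH = 2
MISMATCH = -3
GAP_OPEN = 5   # cost of opening a gap, on top of the per-base cost
GAP_EXTEND = 2  # per gap base

_K = 0.41


def _karlin_lambda(match: float = MATCH, mismatch: float = MISMATCH) -> float:
    # uniform base composition: P(match) = 1/4
    f = lambda lam: 0.25 * math.exp(lam * match) + 0.75 * math.exp(lam * mismatch) - 1.0
    return brentq(f, 1e-6, 10.0)


_LAMBDA = _karlin_lambda()

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def bit_score(raw: float) -> float:
    return (_LAMBDA * raw - math.log(_K)) / math.log(2.0)


def evalue(raw: float, query_len: int, db_len: int) -> float:
    return query_len * db_len * 2.0 ** (-bit_score(raw))


@dataclass(frozen=True)
class SearchParams:
    word_size: int = 10
    evalue_max: float = 0.001
    min_aln_len: int = 75
    both_strands: bool = True
    #: minimum ungapped best-segment score before gapped extension is attempted
    ungapped_trigger: int = 30

    def __post_init__(self):
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be > 0")
        if self.min_aln_len < self.word_size:
            raise ValueError("min_aln_len must be >= word_size")


@dataclass(frozen=True)
class HomologyHit:
    query_id: str
    subject_id: str
    aln_len: int
    identity: float
    score: float  # bits
    evalue: float


class BackendUnavailable(RuntimeError):
    """Raised when the external search tool is not installed."""


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


class SearchDatabase:
    """Word-indexed collection of subject genes.

    Seeds are exact ``word_size``-mers of the forward strands; when searching
    both strands the query is additionally scanned in reverse complement,
    which finds the same seed pairs as indexing both subject strands.
    Words containing ``N`` are never indexed, so ``N`` cannot seed a match.
    """

    def __init__(self, genes: Iterable[GeneRecord], word_size: int = 10):
        self.genes: list[GeneRecord] = list(genes)
        if not self.genes:
            raise ValueError("cannot build a database from zero genes")
        self.word_size = word_size
        self.by_id = {g.gene_id: g for g in self.genes}
        if len(self.by_id) != len(self.genes):
            raise ValueError("duplicate gene ids in database")
        self.arrays = [_encode(g.seq) for g in self.genes]
        self.total_len = sum(len(g.seq) for g in self.genes)
        self.word_index: dict[str, list[tuple[int, int]]] = {}
        w = word_size
        for idx, g in enumerate(self.genes):
            seq = g.seq
            for pos in range(len(seq) - w + 1):
                word = seq[pos:pos + w]
                if "N" in word:
                    continue
                self.word_index.setdefault(word, []).append((idx, pos))

    def __len__(self) -> int:
        return len(self.genes)


def build_database(genes: Iterable[GeneRecord], word_size: int = 10) -> SearchDatabase:
    return SearchDatabase(genes, word_size=word_size)


def _local_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = MATCH
    a.mismatch_score = MISMATCH
    a.open_gap_score = -(GAP_OPEN + GAP_EXTEND)
    a.extend_gap_score = -GAP_EXTEND
    return a


_ALIGNER = _local_aligner()


def _best_segment_score(qa: np.ndarray, sa: np.ndarray, diag: int) -> int:
    """Best ungapped segment score (Kadane) on one diagonal.

    ``diag`` is subject_pos - query_pos.  ``N`` never scores as a match
    because 'N' == 'N' positions are genuine byte matches; they are masked.
    """
    if diag >= 0:
        q = qa[: len(sa) - diag]
        s = sa[diag: diag + len(q)]
    else:
        s = sa[: len(qa) + diag]
        q = qa[-diag: -diag + len(s)]
    if len(q) == 0:
        return 0
    match = (q == s) & (q != ord("N"))
    scores = np.where(match, MATCH, MISMATCH).astype(np.int64)
    cum = np.cumsum(scores)
    prefix_min = np.minimum.accumulate(np.concatenate(([0], cum[:-1])))
    return int(np.max(cum - prefix_min))


def _align_stats(qseq: str, sseq: str):
    """Score, alignment length, identities and query start of the best local alignment."""
    alns = _ALIGNER.align(qseq, sseq)
    if len(alns) == 0:
        return None
    al = alns[0]
    c = al.counts()
    aln_len = c.identities + c.mismatches + c.internal_gaps
    qstart = int(al.aligned[0][0][0])
    return float(al.score), int(aln_len), int(c.identities), qstart


def search(
    queries: Sequence[GeneRecord],
    db: SearchDatabase,
    params: SearchParams | None = None,
    include_self: bool = False,
) -> list[HomologyHit]:
    """Seed-and-extend search of ``queries`` against ``db``.

    Returns at most one hit per (query, subject) pair — the highest-scoring
    local alignment, ties broken by leftmost query start — filtered by the
    minimum alignment length and e-value ceiling.  Output is sorted by
    (query_id, evalue, subject_id) and deterministic for fixed inputs.
    """
    params = params or SearchParams()
    w = params.word_size
    if w != db.word_size:
        raise ValueError(
            f"params.word_size {w} does not match database word size {db.word_size}"
        )
    hits: list[HomologyHit] = []
    strands = ("+", "-") if params.both_strands else ("+",)
    for q in queries:
        best: dict[int, tuple] = {}  # subject idx -> (score, qstart, aln_len, ident)
        for strand in strands:
            qseq = q.seq if strand == "+" else revcomp(q.seq)
            qa = _encode(qseq)
            diags: dict[tuple[int, int], None] = {}
            for pos in range(len(qseq) - w + 1):
                entry = db.word_index.get(qseq[pos:pos + w])
                if not entry:
                    continue
                for sidx, spos in entry:
                    diags.setdefault((sidx, spos - pos), None)
            prescreen: dict[int, int] = {}
            for (sidx, diag) in diags:
                sc = _best_segment_score(qa, db.arrays[sidx], diag)
                if sc > prescreen.get(sidx, -1):
                    prescreen[sidx] = sc
            for sidx, sc in prescreen.items():
                subj = db.genes[sidx]
                if subj.gene_id == q.gene_id and not include_self:
                    continue
                if sc < params.ungapped_trigger:
                    continue
                stats = _align_stats(qseq, subj.seq)
                if stats is None:
                    continue
                score, aln_len, ident, qstart = stats
                prev = best.get(sidx)
                if prev is None or (score, -qstart) > (prev[0], -prev[1]):
                    best[sidx] = (score, qstart, aln_len, ident)
        for sidx in sorted(best):
            score, _qstart, aln_len, ident = best[sidx]
            if aln_len < params.min_aln_len:
                continue
            ev = evalue(score, len(q.seq), db.total_len)
            if ev > params.evalue_max:
                continue
            hits.append(
                HomologyHit(
                    query_id=q.gene_id,
                    subject_id=db.genes[sidx].gene_id,
                    aln_len=aln_len,
                    identity=ident / aln_len if aln_len else 0.0,
                    score=bit_score(score),
                    evalue=ev,
                )
            )
    hits.sort(key=lambda h: (h.query_id, h.evalue, h.subject_id))
    return hits


def pair_score(a: GeneRecord | str, b: GeneRecord | str,
               both_strands: bool = True) -> float:
    """Best local alignment raw score between two sequences (over both strands)."""
    sa = a.seq if isinstance(a, GeneRecord) else a
    sb = b.seq if isinstance(b, GeneRecord) else b
    score = _ALIGNER.score(sa, sb)
    if both_strands:
        score = max(score, _ALIGNER.score(revcomp(sa), sb))
    return float(score)


def write_hit_table(hits: Iterable[HomologyHit], path: str | Path) -> None:
    """Blastn-tabular-style TSV (qseqid, sseqid, pident, length, bitscore, evalue)."""
    lines = ["qseqid\tsseqid\tpident\tlength\tbitscore\tevalue"]
    for h in hits:
        lines.append(
            f"{h.query_id}\t{h.subject_id}\t{h.identity * 100:.2f}\t"
            f"{h.aln_len}\t{h.score:.1f}\t{h.evalue:.3g}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def external_backend_search(
    queries: Sequence[GeneRecord],
    subjects: Sequence[GeneRecord],
    params: SearchParams | None = None,
    include_self: bool = False,
) -> list[HomologyHit]:
    """Run an installed ``blastn`` under the same contract as :func:`search`.

    Tabular output is parsed into :class:`HomologyHit`; hits failing the
    minimum alignment length are filtered post hoc, and only the best hit per
    (query, subject) pair is kept.
    """
    params = params or SearchParams()
    if shutil.which("blastn") is None or shutil.which("makeblastdb") is None:
        raise BackendUnavailable("blastn/makeblastdb not found on PATH")
    with tempfile.TemporaryDirectory() as td:
        qpath = Path(td) / "q.fasta"
        spath = Path(td) / "s.fasta"
        write_gene_fasta(queries, qpath)
        write_gene_fasta(subjects, spath)
        dbpath = Path(td) / "db"
        r = subprocess.run(
            ["makeblastdb", "-in", str(spath), "-dbtype", "nucl",
             "-out", str(dbpath)],
            capture_output=True, text=True,
        )
        if r.returncode != 0:
            raise RuntimeError(f"makeblastdb failed: {r.stderr}")
        cmd = [
            "blastn", "-task", "blastn",
            "-query", str(qpath), "-db", str(dbpath),
            "-word_size", str(params.word_size),
            "-evalue", str(params.evalue_max),
            "-outfmt", "6 qseqid sseqid pident length bitscore evalue",
            "-dust", "no",
        ]
        if not params.both_strands:
            cmd += ["-strand", "plus"]
        r = subprocess.run(cmd, capture_output=True, text=True)
        if r.returncode != 0:
            raise RuntimeError(f"blastn failed: {r.stderr}")
        best: dict[tuple[str, str], HomologyHit] = {}
        for line in r.stdout.splitlines():
            qid, sid, pident, length, bits, ev = line.split("\t")
            if qid == sid and not include_self:
                continue
            hit = HomologyHit(
                query_id=qid, subject_id=sid,
                aln_len=int(length), identity=float(pident) / 100.0,
                score=float(bits), evalue=float(ev),
            )
            if hit.aln_len < params.min_aln_len or hit.evalue > params.evalue_max:
                continue
            key = (qid, sid)
            if key not in best or hit.score > best[key].score:
                best[key] = hit
        hits = sorted(best.values(),
                      key=lambda h: (h.query_id, h.evalue, h.subject_id))
        return hits
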