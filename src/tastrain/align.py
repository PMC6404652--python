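"""Pairwise and read-to-marker alignment.

This module is the internal alignment engine for the profiling pipeline:

* :func:`global_align` — Needleman–Wunsch global alignment, used to compute
  the sequence identity that drives gene grouping and to anchor each gene
  variant to its group representative.
* :func:`local_align` — Smith–Waterman local alignment, used by the plasmid
  homolog screen.
* :class:`KmerIndex` / :func:`map_read` — k-mer seeded, banded semi-global
  read mapping onto marker genes, the stand-in for a general-purpose short
  read mapper with a contract reduced to what the profiler consumes:
  accepted/rejected, the covered gene interval, and the observed base at
  every covered gene position (in the gene's forward frame).

Dynamic programming is delegated to :class:`Bio.Align.PairwiseAligner`;
the surrounding code owns scoring conventions, identity definitions,
seeding, banding and acceptance rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterator, Mapping, Sequence

from Bio import Align

__all__ = [
    "ScoringScheme",
    "PairwiseAlignment",
    "ReadAlignment",
    "KmerIndex",
    "global_align",
    "sequence_identity",
    "local_align",
    "build_kmer_index",
    "map_read",
    "reverse_complement",
    "ValidationError",
    "ConfigurationError",
]

DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ValidationError(ValueError):
    """Invalid sequence or parameter input."""


class ConfigurationError(ValueError):
    """Inconsistent configuration (e.g. k-mer size exceeding gene length)."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def check_dna(seq: str, name: str = "sequence") -> str:
    if not seq:
        raise ValidationError(f"{name} is empty")
    if not set(seq) <= DNA_ALPHABET:
        bad = sorted(set(seq) - DNA_ALPHABET)
        raise ValidationError(f"{name} contains non-DNA characters: {bad}")
    return seq


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scores.

    A gap of length L costs ``gap_open + (L - 1) * gap_extend`` (the opening
    position carries ``gap_open``, each further position ``gap_extend``).
    """

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0

    def __post_init__(self) -> None:
        if not self.match > self.mismatch:
            raise ValidationError("match score must exceed mismatch score")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValidationError("gap penalties must be <= 0")


# Alignment operations use query/target vocabulary:
#   "="  match, "X" mismatch, "I" base present only in the query,
#   "D"  base present only in the target.
@dataclass
class PairwiseAlignment:
    operations: list[tuple[str, int]]
    score: float
    identity: float
    query_interval: tuple[int, int]
    target_interval: tuple[int, int]

    def columns(self) -> int:
        return sum(n for _, n in self.operations)


@dataclass
class ReadAlignment:
    """A read placed on a marker gene, reported in the gene's forward frame.

    ``observed`` maps every covered gene position to the base the read shows
    there ("-" when the read carries a deletion of that gene position).
    Read insertions relative to the gene do not consume gene positions and
    are counted in ``n_mismatch`` only.
    """

    read_id: str
    gene_id: str
    strand: str  # "+" or "-"
    gene_interval: tuple[int, int]
    observed: dict[int, str]
    n_mismatch: int
    score: float
    accepted: bool = True


@lru_cache(maxsize=16)
def _make_aligner(scoring: ScoringScheme, mode: str, free_target_ends: bool) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    if free_target_ends:
        # free end gaps in the *first* sequence passed to align(): overhangs
        # of the second sequence cost nothing (semi-global).
        aligner.end_insertion_score = 0.0
    return aligner


def _walk(alignment: Align.Alignment, query: str, target: str) -> list[tuple[str, int]]:
    """CIGAR-style op list from a biopython alignment.

    ``query`` must be the first sequence passed to ``aligner.align`` and
    ``target`` the second.
    """
    coords = alignment.coordinates
    ops: list[tuple[str, int]] = []

    def push(op: str, n: int) -> None:
        if n == 0:
            return
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + n)
        else:
            ops.append((op, n))

    for idx in range(coords.shape[1] - 1):
        q0, q1 = int(coords[0, idx]), int(coords[0, idx + 1])
        t0, t1 = int(coords[1, idx]), int(coords[1, idx + 1])
        if q1 > q0 and t1 > t0:
            for qi, ti in zip(range(q0, q1), range(t0, t1)):
                push("=" if query[qi] == target[ti] else "X", 1)
        elif q1 > q0:
            push("I", q1 - q0)
        elif t1 > t0:
            push("D", t1 - t0)
    return ops


def _identity(ops: Sequence[tuple[str, int]]) -> float:
    total = sum(n for _, n in ops)
    if total == 0:
        return 0.0
    return sum(n for op, n in ops if op == "=") / total


def global_align(query: str, target: str, scoring: ScoringScheme | None = None) -> PairwiseAlignment:
    """Optimal global (Needleman–Wunsch) alignment.

    Identity is matches / alignment columns, gaps counted in the
    denominator.
    """
    scoring = scoring or ScoringScheme()
    check_dna(query, "query")
    check_dna(target, "target")
    aligner = _make_aligner(scoring, "global", False)
    aln = aligner.align(query, target)[0]
    ops = _walk(aln, query, target)
    return PairwiseAlignment(
        operations=ops,
        score=float(aln.score),
        identity=_identity(ops),
        query_interval=(0, len(query)),
        target_interval=(0, len(target)),
    )


def sequence_identity(a: str, b: str, scoring: ScoringScheme | None = None) -> float:
    """Symmetric global-alignment identity.

    Co-optimal alignments can differ in column count, so the raw
    per-alignment identity may depend on argument order; canonicalizing
    the pair makes the value symmetric and deterministic.
    """
    if b < a:
        a, b = b, a
    return global_align(a, b, scoring).identity


def local_align(query: str, target: str, scoring: ScoringScheme | None = None) -> PairwiseAlignment:
    """Best local (Smith–Waterman) alignment of query against target."""
    scoring = scoring or ScoringScheme()
    check_dna(query, "query")
    check_dna(target, "target")
    aligner = _make_aligner(scoring, "local", False)
    alns = aligner.align(query, target)
    if len(alns) == 0 or alns[0].score <= 0:
        return PairwiseAlignment([], 0.0, 0.0, (0, 0), (0, 0))
    aln = alns[0]
    coords = aln.coordinates
    q_int = (int(coords[0, 0]), int(coords[0, -1]))
    t_int = (int(coords[1, 0]), int(coords[1, -1]))
    ops = _walk(aln, query, target)
    return PairwiseAlignment(
        operations=ops,
        score=float(aln.score),
        identity=_identity(ops),
        query_interval=q_int,
        target_interval=t_int,
    )


def read_fastq(path) -> Iterator[tuple[str, str, str]]:
    """Yield (read_id, sequence, qualities) from a Sanger/Illumina-1.8+
    FASTQ file.  Paired files are simply read one after the other; the
    pipeline uses no pairing information."""
    from Bio import SeqIO

    n_records = 0
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            n_records += 1
            quals = "".join(
                chr(q + 33) for q in rec.letter_annotations["phred_quality"]
            )
            yield rec.id, str(rec.seq).upper(), quals
    except ValueError as exc:
        raise ValidationError(
            f"corrupt FASTQ record in {path} near line {n_records * 4 + 1}: {exc}"
        ) from exc


@dataclass
class KmerIndex:
    """Exact k-mer index over a set of genes, covering both strands.

    ``hits[kmer]`` lists ``(gene_id, position, strand)`` where *position* is
    the 0-based start of the k-mer on the gene's forward strand; strand "-"
    means the k-mer equals the reverse complement of that gene window.
    """

    k: int
    sequences: dict[str, str]
    hits: dict[str, list[tuple[str, int, str]]] = field(repr=False, default_factory=dict)

    def lookup(self, kmer: str) -> list[tuple[str, int, str]]:
        return self.hits.get(kmer, [])


def build_kmer_index(genes: Mapping[str, str], k: int = 15) -> KmerIndex:
    if not genes:
        raise ValidationError("no gene sequences to index")
    shortest = min(len(s) for s in genes.values())
    if k > shortest:
        raise ConfigurationError(
            f"k={k} exceeds the shortest gene length ({shortest})"
        )
    hits: dict[str, list[tuple[str, int, str]]] = {}
    for gene_id in sorted(genes):
        seq = genes[gene_id]
        for pos in range(len(seq) - k + 1):
            kmer = seq[pos : pos + k]
            hits.setdefault(kmer, []).append((gene_id, pos, "+"))
            hits.setdefault(reverse_complement(kmer), []).append((gene_id, pos, "-"))
    return KmerIndex(k=k, sequences=dict(genes), hits=hits)


def _seed_positions(read_len: int, k: int) -> Iterator[int]:
    yield from range(0, read_len - k + 1, k)
    if (read_len - k) % k:
        yield read_len - k


def _candidate_loci(read: str, index: KmerIndex) -> dict[tuple[str, str], set[int]]:
    """Collect candidate (gene, strand) -> set of diagonal offsets."""
    k = index.k
    n = len(read)
    out: dict[tuple[str, str], set[int]] = {}
    for pos in _seed_positions(n, k):
        for gene_id, gpos, strand in index.lookup(read[pos : pos + k]):
            if strand == "+":
                diag = gpos - pos
            else:
                # the read maps reverse-complemented; in rc(read) frame the
                # seed starts at n - k - pos
                diag = gpos - (n - k - pos)
            out.setdefault((gene_id, strand), set()).add(diag)
    return out


def _merge_diagonals(diags: set[int], band: int) -> list[int]:
    merged: list[int] = []
    for d in sorted(diags):
        if merged and d - merged[-1] <= band:
            continue
        merged.append(d)
    return merged


def map_read(
    read_id: str,
    read: str,
    index: KmerIndex,
    scoring: ScoringScheme | None = None,
    max_mismatch_frac: float = 0.1,
    qualities: str | None = None,
    min_base_quality: int = 0,
) -> list[ReadAlignment]:
    """Map one read onto the indexed genes.

    Seeds with non-overlapping k-mers, extends each candidate locus with a
    banded semi-global alignment (read global, gene window free at the
    ends), and accepts a placement iff its mismatch+indel fraction is at
    most ``max_mismatch_frac``.  All placements tying the best score are
    returned; an unmappable read yields an empty list.  Base qualities are
    accepted for interface completeness and unused at the default
    ``min_base_quality`` of 0.
    """
    scoring = scoring or ScoringScheme()
    read = read.upper()
    check_dna(read, "read")
    if len(read) < index.k:
        return []
    band = 3 + 2 * max(1, round(max_mismatch_frac * len(read) * 0.2))
    aligner = _make_aligner(scoring, "global", True)
    results: list[ReadAlignment] = []
    seen: set[tuple[str, str, int, int]] = set()
    for (gene_id, strand), diags in sorted(_candidate_loci(read, index).items()):
        gene = index.sequences[gene_id]
        oriented = read if strand == "+" else reverse_complement(read)
        for diag in _merge_diagonals(diags, band):
            win_start = max(0, diag - band)
            win_end = min(len(gene), diag + len(read) + band)
            window = gene[win_start:win_end]
            if len(window) < index.k:
                continue
            aln = aligner.align(oriented, window)[0]
            placement = _placement(
                read_id, gene_id, strand, oriented, window, win_start, aln
            )
            if placement is None:
                continue
            key = (gene_id, strand, *placement.gene_interval)
            if key in seen:
                continue
            seen.add(key)
            frac = placement.n_mismatch / len(read)
            if frac <= max_mismatch_frac:
                results.append(placement)
    if not results:
        return []
    best = max(r.score for r in results)
    results = [r for r in results if r.score == best]
    results.sort(key=lambda r: (r.gene_id, r.strand, r.gene_interval))
    return results


def _placement(
    read_id: str,
    gene_id: str,
    strand: str,
    oriented: str,
    window: str,
    win_start: int,
    aln: Align.Alignment,
) -> ReadAlignment | None:
    coords = aln.coordinates
    observed: dict[int, str] = {}
    n_mismatch = 0
    ncols = coords.shape[1]
    # Leading/trailing window overhang (free end gaps) is skipped: it shows
    # as a D block while the read has not started / after it has ended.
    for idx in range(ncols - 1):
        r0, r1 = int(coords[0, idx]), int(coords[0, idx + 1])
        w0, w1 = int(coords[1, idx]), int(coords[1, idx + 1])
        if r1 > r0 and w1 > w0:
            for ri, wi in zip(range(r0, r1), range(w0, w1)):
                base = oriented[ri]
                observed[win_start + wi] = base
                if base != window[wi]:
                    n_mismatch += 1
        elif r1 > r0:  # read insertion relative to gene
            if 0 < r0 and r1 < len(oriented):
                n_mismatch += r1 - r0
            else:
                # read overhanging the gene end: not a placement we accept
                return None
        elif w1 > w0:  # gene positions absent from the read
            if 0 < r0 < len(oriented):
                n_mismatch += w1 - w0
                for wi in range(w0, w1):
                    observed[win_start + wi] = "-"
            # else: free end gap, ignore
    if not observed:
        return None
    positions = observed.keys()
    return ReadAlignment(
        read_id=read_id,
        gene_id=gene_id,
        strand=strand,
        gene_interval=(min(positions), max(positions) + 1),
        observed=observed,
        n_mismatch=n_mismatch,
        score=float(aln.score),
    )
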