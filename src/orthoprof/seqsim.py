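"""Pairwise local-alignment search across proteomes.

Exact Smith-Waterman with affine gaps stands in for a heuristic BLASTP
search: at the scale of the datasets this package targets, exactness and
determinism matter more than seed-and-extend speed. Scores are normalized
to bits with fixed Karlin-Altschul parameters and converted to E-values
against a per-organism search space (m = query length, n = residues in the
target organism's proteome), so that best-hit ranking within one organism
is scale-consistent.

The dynamic programming itself is Biopython's PairwiseAligner (a C
implementation of the Gotoh algorithm in local mode); this module owns the
scoring scheme, the statistics, and the search orchestration. A gap of
length g costs open + g*extend.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .io import VALID_RESIDUES, Proteome

LN2 = math.log(2.0)


def _build_matrix(name: str) -> substitution_matrices.Array:
    """Load a named substitution matrix with the ambiguity residue X
    rescored to 0 against everything (neutral, never attractive)."""
    m = substitution_matrices.load(name).copy()
    if "X" in m.alphabet:
        for a in m.alphabet:
            m["X", a] = 0.0
            m[a, "X"] = 0.0
    return m


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus gap and Karlin-Altschul parameters.

    Defaults correspond to BLOSUM62 with gap open 11 / extend 1, the
    ungapped-approximation constants lambda = 0.267 and K = 0.041.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    kappa: float = 0.041

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.lam <= 0 or self.kappa <= 0:
            raise ValueError("Karlin-Altschul lambda and K must be positive")

    @property
    def matrix(self) -> substitution_matrices.Array:
        return _cached_matrix(self.matrix_name)

    def aligner(self) -> Align.PairwiseAligner:
        return _cached_aligner(self.matrix_name, self.gap_open, self.gap_extend)

    def score_pair(self, a: str, b: str) -> float:
        """Substitution score of two single residues."""
        return float(self.matrix[a, b])


@lru_cache(maxsize=8)
def _cached_matrix(name: str) -> substitution_matrices.Array:
    return _build_matrix(name)


@lru_cache(maxsize=8)
def _cached_aligner(matrix_name: str, gap_open: int, gap_extend: int) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _cached_matrix(matrix_name)
    # first gapped position costs open+extend, each further position extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


@dataclass
class AlignmentHit:
    """One scored local alignment. Intervals are 1-based closed; a score-0
    hit (no positive-scoring alignment) has empty intervals (0, 0)."""

    query: str
    subject: str
    score: int
    bits: float
    evalue: float
    qstart: int
    qend: int
    sstart: int
    send: int
    qlen: int
    slen: int
    identities: int = 0
    mismatches: int = 0
    gap_opens: int = 0
    aln_len: int = 0

    @property
    def query_coverage(self) -> float:
        if self.qstart < 1 or self.qend < self.qstart or self.qlen == 0:
            return 0.0
        return (self.qend - self.qstart + 1) / self.qlen

    @property
    def subject_coverage(self) -> float:
        if self.sstart < 1 or self.send < self.sstart or self.slen == 0:
            return 0.0
        return (self.send - self.sstart + 1) / self.slen

    @property
    def pident(self) -> float:
        return 100.0 * self.identities / self.aln_len if self.aln_len else 0.0

    def to_outfmt6_row(self, native: bool = True) -> list:
        row = [
            self.query, self.subject, round(self.pident, 2), self.aln_len,
            self.mismatches, self.gap_opens, self.qstart, self.qend,
            self.sstart, self.send, float(f"{self.evalue:.3g}"), round(self.bits, 2),
        ]
        if native:
            row += [round(self.query_coverage, 4), self.qlen, self.slen]
        return row

    def swapped(self, evalue: float) -> "AlignmentHit":
        """The same alignment viewed with query and subject exchanged."""
        return AlignmentHit(
            query=self.subject, subject=self.query, score=self.score,
            bits=self.bits, evalue=evalue,
            qstart=self.sstart, qend=self.send, sstart=self.qstart, send=self.qend,
            qlen=self.slen, slen=self.qlen, identities=self.identities,
            mismatches=self.mismatches, gap_opens=self.gap_opens, aln_len=self.aln_len,
        )


def _validate_sequence(seq: str, role: str) -> None:
    if not seq:
        raise ValueError(f"{role} sequence is empty")
    bad = set(seq) - VALID_RESIDUES
    if bad:
        raise ValueError(f"{role} sequence contains invalid residues {sorted(bad)}")


def bit_score(score: float, scheme: ScoringScheme) -> float:
    """Karlin-Altschul normalized score: (lambda*S - ln K) / ln 2."""
    if score < 0:
        raise ValueError(f"raw score must be non-negative, got {score}")
    return (scheme.lam * score - math.log(scheme.kappa)) / LN2


def e_value(bits: float, m: int, n: int) -> float:
    """Expected chance hits of >= this bit score in an m x n search space."""
    if m < 1 or n < 1:
        raise ValueError(f"search-space dimensions must be positive, got m={m}, n={n}")
    return m * n * math.pow(2.0, -bits)


def smith_waterman(a: str, b: str, scheme: ScoringScheme | None = None,
                   m: int | None = None, n: int | None = None) -> AlignmentHit:
    """Best local alignment of ``a`` (query) vs ``b`` (subject).

    ``m``/``n`` override the search-space dimensions for the E-value
    (defaulting to the two sequence lengths). If no positive-scoring
    alignment exists, returns a hit with score 0 and empty intervals.
    """
    if scheme is None:
        scheme = ScoringScheme()
    _validate_sequence(a, "query")
    _validate_sequence(b, "subject")
    aligner = scheme.aligner()
    raw = aligner.score(a, b)
    m = m if m is not None else len(a)
    n = n if n is not None else len(b)
    if raw <= 0:
        bits = bit_score(0, scheme)
        return AlignmentHit(
            query="query", subject="subject", score=0, bits=bits,
            evalue=e_value(bits, m, n), qstart=0, qend=0, sstart=0, send=0,
            qlen=len(a), slen=len(b),
        )
    aln = aligner.align(a, b)[0]
    qblocks, sblocks = aln.aligned
    counts = aln.counts()
    gap_opens = 0
    for i in range(len(qblocks) - 1):
        if qblocks[i + 1][0] > qblocks[i][1]:
            gap_opens += 1
        if sblocks[i + 1][0] > sblocks[i][1]:
            gap_opens += 1
    score = int(round(raw))
    bits = bit_score(score, scheme)
    return AlignmentHit(
        query="query", subject="subject", score=score, bits=bits,
        evalue=e_value(bits, m, n),
        qstart=int(qblocks[0][0]) + 1, qend=int(qblocks[-1][1]),
        sstart=int(sblocks[0][0]) + 1, send=int(sblocks[-1][1]),
        qlen=len(a), slen=len(b),
        identities=int(counts.identities), mismatches=int(counts.mismatches),
        gap_opens=gap_opens,
        aln_len=int(counts.identities + counts.mismatches + counts.gaps),
    )


def _kmer_set(seq: str, k: int) -> frozenset[str]:
    return frozenset(seq[i:i + k] for i in range(len(seq) - k + 1))


def search_all(
    proteomes: Sequence[Proteome],
    scheme: ScoringScheme | None = None,
    e_cutoff: float = 1e-10,
    prefilter: bool = True,
    kmer_size: int = 4,
    min_shared_kmers: int = 2,
    include_intra: bool = False,
) -> list[AlignmentHit]:
    """All-vs-all best-local-alignment search across organisms.

    Emits one hit per ordered (query, subject) pair whose E-value is at or
    below ``e_cutoff``; same-organism comparisons are skipped unless
    ``include_intra``. The k-mer prefilter skips pairs sharing fewer than
    ``min_shared_kmers`` distinct exact ``kmer_size``-mers; it is a speed
    device whose equivalence to the exhaustive search is asserted in tests.
    Output sorted by (query id, E-value, subject id).
    """
    if scheme is None:
        scheme = ScoringScheme()
    if len(proteomes) < 2 and not include_intra:
        raise ValueError("need at least 2 proteomes for a cross-organism search")
    if e_cutoff <= 0:
        raise ValueError("e_cutoff must be positive")

    org_of: dict[str, str] = {}
    entries: list[tuple[str, str, str]] = []  # (protein id, organism, sequence)
    org_residues: dict[str, int] = {}
    for prot in proteomes:
        org_residues[prot.organism] = prot.total_residues
        for pid, seq in prot:
            if pid in org_of:
                raise ValueError(f"duplicate protein id across database: {pid!r}")
            org_of[pid] = prot.organism
            entries.append((pid, prot.organism, seq))

    kmers = {pid: _kmer_set(seq, kmer_size) for pid, _, seq in entries} if prefilter else {}
    aligner = scheme.aligner()
    hits: list[AlignmentHit] = []
    for i in range(len(entries)):
        pid_i, org_i, seq_i = entries[i]
        for j in range(i + 1, len(entries)):
            pid_j, org_j, seq_j = entries[j]
            if org_i == org_j and not include_intra:
                continue
            if prefilter and len(kmers[pid_i] & kmers[pid_j]) < min_shared_kmers:
                continue
            raw = aligner.score(seq_i, seq_j)
            if raw <= 0:
                continue
            bits = bit_score(int(round(raw)), scheme)
            e_ij = e_value(bits, len(seq_i), org_residues[org_j])
            e_ji = e_value(bits, len(seq_j), org_residues[org_i])
            if e_ij > e_cutoff and e_ji > e_cutoff:
                continue
            hit = smith_waterman(seq_i, seq_j, scheme, m=len(seq_i), n=org_residues[org_j])
            hit.query, hit.subject = pid_i, pid_j
            if e_ij <= e_cutoff:
                hits.append(hit)
            if e_ji <= e_cutoff:
                hits.append(hit.swapped(evalue=e_ji))
    hits.sort(key=lambda h: (h.query, h.evalue, h.subject))
    return hits
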