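"""Pairwise genome comparison: reciprocal-best-hit AAI and nucleotide identity.

Hits are scored by exact global (Needleman-Wunsch) edit distance computed
with edlib, which is deterministic and exact for desk-scale protein sets —
no heuristic search. For a pair of proteins, identity is matches / aligned
columns from the optimal alignment path (gap columns count as non-matching
columns in the path but are excluded from the nucleotide-identity
denominator, where noted). Coverage of a global alignment is the length
ratio min(|a|,|b|) / max(|a|,|b|). Ties in best-hit selection break by
protein id order.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import edlib

from sagqc.synthetic import InputError, ParameterError

__all__ = [
    "ProteinSet",
    "RBHPair",
    "UndefinedStatisticError",
    "reciprocal_best_hits",
    "aai",
    "shared_protein_count",
    "pairwise_nt_identity",
]

_CIGAR_RE = re.compile(r"(\d+)([=XID])")


class UndefinedStatisticError(ValueError):
    """A summary statistic has no value on the given input (e.g. AAI of
    zero pairs) — distinct from a legitimate zero."""


@dataclass(frozen=True)
class ProteinSet:
    genome_id: str
    proteins: tuple[tuple[str, str], ...]

    def __init__(self, genome_id: str, proteins: Sequence[tuple[str, str]]):
        object.__setattr__(self, "genome_id", genome_id)
        object.__setattr__(self, "proteins", tuple((str(i), str(s)) for i, s in proteins))
        ids = [i for i, _ in self.proteins]
        if len(set(ids)) != len(ids):
            raise InputError("protein ids must be unique within a set")

    def __len__(self) -> int:
        return len(self.proteins)


@dataclass(frozen=True)
class RBHPair:
    protein_id_a: str
    protein_id_b: str
    identity: float


def _alignment_stats(a: str, b: str) -> tuple[int, int, int]:
    """(matches, aligned_columns, non_gap_columns) of the optimal NW path.

    The pair is oriented canonically (lexicographically smaller sequence
    first) so that tie-breaking among equally optimal paths cannot make the
    statistics depend on argument order.
    """
    if b < a:
        a, b = b, a
    res = edlib.align(a, b, mode="NW", task="path")
    matches = cols = nongap = 0
    for n, op in _CIGAR_RE.findall(res["cigar"]):
        n = int(n)
        cols += n
        if op == "=":
            matches += n
            nongap += n
        elif op == "X":
            nongap += n
    return matches, cols, nongap


def reciprocal_best_hits(
    a: ProteinSet,
    b: ProteinSet,
    min_identity: float = 0.30,
    min_coverage: float = 0.70,
) -> list[RBHPair]:
    """Pairs (p, q) where q is p's best hit in b and p is q's best in a,
    passing identity and coverage thresholds.

    Best = smallest global edit distance; ties break by protein id order.
    """
    if len(a) == 0 or len(b) == 0:
        raise InputError("protein sets must be non-empty")
    if not (0.0 <= min_identity <= 1.0 and 0.0 <= min_coverage <= 1.0):
        raise ParameterError("thresholds must be fractions in [0,1]")

    prots_a = sorted(a.proteins)
    prots_b = sorted(b.proteins)
    dist = {}
    for pid, pseq in prots_a:
        for qid, qseq in prots_b:
            dist[pid, qid] = edlib.align(pseq, qseq, mode="NW")["editDistance"]

    best_in_b = {pid: min(prots_b, key=lambda q: (dist[pid, q[0]], q[0]))[0]
                 for pid, _ in prots_a}
    best_in_a = {qid: min(prots_a, key=lambda p: (dist[p[0], qid], p[0]))[0]
                 for qid, _ in prots_b}

    seq_a = dict(prots_a)
    seq_b = dict(prots_b)
    pairs: list[RBHPair] = []
    for pid, qid in best_in_b.items():
        if best_in_a[qid] != pid:
            continue
        sa, sb = seq_a[pid], seq_b[qid]
        matches, cols, _ = _alignment_stats(sa, sb)
        identity = matches / cols if cols else 0.0
        coverage = min(len(sa), len(sb)) / max(len(sa), len(sb))
        if identity >= min_identity and coverage >= min_coverage:
            pairs.append(RBHPair(pid, qid, identity))
    return pairs


def aai(pairs: Sequence[RBHPair]) -> float:
    """Average amino acid identity: unweighted mean pair identity, percent."""
    if not pairs:
        raise UndefinedStatisticError("AAI undefined with zero reciprocal pairs")
    return 100.0 * sum(p.identity for p in pairs) / len(pairs)


def shared_protein_count(pairs: Sequence[RBHPair]) -> int:
    return len(pairs)


def pairwise_nt_identity(seq_a: str, seq_b: str, aligned: bool = False) -> float:
    """Percent identity of two nucleotide sequences.

    aligned=True: sequences are pre-aligned rows of equal length; columns
    where either has a gap ('-') are excluded from the denominator.
    aligned=False: a global alignment is computed first; identity is
    matches / non-gap aligned columns.
    """
    if not seq_a or not seq_b:
        raise InputError("sequences must be non-empty")
    if aligned:
        if len(seq_a) != len(seq_b):
            raise InputError("pre-aligned sequences must have equal length")
        matches = compared = 0
        for x, y in zip(seq_a.upper(), seq_b.upper()):
            if x == "-" or y == "-":
                continue
            compared += 1
            if x == y:
                matches += 1
        if compared == 0:
            raise InputError("no comparable (gap-free) columns")
        return 100.0 * matches / compared
    matches, _, nongap = _alignment_stats(seq_a.upper(), seq_b.upper())
    if nongap == 0:
        raise InputError("alignment has no comparable columns")
    return 100.0 * matches / nongap
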