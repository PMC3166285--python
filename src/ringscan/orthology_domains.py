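"""Reciprocal-best-hit orthology and domain-architecture comparison.

Putative orthologs are reciprocal best hits (RBBH): protein pairs that are
each other's top-ranking cross-proteome hit.  Ranking is by bit score, with
ties broken by lower e-value, then higher percent identity, then
lexicographic subject id; self-hits are removed before ranking.  Domain
architectures (ordered domain-name lists) are compared by longest common
subsequence: identical, insertion (one list a strict subsequence of the
other), deletion, rearrangement (same multiset, different order) or other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ringscan.io_model import DomainArchitecture, HitRecord


@dataclass(frozen=True)
class OrthologPair:
    id_a: str
    id_b: str
    score_ab: float
    score_ba: float
    evalue_ab: float
    evalue_ba: float


@dataclass
class ArchitectureDiff:
    relation: str  # identical | insertion | deletion | rearrangement | other
    inserted: list[tuple[str, int]] = field(default_factory=list)
    deleted: list[tuple[str, int]] = field(default_factory=list)


def _rank_key(hit: HitRecord) -> tuple:
    # best first: highest bit score, lowest e-value, highest identity,
    # lexicographically smallest subject id
    return (-hit.bit_score, hit.e_value, -hit.pct_identity, hit.subject_id)


def best_hits(hits: list[HitRecord]) -> dict[str, HitRecord]:
    """Per query, the best-ranking hit (self-hits removed first)."""
    best: dict[str, HitRecord] = {}
    for hit in hits:
        if hit.query_id == hit.subject_id:
            continue
        cur = best.get(hit.query_id)
        if cur is None or _rank_key(hit) < _rank_key(cur):
            best[hit.query_id] = hit
    return best


def rbbh(hits_ab: list[HitRecord], hits_ba: list[HitRecord]) -> list[OrthologPair]:
    """Reciprocal best hits between two directional hit tables."""
    best_ab = best_hits(hits_ab)
    best_ba = best_hits(hits_ba)
    pairs = []
    for a, hit_ab in best_ab.items():
        b = hit_ab.subject_id
        hit_ba = best_ba.get(b)
        if hit_ba is not None and hit_ba.subject_id == a:
            pairs.append(
                OrthologPair(
                    id_a=a,
                    id_b=b,
                    score_ab=hit_ab.bit_score,
                    score_ba=hit_ba.bit_score,
                    evalue_ab=hit_ab.e_value,
                    evalue_ba=hit_ba.e_value,
                )
            )
    pairs.sort(key=lambda p: p.id_a)
    return pairs


def _lcs_indices(a: list[str], b: list[str]) -> list[tuple[int, int]]:
    """Index pairs of one longest common subsequence of two name lists."""
    n, m = len(a), len(b)
    L = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n - 1, -1, -1):
        for j in range(m - 1, -1, -1):
            if a[i] == b[j]:
                L[i][j] = 1 + L[i + 1][j + 1]
            else:
                L[i][j] = max(L[i + 1][j], L[i][j + 1])
    out = []
    i = j = 0
    while i < n and j < m:
        if a[i] == b[j]:
            out.append((i, j))
            i += 1
            j += 1
        elif L[i + 1][j] >= L[i][j + 1]:
            i += 1
        else:
            j += 1
    return out


def compare_architectures(
    arch_a: DomainArchitecture, arch_b: DomainArchitecture
) -> ArchitectureDiff:
    """Ordered domain-name comparison of two architectures.

    Insertion/deletion positions are reported 1-based on the longer list
    (e.g. BIR,BIR,BIR,RING vs BIR,BIR,BIR,CARD,RING -> CARD inserted at
    position 4).
    """
    if not arch_a.domains or not arch_b.domains:
        raise ValueError("architectures must be non-empty")
    a, b = arch_a.names, arch_b.names
    if a == b:
        return ArchitectureDiff(relation="identical")
    lcs = _lcs_indices(a, b)
    matched_a = {i for i, _ in lcs}
    matched_b = {j for _, j in lcs}
    extra_a = [(a[i], i + 1) for i in range(len(a)) if i not in matched_a]
    extra_b = [(b[j], j + 1) for j in range(len(b)) if j not in matched_b]
    if len(lcs) == len(a) and len(a) < len(b):
        return ArchitectureDiff(relation="insertion", inserted=extra_b)
    if len(lcs) == len(b) and len(b) < len(a):
        return ArchitectureDiff(relation="deletion", deleted=extra_a)
    if sorted(a) == sorted(b):
        return ArchitectureDiff(relation="rearrangement",
                                inserted=extra_b, deleted=extra_a)
    return ArchitectureDiff(relation="other", inserted=extra_b, deleted=extra_a)
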