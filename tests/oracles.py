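"""Independent brute-force oracles used to verify the package's fast paths.

Everything here is deliberately naive — exact rational arithmetic,
all-pairs scans, O(n^2)/O(n^3) loops — and shares no code with the
implementations it checks.
"""

from __future__ import annotations

import re
from fractions import Fraction
from math import comb
from typing import Dict, List, Mapping, Set, Tuple

import numpy as np

TAG_RE = re.compile(r"(?=(CATG[ACGT]{17}))")


def scan_tags(reference: Mapping[str, str]) -> List[Tuple[str, str, int]]:
    """All (tag, gene, offset) triples via a regex scan of each transcript."""
    out = []
    for gene_id, seq in reference.items():
        for m in TAG_RE.finditer(seq.upper()):
            out.append((m.group(1), gene_id, m.start()))
    return out


def hamming(a: str, b: str) -> int:
    assert len(a) == len(b)
    return sum(x != y for x, y in zip(a, b))


def map_tags_all_pairs(
    clean: Mapping[str, int],
    index_keys: Mapping[str, Set[str]],
    max_mismatch: int,
) -> Tuple[Dict[str, int], int, int, int]:
    """All-pairs Hamming mapping oracle.

    `index_keys` maps each indexed tag to its set of genes. Returns
    (gene_counts, distinct_mapped, ambiguous_distinct, unmapped_distinct)
    with exact-match priority and anchor positions 0-3 immutable.
    """
    gene_counts: Dict[str, int] = {}
    n_mapped = n_ambig = n_unmapped = 0
    for tag, count in clean.items():
        if tag in index_keys:
            genes = set(index_keys[tag])
        else:
            genes = set()
            if max_mismatch == 1:
                for key, key_genes in index_keys.items():
                    if tag[:4] == key[:4] and hamming(tag, key) == 1:
                        genes |= key_genes
        if len(genes) == 1:
            gene = next(iter(genes))
            gene_counts[gene] = gene_counts.get(gene, 0) + count
            n_mapped += 1
        elif len(genes) > 1:
            n_ambig += 1
        else:
            n_unmapped += 1
    return gene_counts, n_mapped, n_ambig, n_unmapped


def exact_test_enumeration(x: int, y: int, n1: int, n2: int) -> Fraction:
    """Two-sided conditional binomial p by full enumeration over all splits
    of n = x + y, in exact rational arithmetic."""
    n = x + y
    if n == 0:
        return Fraction(1)
    prob = Fraction(n2, n1 + n2)
    pmf = [comb(n, j) * prob**j * (1 - prob) ** (n - j) for j in range(n + 1)]
    lower = sum(pmf[: y + 1])
    upper = sum(pmf[y:])
    return min(Fraction(1), 2 * min(lower, upper))


def bh_step_up(p_values) -> np.ndarray:
    """Literal O(n^2) BH: q_i = min over p_j >= p_i of m * p_j / rank(p_j)."""
    p = list(map(float, p_values))
    m = len(p)
    ranks = {}
    for rank, (value, idx) in enumerate(sorted((v, i) for i, v in enumerate(p)), start=1):
        ranks[idx] = rank
    q = []
    for i in range(m):
        candidates = [
            m * p[j] / ranks[j]
            for j in range(m)
            if p[j] > p[i] or (p[j] == p[i] and ranks[j] >= ranks[i])
        ]
        q.append(min(1.0, min(candidates)))
    return np.array(q)


def hypergeom_upper_tail_exact(k: int, K: int, n: int, N: int) -> Fraction:
    """P(X >= k), X ~ Hypergeometric(N, K, n), via exact combinatorial sums."""
    total = comb(N, n)
    acc = Fraction(0)
    for j in range(k, min(K, n) + 1):
        acc += Fraction(comb(K, j) * comb(N - K, n - j), total)
    return acc


def naive_linkage(dist: np.ndarray, method: str) -> np.ndarray:
    """O(n^3) agglomerative linkage producing a scipy-format merge matrix.

    Ties are broken by the smallest (i, j) pair, matching scipy's behavior on
    distinct distances (ties are avoided in test fixtures).
    """
    n = dist.shape[0]
    active = {i: [i] for i in range(n)}  # cluster id -> leaf members
    ids = {i: i for i in range(n)}  # cluster id -> merge-matrix id
    d = {(i, j): float(dist[i, j]) for i in range(n) for j in range(i + 1, n)}
    merges = []
    next_id = n
    while len(active) > 1:
        (i, j), height = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        members = active[i] + active[j]
        new_d = {}
        for k in active:
            if k in (i, j):
                continue
            a, b = (min(i, k), max(i, k)), (min(j, k), max(j, k))
            if method == "average":
                ni, nj = len(active[i]), len(active[j])
                value = (d[a] * ni + d[b] * nj) / (ni + nj)
            else:  # complete
                value = max(d[a], d[b])
            new_d[k] = value
        merges.append([min(ids[i], ids[j]), max(ids[i], ids[j]), height, len(members)])
        del active[i], active[j]
        d = {key: value for key, value in d.items() if i not in key and j not in key}
        active[i] = members  # reuse slot i for the merged cluster
        ids[i] = next_id
        for k, value in new_d.items():
            d[(min(i, k), max(i, k))] = value
        next_id += 1
    return np.array(merges)
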