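"""Plasma-cell heavy-chain clone grouping and divergence statistics.

Clones are sets of sequences descended from one naive B cell, grouped here
by shared V gene, J gene and junction length with single-linkage merging at
a 0.15 normalised junction Hamming distance (a standard repertoire
heuristic; a precomputed clone_id column is honoured as-is). Per clone the
package reports amino-acid divergence from the inferred germline and mean
pairwise divergence, separately for the CDR3 and the full-length chain, plus
isotype composition.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np

AMBIGUOUS = "X"


@dataclass
class BcrSequence:
    cell_id: str
    junction_nt: str
    junction_aa: str
    full_aa: str  # aligned, gap-free, same length as germline
    v_call: str
    j_call: str
    isotype: str
    light_chain_id: str
    locus: str = "IGH"
    clone_id: str | None = None
    germline_full_aa: str | None = None
    cdr3_aa_span: tuple[int, int] | None = None


@dataclass
class Clone:
    clone_id: str
    members: list[BcrSequence]
    germline_full_aa: str
    cdr3_aa_span: tuple[int, int]

    @property
    def size(self) -> int:
        return len(self.members)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        self.parent[self.find(i)] = self.find(j)


def _hamming_norm(a: str, b: str) -> float:
    if len(a) != len(b):
        raise ValueError("sequences of unequal length")
    return sum(x != y for x, y in zip(a, b)) / len(a)


def _consensus(seqs: list[str]) -> str:
    out = []
    for column in zip(*seqs):
        counts = Counter(column)
        top = max(counts.items(), key=lambda kv: (kv[1], -ord(kv[0][0])))
        out.append(top[0])
    return "".join(out)


def _clone_germline(members: list[BcrSequence]) -> str:
    fixtures = {m.germline_full_aa for m in members if m.germline_full_aa}
    if len(fixtures) == 1:
        return fixtures.pop()
    return _consensus([m.full_aa for m in members])


def group_clones(
    seqs: list[BcrSequence], distance_threshold: float = 0.15
) -> list[Clone]:
    """Single-linkage clonal grouping by V/J/junction-length partitions.

    With a clone_id on every input sequence the grouping is a pass-through
    of that partition. The clone germline is the supplied fixture germline
    when members agree on one, else the column-wise majority consensus.
    """
    loci = {s.locus for s in seqs}
    if len(loci) > 1:
        raise ValueError(f"mixed loci: {sorted(loci)}")
    if seqs and all(s.clone_id is not None for s in seqs):
        partition: dict[str, list[BcrSequence]] = {}
        for s in seqs:
            partition.setdefault(s.clone_id, []).append(s)
        return [
            _make_clone(cid, members) for cid, members in sorted(partition.items())
        ]
    buckets: dict[tuple[str, str, int], list[int]] = {}
    for i, s in enumerate(seqs):
        buckets.setdefault((s.v_call, s.j_call, len(s.junction_nt)), []).append(i)
    uf = _UnionFind(len(seqs))
    for members in buckets.values():
        for ai in range(len(members)):
            for bi in range(ai + 1, len(members)):
                i, j = members[ai], members[bi]
                if _hamming_norm(seqs[i].junction_nt, seqs[j].junction_nt) <= distance_threshold:
                    uf.union(i, j)
    groups: dict[int, list[BcrSequence]] = {}
    for i, s in enumerate(seqs):
        groups.setdefault(uf.find(i), []).append(s)
    clones = []
    for n, (_, members) in enumerate(
        sorted(groups.items(), key=lambda kv: min(m.cell_id for m in kv[1]))
    ):
        clones.append(_make_clone(f"clone{n + 1}", members))
    return clones


def _make_clone(clone_id: str, members: list[BcrSequence]) -> Clone:
    spans = {m.cdr3_aa_span for m in members if m.cdr3_aa_span}
    if len(spans) == 1:
        span = spans.pop()
    else:
        # fall back to the junction length anchored at the alignment start
        span = (0, len(members[0].junction_aa))
    return Clone(
        clone_id=clone_id,
        members=list(members),
        germline_full_aa=_clone_germline(members),
        cdr3_aa_span=span,
    )


def top_clones(clones: list[Clone]) -> list[Clone]:
    """All clones tied at the maximum size."""
    if not clones:
        raise ValueError("no clones")
    max_size = max(c.size for c in clones)
    return [c for c in clones if c.size == max_size]


def enforce_light_chain(clone: Clone) -> Clone:
    """Keep only members using the clone's majority light chain.

    Members without a light-chain identifier are removed with a warning; a
    tie in the majority keeps the lexicographically smallest chain id.
    """
    with_lc = [m for m in clone.members if m.light_chain_id]
    if len(with_lc) < len(clone.members):
        warnings.warn(
            f"{clone.clone_id}: removing {len(clone.members) - len(with_lc)} "
            "member(s) without light_chain_id",
            stacklevel=2,
        )
    if not with_lc:
        return Clone(clone.clone_id, [], clone.germline_full_aa, clone.cdr3_aa_span)
    counts = Counter(m.light_chain_id for m in with_lc)
    best = max(counts.values())
    tied = sorted(lc for lc, n in counts.items() if n == best)
    if len(tied) > 1:
        warnings.warn(
            f"{clone.clone_id}: light-chain majority tie {tied}; keeping {tied[0]}",
            stacklevel=2,
        )
    keep_lc = tied[0]
    members = [m for m in with_lc if m.light_chain_id == keep_lc]
    return Clone(clone.clone_id, members, clone.germline_full_aa, clone.cdr3_aa_span)


def _region_slice(clone: Clone, region: str) -> slice:
    if region == "full":
        return slice(0, len(clone.germline_full_aa))
    if region == "cdr3":
        lo, hi = clone.cdr3_aa_span
        if hi <= lo:
            raise ValueError("zero-length CDR3 region")
        return slice(lo, hi)
    if region == "full_minus_cdr3":
        raise ValueError("use divergence with region='full' and subtract explicitly")
    raise ValueError(f"unknown region {region!r}")


def _aa_divergence(a: str, b: str) -> float:
    pairs = [(x, y) for x, y in zip(a, b) if AMBIGUOUS not in (x, y)]
    if not pairs:
        raise ValueError("no unambiguous positions in region")
    return sum(x != y for x, y in pairs) / len(pairs)


def divergence_from_germline(clone: Clone, region: str = "cdr3") -> float:
    """Mean per-member amino-acid Hamming proportion to the clone germline."""
    sl = _region_slice(clone, region)
    germ = clone.germline_full_aa[sl]
    if len(germ) == 0:
        raise ValueError("zero-length region")
    vals = [_aa_divergence(m.full_aa[sl], germ) for m in clone.members]
    return float(np.mean(vals))


def pairwise_divergence(clone: Clone, region: str = "cdr3") -> float | None:
    """Mean amino-acid Hamming proportion over all unordered member pairs.

    Undefined (None) for single-member clones.
    """
    if clone.size < 2:
        return None
    sl = _region_slice(clone, region)
    seqs = [m.full_aa[sl] for m in clone.members]
    if len(seqs[0]) == 0:
        raise ValueError("zero-length region")
    vals = [
        _aa_divergence(seqs[i], seqs[j])
        for i in range(len(seqs))
        for j in range(i + 1, len(seqs))
    ]
    return float(np.mean(vals))


def isotype_composition(clone: Clone) -> dict[str, float]:
    """Member proportions per isotype, summing to 1."""
    counts = Counter(m.isotype for m in clone.members)
    total = sum(counts.values())
    return {iso: n / total for iso, n in sorted(counts.items())}
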