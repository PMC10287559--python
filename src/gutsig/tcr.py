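"""TCR CDR3 trimming, motif statistics and TRBD2 reading-frame census.

The central operation trims each CDR3 amino-acid sequence to the span
between the leftmost and rightmost residue whose codon differs from the
germline (point mutation, silent or missense) or overlaps non-templated
N-region nucleotides — isolating the non-germline-encoded core in which
motifs such as leucine-alanine (LA) are counted.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

# standard nuclear codon table, stops rendered "*"
_BASES = "TCAG"
_AMINO = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODON_TABLE = {
    a + b + c: _AMINO[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}

N_REGION = "N-region"


def translate(nt: str) -> str:
    """Translate ``nt`` codon by codon, dropping any trailing partial codon."""
    return "".join(CODON_TABLE[nt[i : i + 3]] for i in range(0, len(nt) - len(nt) % 3, 3))


@dataclass
class TcrChain:
    cell_id: str
    locus: str
    v_call: str
    d_call: str
    j_call: str
    junction_nt: str
    junction_aa: str
    productive: bool
    codon_alignment: list[str] = field(default_factory=list)
    subset: str = ""
    read_count: int = 1
    patient: str = ""


@dataclass
class TrimmedCdr3:
    """Half-open span [start, end) into junction_aa; empty when unmutated."""

    start: int
    end: int
    trimmed_aa: str


def filter_chains(chains: list[TcrChain]) -> list[TcrChain]:
    """Remove nonproductive chains and deduplicate per (cell, locus).

    Among same-locus chains sharing a barcode the one with the highest read
    support wins; ties go to the lexicographically smallest junction.
    """
    best: dict[tuple[str, str], TcrChain] = {}
    for ch in chains:
        if not ch.productive:
            continue
        key = (ch.cell_id, ch.locus)
        cur = best.get(key)
        if cur is None or (ch.read_count, _neg(ch.junction_nt)) > (
            cur.read_count,
            _neg(cur.junction_nt),
        ):
            best[key] = ch
    return list(best.values())


def _neg(s: str) -> tuple[int, ...]:
    # invert lexicographic order so that max() prefers the smallest sequence
    return tuple(-ord(c) for c in s)


def trim_cdr3(chain: TcrChain, include_n_regions: bool = True) -> TrimmedCdr3:
    """Trim the CDR3 to its non-germline-supported core.

    A position is mutated iff its codon differs from the aligned germline
    codon at any nucleotide, or (by default) overlaps an N-region. The
    trimmed span runs from the leftmost to the rightmost mutated amino acid,
    inclusive; with no mutated position the trimmed sequence is empty.
    """
    aa = chain.junction_aa
    aln = chain.codon_alignment
    if len(aln) != len(aa) or len(chain.junction_nt) < 3 * len(aa):
        raise ValueError(
            f"malformed codon alignment for {chain.cell_id}: "
            f"{len(aln)} entries for {len(aa)} residues"
        )
    mutated = []
    for i, germ in enumerate(aln):
        codon = chain.junction_nt[3 * i : 3 * i + 3]
        if germ == N_REGION:
            mutated.append(include_n_regions)
        else:
            if len(germ) != 3:
                raise ValueError(f"malformed germline codon {germ!r} at position {i}")
            mutated.append(codon != germ)
    idx = [i for i, m in enumerate(mutated) if m]
    if not idx:
        return TrimmedCdr3(start=0, end=0, trimmed_aa="")
    lo, hi = idx[0], idx[-1] + 1
    return TrimmedCdr3(start=lo, end=hi, trimmed_aa=aa[lo:hi])


def motif_proportion(
    trimmed: pd.DataFrame, motif: str = "LA"
) -> pd.DataFrame:
    """Per-(patient, subset) proportion of chains whose trimmed CDR3 contains
    ``motif`` as a contiguous substring.

    ``trimmed`` needs columns patient, subset, trimmed_aa. Groups with no
    chains are absent; the proportion of an empty group is undefined.
    """
    df = trimmed.copy()
    df["has_motif"] = df["trimmed_aa"].str.contains(motif, regex=False)
    out = (
        df.groupby(["patient", "subset"])["has_motif"]
        .agg(proportion="mean", n_chains="size")
        .reset_index()
    )
    return out


def compare_motif_groups(
    proportions: pd.DataFrame, subset_a: str, subset_b: str
) -> float:
    """Two-sided Wilcoxon rank-sum p comparing per-patient motif proportions."""
    a = proportions.loc[proportions["subset"] == subset_a, "proportion"]
    b = proportions.loc[proportions["subset"] == subset_b, "proportion"]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both subsets need at least one patient")
    return float(mannwhitneyu(a, b, alternative="two-sided").pvalue)


def trbd2_frame_census(trbd2_nt: str, motif: str = "LA") -> set[int]:
    """Reading-frame offsets (subset of {0, 1, 2}) whose translation of
    ``trbd2_nt`` contains ``motif``. Stop codons are rendered '*'."""
    if len(trbd2_nt) < 6:
        raise ValueError("sequence shorter than two codons")
    bad = set(trbd2_nt) - set("ACGT")
    if bad:
        raise ValueError(f"non-ACGT characters: {sorted(bad)}")
    return {off for off in (0, 1, 2) if motif in translate(trbd2_nt[off:])}


def gene_usage(
    chains: list[TcrChain], group_by: str = "subset"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """V/D/J usage proportions per group with pairwise proportion tests.

    Returns (usage table, test table). Usage proportions sum to 1 within
    each (group, locus, segment); pairwise two-sided proportion z-tests per
    gene are BH-adjusted within each segment.
    """
    rows = []
    for ch in chains:
        group = getattr(ch, group_by)
        for segment, call in (("V", ch.v_call), ("D", ch.d_call), ("J", ch.j_call)):
            if call:
                rows.append((group, ch.locus, segment, call))
    df = pd.DataFrame(rows, columns=["group", "locus", "segment", "gene"])
    counts = (
        df.groupby(["group", "locus", "segment", "gene"]).size().rename("count").reset_index()
    )
    totals = counts.groupby(["group", "locus", "segment"])["count"].transform("sum")
    counts["proportion"] = counts["count"] / totals

    tests = []
    groups = sorted(df["group"].unique())
    for (locus, segment), sub in counts.groupby(["locus", "segment"]):
        genes = sorted(sub["gene"].unique())
        for i, ga in enumerate(groups):
            for gb in groups[i + 1 :]:
                pvals, keys = [], []
                for gene in genes:
                    xa = sub.query("group == @ga and gene == @gene")["count"].sum()
                    xb = sub.query("group == @gb and gene == @gene")["count"].sum()
                    na = sub.query("group == @ga")["count"].sum()
                    nb = sub.query("group == @gb")["count"].sum()
                    if na == 0 or nb == 0:
                        continue
                    if xa + xb == 0 or xa + xb == na + nb:
                        p = 1.0
                    else:
                        _, p = proportions_ztest([xa, xb], [na, nb])
                    pvals.append(p)
                    keys.append(gene)
                if pvals:
                    adj = multipletests(pvals, method="fdr_bh")[1]
                    for gene, p, ap in zip(keys, pvals, adj):
                        tests.append((locus, segment, ga, gb, gene, p, ap))
    tests_df = pd.DataFrame(
        tests,
        columns=["locus", "segment", "group_a", "group_b", "gene", "pvalue", "adj_pvalue"],
    )
    return counts, tests_df


def kmer_enrichment(
    trimmed: pd.DataFrame, k: int = 2, subset_a: str = "DP", subset_b: str = "SP"
) -> pd.DataFrame:
    """Exhaustive k-mer presence comparison between two subsets.

    A simple stand-in for de novo motif discovery: for every k-mer observed
    in any trimmed CDR3, compare the proportion of chains containing it
    between the two subsets (two-sided proportion z-test, BH-adjusted).
    """
    sub = trimmed[trimmed["subset"].isin([subset_a, subset_b])]
    kmers: Counter[str] = Counter()
    for s in sub["trimmed_aa"]:
        for i in range(len(s) - k + 1):
            kmers[s[i : i + k]] += 1
    rows = []
    a_seqs = sub.loc[sub["subset"] == subset_a, "trimmed_aa"]
    b_seqs = sub.loc[sub["subset"] == subset_b, "trimmed_aa"]
    for kmer in sorted(kmers):
        xa = int(a_seqs.str.contains(kmer, regex=False).sum())
        xb = int(b_seqs.str.contains(kmer, regex=False).sum())
        na, nb = len(a_seqs), len(b_seqs)
        if na == 0 or nb == 0:
            continue
        if xa + xb in (0, na + nb):
            p = 1.0
        else:
            _, p = proportions_ztest([xa, xb], [na, nb])
        rows.append((kmer, xa / na, xb / nb, p))
    out = pd.DataFrame(rows, columns=["kmer", f"prop_{subset_a}", f"prop_{subset_b}", "pvalue"])
    if len(out):
        out["adj_pvalue"] = multipletests(out["pvalue"], method="fdr_bh")[1]
    return out
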