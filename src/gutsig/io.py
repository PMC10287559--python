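"""Readers and writers for the standard on-disk formats.

Counts travel as TSV (genes x samples) or MatrixMarket MTX with row/column
name sidecars; gene sets as GMT; repertoires as AIRR rearrangement TSV;
metadata and result tables as TSV.
"""

from __future__ import annotations

import os

import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

from .bcr import BcrSequence
from .bulk import GeneCountMatrix
from .tcr import TcrChain

AIRR_COLUMNS = [
    "sequence_id",
    "cell_id",
    "locus",
    "v_call",
    "d_call",
    "j_call",
    "junction",
    "junction_aa",
    "productive",
    "germline_alignment",
    "isotype",
]


def read_counts_tsv(counts_path: str, gene_meta_path: str) -> GeneCountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(gene_meta_path, sep="\t", index_col=0)
    return GeneCountMatrix(counts=counts, gene_meta=meta.reindex(counts.index))


def write_counts_tsv(gcm: GeneCountMatrix, counts_path: str, gene_meta_path: str) -> None:
    gcm.counts.to_csv(counts_path, sep="\t")
    gcm.gene_meta.to_csv(gene_meta_path, sep="\t")


def write_counts_mtx(gcm: GeneCountMatrix, prefix: str) -> None:
    mmwrite(f"{prefix}.mtx", csr_matrix(gcm.counts.to_numpy()))
    with open(f"{prefix}.rows.txt", "w") as fh:
        fh.write("\n".join(gcm.counts.index) + "\n")
    with open(f"{prefix}.cols.txt", "w") as fh:
        fh.write("\n".join(gcm.counts.columns) + "\n")


def read_counts_mtx(prefix: str, gene_meta_path: str | None = None) -> GeneCountMatrix:
    mat = mmread(f"{prefix}.mtx").toarray().astype(int)
    with open(f"{prefix}.rows.txt") as fh:
        rows = fh.read().split()
    with open(f"{prefix}.cols.txt") as fh:
        cols = fh.read().split()
    counts = pd.DataFrame(mat, index=rows, columns=cols)
    if gene_meta_path and os.path.exists(gene_meta_path):
        meta = pd.read_csv(gene_meta_path, sep="\t", index_col=0).reindex(rows)
    else:
        meta = pd.DataFrame({"biotype": "protein_coding"}, index=counts.index)
    return GeneCountMatrix(counts=counts, gene_meta=meta)


def read_gmt(path: str) -> dict[str, list[str]]:
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, name] + list(genes)) + "\n")


def tcr_to_airr(chains: list[TcrChain]) -> pd.DataFrame:
    rows = []
    for i, ch in enumerate(chains):
        rows.append(
            {
                "sequence_id": f"seq{i + 1}",
                "cell_id": ch.cell_id,
                "locus": ch.locus,
                "v_call": ch.v_call,
                "d_call": ch.d_call,
                "j_call": ch.j_call,
                "junction": ch.junction_nt,
                "junction_aa": ch.junction_aa,
                "productive": "T" if ch.productive else "F",
                "germline_alignment": "|".join(ch.codon_alignment),
                "isotype": "",
                "subset": ch.subset,
                "patient": ch.patient,
                "read_count": ch.read_count,
            }
        )
    return pd.DataFrame(rows)


def airr_to_tcr(df: pd.DataFrame) -> list[TcrChain]:
    chains = []
    for _, r in df.iterrows():
        aln = str(r.get("germline_alignment", "")).split("|") if r.get("germline_alignment") else []
        chains.append(
            TcrChain(
                cell_id=str(r["cell_id"]),
                locus=str(r["locus"]),
                v_call=str(r["v_call"]),
                d_call=str(r.get("d_call", "")),
                j_call=str(r["j_call"]),
                junction_nt=str(r["junction"]),
                junction_aa=str(r["junction_aa"]),
                productive=str(r["productive"]) in ("T", "True", "true", "TRUE"),
                codon_alignment=aln,
                subset=str(r.get("subset", "")),
                read_count=int(r.get("read_count", 1)),
                patient=str(r.get("patient", "")),
            )
        )
    return chains


def bcr_to_airr(seqs: list[BcrSequence]) -> pd.DataFrame:
    rows = []
    for i, s in enumerate(seqs):
        rows.append(
            {
                "sequence_id": f"seq{i + 1}",
                "cell_id": s.cell_id,
                "locus": s.locus,
                "v_call": s.v_call,
                "d_call": "",
                "j_call": s.j_call,
                "junction": s.junction_nt,
                "junction_aa": s.junction_aa,
                "productive": "T",
                "germline_alignment": s.germline_full_aa or "",
                "isotype": s.isotype,
                "full_aa": s.full_aa,
                "light_chain_id": s.light_chain_id,
                "clone_id": s.clone_id or "",
                "cdr3_start_aa": s.cdr3_aa_span[0] if s.cdr3_aa_span else "",
                "cdr3_end_aa": s.cdr3_aa_span[1] if s.cdr3_aa_span else "",
            }
        )
    return pd.DataFrame(rows)


def airr_to_bcr(df: pd.DataFrame) -> list[BcrSequence]:
    seqs = []
    for _, r in df.iterrows():
        span = None
        if str(r.get("cdr3_start_aa", "")) not in ("", "nan"):
            span = (int(r["cdr3_start_aa"]), int(r["cdr3_end_aa"]))
        clone = str(r.get("clone_id", "")) or None
        if clone in ("nan",):
            clone = None
        seqs.append(
            BcrSequence(
                cell_id=str(r["cell_id"]),
                junction_nt=str(r["junction"]),
                junction_aa=str(r["junction_aa"]),
                full_aa=str(r["full_aa"]),
                v_call=str(r["v_call"]),
                j_call=str(r["j_call"]),
                isotype=str(r.get("isotype", "")),
                light_chain_id=str(r.get("light_chain_id", "")),
                locus=str(r.get("locus", "IGH")),
                clone_id=clone,
                germline_full_aa=str(r.get("germline_alignment", "")) or None,
                cdr3_aa_span=span,
            )
        )
    return seqs
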