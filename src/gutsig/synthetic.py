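"""Synthetic cohorts with the statistical structure the analysis assumes.

Five generators cover the pipeline end to end: a negative-binomial bulk
RNA-seq cohort with four planted transcriptional clusters (U1/U2/I1/I2) and
diagnosis-dependent cluster frequencies, a CD4 single-cell matrix with
IL17A+FOXP3+ double-positive cells and a matched flow-cytometry frequency
table, a TCR beta repertoire assembled from germline segments with
N-nucleotides (with a controllable leucine-alanine reading-frame bias in DP
cells), power-law B-cell clones with CDR3-hotspot somatic hypermutation,
and a replica clinical survival cohort whose printed event margins are
reproduced deterministically.

Everything is driven by :class:`SimConfig`; the same config (including
seed) yields bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import germlines
from .bcr import BcrSequence
from .bulk import GeneCountMatrix
from .dp_cells import CellCountMatrix
from .tcr import N_REGION, CODON_TABLE, TcrChain, translate

CLUSTERS = ("U1", "U2", "I1", "I2")

_DEFAULT_CLUSTER_PROBS = {
    # mimics the observed diagnosis-by-cluster distribution: I2 is common in
    # PSC (~27%), rare in IBD (~7%) and nearly absent in healthy controls
    "PSC": (0.33, 0.20, 0.20, 0.27),
    "IBD": (0.45, 0.28, 0.20, 0.07),
    "HC": (0.60, 0.35, 0.04, 0.01),
}

N_INFLAMMATION_GENES = 81
N_SUBTYPE_GENES = 80


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic generators; the seed fully determines output."""

    seed: int = 0
    n_samples_per_diagnosis: dict[str, int] = field(
        default_factory=lambda: {"PSC": 50, "IBD": 50, "HC": 50}
    )
    cluster_probs_by_diagnosis: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_CLUSTER_PROBS)
    )
    n_genes: int = 2000
    inflammation_effect: float = 2.0  # log2 fold change in I2; half in I1
    batch_count: int = 2
    batch_effect_sd: float = 0.2  # log2 units
    nb_dispersion: float = 0.1
    sc_n_cells: int = 2000
    dp_frequency: float = 0.05
    la_enrichment: float = 0.6
    clone_size_law: float = 2.0
    shm_rate: float = 0.01
    cdr3_hotspot_multiplier: float = 5.0

    def __post_init__(self) -> None:
        for diag, n in self.n_samples_per_diagnosis.items():
            if n <= 0:
                raise ValueError(f"non-positive sample count for {diag!r}")
        for diag, probs in self.cluster_probs_by_diagnosis.items():
            if len(probs) != len(CLUSTERS):
                raise ValueError(f"{diag!r}: need one probability per cluster")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"{diag!r}: cluster probabilities must sum to 1")
            if any(p < 0 for p in probs):
                raise ValueError(f"{diag!r}: negative cluster probability")
        for name in ("dp_frequency", "la_enrichment", "shm_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.inflammation_effect < 0:
            raise ValueError("inflammation_effect must be >= 0")
        if self.n_genes <= N_INFLAMMATION_GENES + N_SUBTYPE_GENES:
            raise ValueError("n_genes too small for the planted programs")
        if self.batch_count < 1 or self.nb_dispersion <= 0:
            raise ValueError("batch_count >= 1 and nb_dispersion > 0 required")
        if self.cdr3_hotspot_multiplier < 1:
            raise ValueError("cdr3_hotspot_multiplier must be >= 1")
        if self.sc_n_cells <= 0:
            raise ValueError("sc_n_cells must be positive")
        if self.clone_size_law <= 0:
            raise ValueError("clone_size_law must be positive")


def inflammation_program_genes(n_genes: int = 2000) -> list[str]:
    return [f"G{i + 1:04d}" for i in range(N_INFLAMMATION_GENES)]


# ---------------------------------------------------------------------------
# bulk cohort
# ---------------------------------------------------------------------------

def simulate_bulk_cohort(cfg: SimConfig) -> tuple[GeneCountMatrix, pd.DataFrame]:
    """Negative-binomial bulk cohort with planted U1/U2/I1/I2 structure.

    An 81-gene inflammation program is up-shifted by half the configured
    effect in I1 and the full effect in I2; an 80-gene subtype program
    (scaled to 0.75x the effect) separates U1 from U2 so that four clusters
    exist whenever the effect is nonzero and none when it is zero. Per-batch
    per-gene log2 shifts emulate sequencing batches. True cluster labels are
    returned in the sample table.
    """
    rng = np.random.default_rng(cfg.seed)
    n_genes = cfg.n_genes
    gene_ids = [f"G{i + 1:04d}" for i in range(n_genes)]
    inflam = np.zeros(n_genes, dtype=bool)
    inflam[:N_INFLAMMATION_GENES] = True
    subtype = np.zeros(n_genes, dtype=bool)
    subtype[N_INFLAMMATION_GENES : N_INFLAMMATION_GENES + N_SUBTYPE_GENES] = True

    base_log2 = rng.normal(5.0, 2.0, size=n_genes)
    # program genes must clear the median>5 expression filter downstream
    base_log2[inflam | subtype] = np.clip(base_log2[inflam | subtype], 5.0, None)

    biotype = np.array(["protein_coding"] * n_genes, dtype=object)
    other = ~(inflam | subtype)
    other_idx = np.flatnonzero(other)
    n_linc = max(1, n_genes // 10)
    biotype[other_idx[:n_linc]] = "lincRNA"
    biotype[other_idx[n_linc : n_linc + 20]] = "TR_gene"
    biotype[other_idx[n_linc + 20 : n_linc + 40]] = "IG_gene"

    program = np.where(inflam, "inflammation", np.where(subtype, "subtype", ""))
    gene_meta = pd.DataFrame(
        {"biotype": biotype, "program": program}, index=pd.Index(gene_ids, name="gene_id")
    )

    # the subtype program sits on U1 so that the classifier's U2/I1/I2
    # contrasts never see it: the I2 signal is carried by the 81
    # inflammation genes alone
    shift = {
        "U1": (0.0, 0.75 * cfg.inflammation_effect),
        "U2": (0.0, 0.0),
        "I1": (0.5 * cfg.inflammation_effect, 0.0),
        "I2": (cfg.inflammation_effect, 0.0),
    }
    batch_shift = rng.normal(0.0, cfg.batch_effect_sd, size=(cfg.batch_count, n_genes))

    sample_rows = []
    columns = {}
    for diag in sorted(cfg.n_samples_per_diagnosis):
        n = cfg.n_samples_per_diagnosis[diag]
        probs = np.asarray(cfg.cluster_probs_by_diagnosis[diag], dtype=float)
        clusters = rng.choice(CLUSTERS, size=n, p=probs / probs.sum())
        batches = rng.integers(0, cfg.batch_count, size=n)
        sexes = rng.choice(["F", "M"], size=n)
        ages = rng.integers(20, 80, size=n)
        depth = rng.lognormal(0.0, 0.2, size=n)
        for i in range(n):
            sid = f"{diag}{i + 1:03d}"
            cl = str(clusters[i])
            s_inf, s_sub = shift[cl]
            log2_mu = (
                base_log2
                + s_inf * inflam
                + s_sub * subtype
                + batch_shift[batches[i]]
            )
            mu = (2.0**log2_mu) * depth[i]
            r = 1.0 / cfg.nb_dispersion
            counts = rng.negative_binomial(r, r / (r + mu))
            columns[sid] = counts
            sample_rows.append(
                (sid, diag, cl, f"batch{batches[i]}", sexes[i], int(ages[i]))
            )
    counts_df = pd.DataFrame(columns, index=gene_meta.index)
    samples = pd.DataFrame(
        sample_rows,
        columns=["sample_id", "diagnosis", "cluster", "batch", "sex", "age"],
    ).set_index("sample_id")
    return GeneCountMatrix(counts=counts_df, gene_meta=gene_meta), samples


# ---------------------------------------------------------------------------
# CD4 single cells + flow table
# ---------------------------------------------------------------------------

SIGNATURE_PANEL = [f"SIG{i + 1:02d}" for i in range(25)]
_BACKGROUND_GENES = [f"BG{i + 1:03d}" for i in range(100)]
_SP_FREQUENCY = 0.15  # each single-positive population

def simulate_cd4_cells(
    cfg: SimConfig, n_samples: int = 6
) -> tuple[CellCountMatrix, pd.DataFrame]:
    """Per-cell UMI counts for IL17A/FOXP3 and a signature panel, plus a
    flow table of per-sample DP/SP target frequencies.

    Marker transcripts are detected only in truth-positive cells (1 + Poisson
    counts), emulating the sparsity of cytokine transcripts at 10x depth;
    DP cells carry a 1-log2-unit up-shift of the 25-gene signature panel.
    The flow table holds the empirical truth-label frequencies per sample.
    """
    if cfg.sc_n_cells <= 0:
        raise ValueError("zero cells requested")
    if cfg.dp_frequency + 2 * _SP_FREQUENCY > 1:
        raise ValueError("dp_frequency plus SP frequencies exceeds 1")
    rng = np.random.default_rng(cfg.seed + 1)
    genes = ["IL17A", "FOXP3"] + SIGNATURE_PANEL + _BACKGROUND_GENES
    sample_clusters = [("U", "I1", "I2")[i % 3] for i in range(n_samples)]
    per_sample = np.full(n_samples, cfg.sc_n_cells // n_samples)
    per_sample[-1] += cfg.sc_n_cells - per_sample.sum()

    sig_rate = rng.lognormal(0.0, 0.5, size=len(SIGNATURE_PANEL))
    bg_rate = rng.lognormal(0.0, 0.5, size=len(_BACKGROUND_GENES))

    cols, meta_rows = {}, []
    probs = np.array(
        [cfg.dp_frequency, _SP_FREQUENCY, _SP_FREQUENCY,
         1 - cfg.dp_frequency - 2 * _SP_FREQUENCY]
    )
    flow_rows = []
    for s in range(n_samples):
        sid = f"S{s + 1:02d}"
        n = int(per_sample[s])
        subsets = rng.choice(["DP", "IL17A_SP", "FOXP3_SP", "DN"], size=n, p=probs)
        depth = rng.lognormal(0.0, 0.3, size=n)
        for c in range(n):
            cid = f"{sid}_c{c + 1:04d}"
            sub = str(subsets[c])
            il17a = 1 + rng.poisson(3) if sub in ("DP", "IL17A_SP") else 0
            foxp3 = 1 + rng.poisson(3) if sub in ("DP", "FOXP3_SP") else 0
            sig_mult = 2.0 if sub == "DP" else 1.0
            sig = rng.poisson(sig_rate * depth[c] * sig_mult)
            bg = rng.poisson(bg_rate * depth[c])
            cols[cid] = np.concatenate(([il17a, foxp3], sig, bg))
            meta_rows.append((cid, sid, sample_clusters[s], sub))
        counts = pd.Series(subsets)
        flow_rows.append(
            (
                sid,
                float((counts == "DP").mean()),
                float((counts == "IL17A_SP").mean()),
                float((counts == "FOXP3_SP").mean()),
            )
        )
    counts_df = pd.DataFrame(cols, index=pd.Index(genes, name="gene"), dtype=int)
    meta = pd.DataFrame(
        meta_rows, columns=["cell_id", "sample_id", "patient_cluster", "true_subset"]
    ).set_index("cell_id")
    flow = pd.DataFrame(
        flow_rows, columns=["sample_id", "dp_freq", "il17a_freq", "foxp3_freq"]
    ).set_index("sample_id")
    return CellCountMatrix(counts=counts_df, cell_meta=meta), flow


# ---------------------------------------------------------------------------
# TCR repertoire
# ---------------------------------------------------------------------------

_NON_STOP_CODONS = sorted(c for c, aa in CODON_TABLE.items() if aa != "*")


def _assemble_trb_junction(
    rng: np.random.Generator, v_call: str, j_call: str, d_allele: str, la_frame: bool
) -> tuple[str, list[str], str]:
    """Junction assembly: V end + N + TRBD2 segment + N + J start.

    N additions are one full random (non-stop) codon on each side of D, so
    codon boundaries stay aligned; the D segment uses reading-frame offset 1
    (whose translation contains LA) or offset 0. Returns (junction_nt,
    codon_alignment, d_call).
    """
    if v_call not in germlines.TRBV_ENDS:
        raise KeyError(f"missing germline fixture for V segment {v_call!r}")
    if j_call not in germlines.TRBJ_STARTS:
        raise KeyError(f"missing germline fixture for J segment {j_call!r}")
    if d_allele not in germlines.TRBD2:
        raise KeyError(f"missing germline fixture for D segment {d_allele!r}")
    v_nt = germlines.TRBV_ENDS[v_call]
    j_nt = germlines.TRBJ_STARTS[j_call]
    d_full = germlines.TRBD2[d_allele]
    offset = 1 if la_frame else 0
    d_nt = d_full[offset : offset + 12]
    n1 = "".join(rng.choice(_NON_STOP_CODONS, size=1))
    n2 = "".join(rng.choice(_NON_STOP_CODONS, size=1))
    junction = v_nt + n1 + d_nt + n2 + j_nt
    alignment = (
        [v_nt[i : i + 3] for i in range(0, len(v_nt), 3)]
        + [N_REGION]
        + [d_nt[i : i + 3] for i in range(0, len(d_nt), 3)]
        + [N_REGION]
        + [j_nt[i : i + 3] for i in range(0, len(j_nt), 3)]
    )
    return junction, alignment, d_allele


def _point_mutate(
    rng: np.random.Generator, junction: str, alignment: list[str], rate: float
) -> str:
    """Mutate V/J-templated nucleotides at ``rate``; N and D codons untouched."""
    if rate == 0:
        return junction
    nts = list(junction)
    d_codons = {4 + 1, 4 + 2, 4 + 3, 4 + 4}  # codons 5..8 hold the D segment
    for ci, germ in enumerate(alignment):
        if germ == N_REGION or ci in d_codons:
            continue
        for k in range(3):
            if rng.random() < rate:
                pos = 3 * ci + k
                nts[pos] = str(rng.choice([b for b in "ACGT" if b != nts[pos]]))
    return "".join(nts)


def simulate_tcr_repertoire(
    cfg: SimConfig,
    n_patients: int = 8,
    chains_per_patient: int = 40,
    sp_la_fraction: float | None = 0.15,
    nonproductive_rate: float = 0.05,
    doublet_rate: float = 0.05,
) -> list[TcrChain]:
    """TRB chains assembled from germline segments with N-nucleotides.

    DP-labelled chains use the LA-containing TRBD2 reading frame with
    probability ``cfg.la_enrichment``; SP chains with ``sp_la_fraction``
    (pass the same value to both for a null repertoire). A small fraction of
    nonproductive chains and same-barcode duplicates exercise the filters.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    if sp_la_fraction is None:
        sp_la_fraction = cfg.la_enrichment
    v_names = sorted(germlines.TRBV_ENDS)
    j_names = sorted(germlines.TRBJ_STARTS)
    d_names = sorted(germlines.TRBD2)
    chains: list[TcrChain] = []
    for p in range(n_patients):
        patient = f"P{p + 1:02d}"
        for c in range(chains_per_patient):
            cell_id = f"{patient}_cell{c + 1:04d}"
            subset = "DP" if rng.random() < 0.5 else "SP"
            la_prob = cfg.la_enrichment if subset == "DP" else sp_la_fraction
            la = bool(rng.random() < la_prob)
            v = str(rng.choice(v_names))
            j = str(rng.choice(j_names))
            d = str(rng.choice(d_names))
            junction, alignment, d_call = _assemble_trb_junction(rng, v, j, d, la)
            junction = _point_mutate(rng, junction, alignment, cfg.shm_rate)
            aa = translate(junction)
            productive = "*" not in aa
            chains.append(
                TcrChain(
                    cell_id=cell_id,
                    locus="TRB",
                    v_call=v,
                    d_call=d_call,
                    j_call=j,
                    junction_nt=junction,
                    junction_aa=aa,
                    productive=productive,
                    codon_alignment=alignment,
                    subset=subset,
                    read_count=int(rng.integers(2, 100)),
                    patient=patient,
                )
            )
            if rng.random() < doublet_rate:
                # second, lower-support chain sharing the barcode
                j2 = str(rng.choice(j_names))
                jn2, aln2, dc2 = _assemble_trb_junction(rng, v, j2, d, not la)
                chains.append(
                    TcrChain(
                        cell_id=cell_id,
                        locus="TRB",
                        v_call=v,
                        d_call=dc2,
                        j_call=j2,
                        junction_nt=jn2,
                        junction_aa=translate(jn2),
                        productive=True,
                        codon_alignment=aln2,
                        subset=subset,
                        read_count=1,
                        patient=patient,
                    )
                )
            if rng.random() < nonproductive_rate:
                chains.append(
                    TcrChain(
                        cell_id=f"{patient}_np{c + 1:04d}",
                        locus="TRB",
                        v_call=v,
                        d_call=d_call,
                        j_call=j,
                        junction_nt=junction[:-1] + "A",
                        junction_aa=aa,
                        productive=False,
                        codon_alignment=alignment,
                        subset=subset,
                        read_count=int(rng.integers(1, 20)),
                        patient=patient,
                    )
                )
    return chains


# ---------------------------------------------------------------------------
# BCR clones
# ---------------------------------------------------------------------------

def _power_law_size(rng: np.random.Generator, a: float, lo: int = 2, hi: int = 40) -> int:
    u = rng.random()
    size = int(round((1 - u) ** (-1.0 / a)))
    return int(np.clip(size + lo - 1, lo, hi))


def _random_cdr3_nt(rng: np.random.Generator, n_codons: int = 15) -> str:
    return "".join(rng.choice(_NON_STOP_CODONS, size=n_codons))


def simulate_bcr_clones(
    cfg: SimConfig, n_clones: int = 12, discordant_light_rate: float = 0.05
) -> list[BcrSequence]:
    """Power-law-sized heavy-chain clones mutated from a stored germline.

    Each clone gets its own CDR3 (clone CDR3s sharing V/J are kept at
    normalised Hamming distance >= 0.3 so the clonal partition is
    recoverable); members mutate at ``cfg.shm_rate`` per nucleotide outside
    the CDR3 and ``shm_rate * cdr3_hotspot_multiplier`` inside it. Isotypes
    follow a per-clone mixture; each cell carries a paired light-chain id,
    occasionally discordant.
    """
    rng = np.random.default_rng(cfg.seed + 3)
    fr_before = germlines.BCR_HEAVY_GERMLINE_NT[: germlines.BCR_CDR3_NT_SPAN[0]]
    fr_after = germlines.BCR_HEAVY_GERMLINE_NT[germlines.BCR_CDR3_NT_SPAN[1] :]
    lo, hi = germlines.BCR_CDR3_NT_SPAN
    cdr3_len = hi - lo
    seqs: list[BcrSequence] = []
    used_cdr3: dict[tuple[str, str], list[str]] = {}
    cell = 0
    for k in range(n_clones):
        v_call = germlines.BCR_V_CALLS[k % len(germlines.BCR_V_CALLS)]
        j_call = germlines.BCR_J_CALLS[k % len(germlines.BCR_J_CALLS)]
        while True:
            cdr3 = _random_cdr3_nt(rng, cdr3_len // 3)
            prior = used_cdr3.get((v_call, j_call), [])
            if all(
                sum(a != b for a, b in zip(cdr3, other)) / cdr3_len >= 0.3
                for other in prior
            ):
                break
        used_cdr3.setdefault((v_call, j_call), []).append(cdr3)
        germ_nt = fr_before + cdr3 + fr_after
        germ_aa = translate(germ_nt).replace("*", "X")
        size = _power_law_size(rng, cfg.clone_size_law)
        iso_probs = rng.dirichlet(np.ones(len(germlines.ISOTYPES)) * 0.3)
        light = f"LC{k + 1:02d}"
        cdr3_rate = min(1.0, cfg.shm_rate * cfg.cdr3_hotspot_multiplier)
        for _ in range(size):
            cell += 1
            nts = list(germ_nt)
            for pos in range(len(nts)):
                rate = cdr3_rate if lo <= pos < hi else cfg.shm_rate
                if rate > 0 and rng.random() < rate:
                    nts[pos] = str(rng.choice([b for b in "ACGT" if b != nts[pos]]))
            nt = "".join(nts)
            aa = translate(nt).replace("*", "X")
            lc = light
            if rng.random() < discordant_light_rate:
                lc = f"{light}x"
            seqs.append(
                BcrSequence(
                    cell_id=f"B{cell:05d}",
                    junction_nt=nt[lo:hi],
                    junction_aa=aa[lo // 3 : hi // 3],
                    full_aa=aa,
                    v_call=v_call,
                    j_call=j_call,
                    isotype=str(rng.choice(germlines.ISOTYPES, p=iso_probs)),
                    light_chain_id=lc,
                    clone_id=None,
                    germline_full_aa=germ_aa,
                    cdr3_aa_span=germlines.BCR_CDR3_AA_SPAN,
                )
            )
    return seqs


# ---------------------------------------------------------------------------
# replica survival cohort
# ---------------------------------------------------------------------------

_BASE_DATE = pd.Timestamp("1990-01-01")


def build_survival_fixture(cfg: SimConfig | None = None) -> pd.DataFrame:
    """Replica clinical cohort reproducing the printed margins exactly.

    64 PSC patients with 10 right-sided events (6 ever-I2) and 10
    non-right-sided events (5 ever-I2); 127 IBD patients with 17 right-sided
    and 23 non-right-sided events (0 ever-I2 among either). Follow-up times
    are deterministic grids whose medians equal the printed 15.5 (PSC) and
    13.8 (IBD) years; ever-I2 right-sided events occur earliest so the PSC
    Kaplan-Meier curves separate. Event labels are assigned
    deterministically, not sampled.
    """
    rows = []

    def add_patient(
        diagnosis: str, idx: int, years: float, ever_i2: bool, side: str | None
    ) -> None:
        pid = f"{diagnosis}{idx + 1:03d}"
        colitis = _BASE_DATE + pd.Timedelta(days=13 * idx)
        event_date = None
        last = colitis + pd.Timedelta(days=round(years * 365.25))
        if side is not None:
            event_date = last
        visits = "U;I2" if ever_i2 else ("I1;U" if idx % 2 else "U")
        rows.append(
            (
                pid,
                diagnosis,
                bool(ever_i2),
                colitis.date().isoformat(),
                event_date.date().isoformat() if event_date is not None else "",
                side or "",
                last.date().isoformat(),
                visits,
            )
        )

    psc_times = np.linspace(4.0, 27.0, 64)
    psc_right_i2 = {0, 2, 4, 6, 8, 10}
    psc_right_non = {30, 34, 38, 42}
    psc_nonright_i2 = {13, 15, 17, 19, 21}
    psc_nonright_non = {45, 47, 49, 51, 53}
    psc_censored_i2 = {23, 25, 27, 29, 33, 35}
    for i, t in enumerate(psc_times):
        if i in psc_right_i2 or i in psc_right_non:
            add_patient("PSC", i, float(t), i in psc_right_i2, "right")
        elif i in psc_nonright_i2 or i in psc_nonright_non:
            add_patient("PSC", i, float(t), i in psc_nonright_i2, "nonright")
        else:
            add_patient("PSC", i, float(t), i in psc_censored_i2, None)

    ibd_times = np.linspace(2.6, 25.0, 127)
    ibd_right = set(range(0, 34, 2))  # 17 events, none I2
    ibd_nonright = set(range(40, 63))  # 23 events, none I2
    ibd_censored_i2 = set(range(70, 88, 2))  # 9 ever-I2 without events
    for i, t in enumerate(ibd_times):
        if i in ibd_right:
            add_patient("IBD", i, float(t), False, "right")
        elif i in ibd_nonright:
            add_patient("IBD", i, float(t), False, "nonright")
        else:
            add_patient("IBD", i, float(t), i in ibd_censored_i2, None)

    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "diagnosis",
            "ever_i2",
            "colitis_diagnosis_date",
            "event_date",
            "event_side",
            "last_colonoscopy_date",
            "visit_clusters",
        ],
    )
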