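"""Germline V(D)J segment fixtures and packaged gene lists.

TRBD2 alleles are the IMGT reference sequences for the human TCR beta
diversity-2 segment; the leucine-alanine (LA) dipeptide is germline-encoded
in exactly one of their three reading frames, which is what the frame census
in :mod:`gutsig.tcr` demonstrates.

The TRBV/TRBJ stubs and the BCR heavy-chain template below are synthetic
stand-ins with the right structural properties (conserved junction-flanking
residues, in-frame lengths, no stop codons) rather than database alleles;
they exist so the repertoire simulators can assemble junctions without
external downloads.
"""

# IMGT reference alleles (nucleotide).
TRBD2 = {
    "TRBD2*01": "GGGACTAGCGGGAGGG",
    "TRBD2*02": "GGGACTAGCGGGGGGG",
}

# Synthetic TRBV 3' ends: each ends with the conserved Cys codon region that
# opens the CDR3 (C-A-S-S style).  12 nt, codon-aligned.
TRBV_ENDS = {
    "TRBV7-9": "TGTGCCAGCAGC",
    "TRBV19": "TGTGCCAGTAGT",
    "TRBV5-1": "TGCGCCAGCAGC",
}

# Synthetic TRBJ 5' starts: in-frame, conserved Phe toward the junction end.
TRBJ_STARTS = {
    "TRBJ2-1": "AACGAGCAGTTCTTC",  # N E Q F F
    "TRBJ2-7": "TACGAGCAGTACTTC",  # Y E Q Y F
}

# Synthetic BCR heavy-chain germline: 267 nt / 89 aa, gap-free, stop-free.
# CDR3 occupies amino-acid positions [30, 45) (nt [90, 135)).
_FR_BEFORE = (
    "GAGGTGCAGCTGGTGGAGTCTGGGGGAGGCTTGGTACAGCCT"
    "GGGGGGTCCCTGAGACTCTCCTGTGCAGCCTCTGGATTCACCTTTAGC"
)
_CDR3 = "TGTGCGAGAGATCGGAGCAGCTGGTACGACTATTACTACGGTATG"
_FR_AFTER = (
    "TGGGGCCAAGGGACAATGGTCACCGTCTCTTCAGCCTCCACCAAGGGCCCATCGGTCTTC"
    "CCCCTGGCACCCTCCTCCAAGAGCACCTCTGGGGGCACAGCGGCCCTGGGCTGCCTGGTCAAGGACTACTTC"
)
BCR_HEAVY_GERMLINE_NT = _FR_BEFORE + _CDR3 + _FR_AFTER
BCR_CDR3_NT_SPAN = (90, 135)
BCR_CDR3_AA_SPAN = (30, 45)

BCR_V_CALLS = ["IGHV3-23", "IGHV1-69", "IGHV4-34"]
BCR_J_CALLS = ["IGHJ4", "IGHJ6"]
ISOTYPES = ["IgM", "IgG1", "IgG2", "IgG3", "IgG4", "IgA1", "IgA2"]

# Default pathogenic IL-17 signature (user-replaceable; GMT input accepted by
# the scoring functions).  Human orthologs of a published pathogenic Th17
# program; synthetic CD4 cells use the simulator's SIG panel instead.
PATHOGENIC_IL17_SIGNATURE = [
    "IL23R", "CSF2", "IL22", "CCL4", "CCL5", "GZMB", "LRMP", "CASP1",
    "TBX21", "ICOS", "STAT4", "LGALS3", "LAG3", "IL7R", "CCL3", "IL3",
]
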