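"""Bundled approximate C. elegans codon usage.

Values are genome-wide codon fractions within each synonymous family
(Kazusa-style, rounded); they are renormalized within family at load time,
so only their relative sizes matter.  The table's sole job in this package
is to gate rarely used codons below the usage floor when recoding.
"""

CELEGANS_CODON_FRACTIONS = {
    # Ala
    "GCT": 0.36, "GCA": 0.31, "GCC": 0.20, "GCG": 0.13,
    # Arg
    "CGT": 0.21, "CGA": 0.23, "CGC": 0.10, "CGG": 0.09, "AGA": 0.29, "AGG": 0.08,
    # Asn
    "AAT": 0.62, "AAC": 0.38,
    # Asp
    "GAT": 0.68, "GAC": 0.32,
    # Cys
    "TGT": 0.55, "TGC": 0.45,
    # Gln
    "CAA": 0.66, "CAG": 0.34,
    # Glu
    "GAA": 0.62, "GAG": 0.38,
    # Gly
    "GGA": 0.59, "GGT": 0.20, "GGC": 0.12, "GGG": 0.08,
    # His
    "CAT": 0.61, "CAC": 0.39,
    # Ile
    "ATT": 0.53, "ATC": 0.31, "ATA": 0.16,
    # Leu
    "TTA": 0.11, "TTG": 0.23, "CTT": 0.24, "CTC": 0.17, "CTA": 0.09, "CTG": 0.14,
    # Lys
    "AAA": 0.59, "AAG": 0.41,
    # Met
    "ATG": 1.00,
    # Phe
    "TTT": 0.50, "TTC": 0.50,
    # Pro
    "CCA": 0.53, "CCT": 0.18, "CCC": 0.09, "CCG": 0.20,
    # Ser
    "TCA": 0.25, "TCT": 0.21, "TCC": 0.13, "TCG": 0.15, "AGT": 0.15, "AGC": 0.10,
    # Thr
    "ACA": 0.34, "ACT": 0.32, "ACC": 0.18, "ACG": 0.15,
    # Trp
    "TGG": 1.00,
    # Tyr
    "TAT": 0.56, "TAC": 0.44,
    # Val
    "GTT": 0.39, "GTC": 0.22, "GTA": 0.16, "GTG": 0.23,
    # Stop
    "TAA": 0.43, "TGA": 0.39, "TAG": 0.18,
}
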