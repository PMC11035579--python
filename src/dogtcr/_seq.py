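"""Small nucleotide-sequence helpers shared across modules.

All coordinates are 0-based, half-open; sequences are stored 5'->3' in
transcript (mRNA) orientation, uppercase ACGTN.
"""

from __future__ import annotations

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
CYS_CODONS = frozenset({"TGT", "TGC"})
PHE_CODONS = frozenset({"TTT", "TTC"})
TRP_CODONS = frozenset({"TGG"})
GLY_CODONS = frozenset({"GGT", "GGC", "GGA", "GGG"})

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

VALID_NT = frozenset("ACGTN")


def translate(nt: str) -> str:
    """Translate an in-frame nucleotide string; trailing partial codon dropped.

    Stops render as '*'; any codon containing N renders as 'X'.
    """
    aa = []
    for i in range(0, len(nt) - 2, 3):
        aa.append(_CODON_TABLE.get(nt[i : i + 3], "X"))
    return "".join(aa)


def has_stop(nt: str) -> bool:
    """True if any complete in-frame codon of ``nt`` is a stop codon."""
    return any(nt[i : i + 3] in STOP_CODONS for i in range(0, len(nt) - 2, 3))


def validate_nt(seq: str, context: str = "sequence") -> str:
    """Uppercase ``seq`` and reject empty or non-ACGTN content."""
    s = seq.upper()
    if not s:
        raise ValueError(f"{context}: empty nucleotide sequence")
    bad = set(s) - VALID_NT
    if bad:
        raise ValueError(f"{context}: invalid nucleotide characters {sorted(bad)}")
    return s
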