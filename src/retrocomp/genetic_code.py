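"""Standard genetic code tables and synonymous-family partitions.

Everything downstream (RSCU, Nc, CAI, RCDI, amino-acid composition) works
from these dictionaries, so the degeneracy partition used by Wright's Nc
lives here too: 2 single-codon families (Met, Trp), 9 two-fold, 1
three-fold (Ile), 5 four-fold and 3 six-fold (Leu, Ser, Arg).
"""

from __future__ import annotations

from Bio.Data import CodonTable

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid, sense codons only (61 entries)
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)

STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)  # TAA, TAG, TGA

SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

#: one-letter amino acid -> tuple of synonymous codons, sorted
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    AA_TO_CODONS.setdefault(_aa, ())
AA_TO_CODONS = {
    aa: tuple(sorted(c for c, a in CODON_TO_AA.items() if a == aa))
    for aa in AA_TO_CODONS
}

AMINO_ACIDS: tuple[str, ...] = tuple(sorted(AA_TO_CODONS))  # 20 letters

#: amino acid -> family size (degeneracy)
DEGENERACY: dict[str, int] = {aa: len(cods) for aa, cods in AA_TO_CODONS.items()}

#: degeneracy class -> amino acids in it; Wright's partition of the 20
#: families used by the effective-number-of-codons estimator
DEGENERACY_CLASSES: dict[int, tuple[str, ...]] = {
    k: tuple(aa for aa in AMINO_ACIDS if DEGENERACY[aa] == k)
    for k in sorted(set(DEGENERACY.values()))
}

NUCLEOTIDES: tuple[str, ...] = ("A", "C", "G", "T")

#: the 12 off-diagonal substitutions, row-major A,C,G,T order
SUBSTITUTIONS: tuple[tuple[str, str], ...] = tuple(
    (x, y) for x in NUCLEOTIDES for y in NUCLEOTIDES if x != y
)


def translate_codon(codon: str) -> str | None:
    """One-letter amino acid for a sense codon, ``None`` for a stop,
    ``KeyError`` for anything else (including N-containing codons)."""
    if codon in STOP_CODONS:
        return None
    return CODON_TO_AA[codon]
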