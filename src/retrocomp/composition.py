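"""Sequence-composition statistics for element ORFs.

Per-sequence statistics: base fractions on the positive strand (%A, %AT,
%GC), GC percent at each codon position (GC1/GC2/GC3), overlapping
dinucleotide observed/expected ratios with a chi-square test against the
zero-order (mononucleotide product) model, polyadenylation-signal counts
and amino-acid composition.

Conventions: N positions are excluded from mononucleotide fractions and
break dinucleotide windows; dinucleotides are counted with overlap and no
wrap-around; polyA motifs are counted with overlap on the positive strand
only.
"""

from __future__ import annotations

import dataclasses

from scipy import stats as _sps

from .genetic_code import NUCLEOTIDES, translate_codon
from .seq_io import CodingSequence, codons_of

#: canonical and non-canonical polyadenylation signal hexamers
DEFAULT_POLYA_MOTIFS: tuple[str, ...] = ("AATAAA", "ATTAAA")

DINUCLEOTIDES: tuple[str, ...] = tuple(x + y for x in NUCLEOTIDES for y in NUCLEOTIDES)


@dataclasses.dataclass
class CompositionProfile:
    """Composition summary of one sequence.

    Fractions are over non-N positions and sum to 1; ``gc1/gc2/gc3`` are
    percentages in [0, 100]; ``dinucleotide_ratio`` maps each of the 16
    dinucleotides to observed/expected frequency under the zero-order
    model (``None`` where the expected frequency is zero).
    """

    frac_A: float
    frac_C: float
    frac_G: float
    frac_T: float
    gc1: float | None = None
    gc2: float | None = None
    gc3: float | None = None
    dinucleotide_obs: dict[str, float] | None = None
    dinucleotide_exp: dict[str, float] | None = None
    dinucleotide_ratio: dict[str, float | None] | None = None
    chi2: float | None = None
    chi2_p: float | None = None
    polyA_count: int | None = None
    aa_counts: dict[str, int] | None = None
    n_excluded: int = 0

    @property
    def pct_AT(self) -> float:
        return 100.0 * (self.frac_A + self.frac_T)

    @property
    def pct_GC(self) -> float:
        return 100.0 * (self.frac_C + self.frac_G)

    @property
    def pct_A(self) -> float:
        return 100.0 * self.frac_A


def base_composition(seq: CodingSequence) -> CompositionProfile:
    """Mononucleotide fractions over non-N positions of the positive strand."""
    counts = {b: 0 for b in NUCLEOTIDES}
    n_excluded = 0
    for ch in seq.sequence:
        if ch == "N":
            n_excluded += 1
        else:
            counts[ch] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError(f"sequence {seq.id!r} has no unambiguous bases")
    return CompositionProfile(
        frac_A=counts["A"] / total,
        frac_C=counts["C"] / total,
        frac_G=counts["G"] / total,
        frac_T=counts["T"] / total,
        n_excluded=n_excluded,
    )


def codon_position_gc(seq: CodingSequence) -> tuple[float, float, float]:
    """GC percent at codon positions 1-3 over all codons (N codons excluded)."""
    codons = codons_of(seq)
    if not codons:
        raise ValueError(f"sequence {seq.id!r} has no usable codons")
    gc = [0, 0, 0]
    for codon in codons:
        for pos in range(3):
            if codon[pos] in "GC":
                gc[pos] += 1
    n = len(codons)
    return tuple(100.0 * g / n for g in gc)  # type: ignore[return-value]


def dinucleotide_ratios(seq: CodingSequence) -> CompositionProfile:
    """Observed/expected ratios of the 16 overlapping dinucleotides.

    Expected frequency of XpY is the product of the mononucleotide
    fractions; the chi-square statistic compares observed window counts to
    expected counts under that model, 15 degrees of freedom, no
    continuity correction.  Windows containing N are skipped.
    """
    if len(seq.sequence) < 2:
        raise ValueError(f"sequence {seq.id!r} too short for dinucleotides")
    profile = base_composition(seq)
    mono = {
        "A": profile.frac_A,
        "C": profile.frac_C,
        "G": profile.frac_G,
        "T": profile.frac_T,
    }
    counts = {d: 0 for d in DINUCLEOTIDES}
    s = seq.sequence
    n_windows = 0
    for i in range(len(s) - 1):
        w = s[i : i + 2]
        if "N" in w:
            continue
        counts[w] += 1
        n_windows += 1
    if n_windows == 0:
        raise ValueError(f"sequence {seq.id!r} has no N-free dinucleotide windows")
    obs = {d: counts[d] / n_windows for d in DINUCLEOTIDES}
    exp = {d: mono[d[0]] * mono[d[1]] for d in DINUCLEOTIDES}
    ratio = {d: (obs[d] / exp[d] if exp[d] > 0 else None) for d in DINUCLEOTIDES}
    chi2 = 0.0
    for d in DINUCLEOTIDES:
        e_count = exp[d] * n_windows
        if e_count > 0:
            chi2 += (counts[d] - e_count) ** 2 / e_count
    p = float(_sps.chi2.sf(chi2, df=15))
    return dataclasses.replace(
        profile,
        dinucleotide_obs=obs,
        dinucleotide_exp=exp,
        dinucleotide_ratio=ratio,
        chi2=chi2,
        chi2_p=p,
    )


def count_polya_signals(
    seq: CodingSequence, motifs: tuple[str, ...] = DEFAULT_POLYA_MOTIFS
) -> int:
    """Count polyadenylation-signal motifs, overlapping occurrences included.

    Only the positive strand is scanned: premature termination of element
    transcription requires the signal on the transcribed strand.
    """
    s = seq.sequence
    count = 0
    for motif in motifs:
        for i in range(len(s) - len(motif) + 1):
            if s[i : i + len(motif)] == motif:
                count += 1
    return count


def aa_composition(seq: CodingSequence) -> dict[str, int]:
    """Translation counts per amino acid; stops and N codons excluded."""
    counts: dict[str, int] = {}
    for codon in codons_of(seq):
        aa = translate_codon(codon)
        if aa is not None:
            counts[aa] = counts.get(aa, 0) + 1
    return counts


def full_profile(
    seq: CodingSequence, motifs: tuple[str, ...] = DEFAULT_POLYA_MOTIFS
) -> CompositionProfile:
    """All composition statistics of one validated sequence in one profile."""
    profile = dinucleotide_ratios(seq)
    gc1, gc2, gc3 = codon_position_gc(seq)
    return dataclasses.replace(
        profile,
        gc1=gc1,
        gc2=gc2,
        gc3=gc3,
        polyA_count=count_polya_signals(seq, motifs),
        aa_counts=aa_composition(seq),
    )
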