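"""Codon-usage bias statistics: RSCU, Nc, CAI/eCAI and RCDI/eRCDI.

All statistics operate on :class:`CodonUsageTable` objects (counts over
the 61 sense codons) and, for the two randomization-based expectations,
on the query sequence itself.  The reference table is built from a host
CDS set and stands in for the host's genome-wide codon usage.

Definitions
-----------
RSCU
    A codon's count divided by the mean count of its synonymous family;
    the family sum of RSCU equals the family size.
Nc (effective number of codons)
    Wright's estimator over degeneracy classes,
    ``Nc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6`` with family homozygosity
    ``F = sum(p_c^2)`` (frequency-based, default) or the small-sample
    corrected ``F = (n*sum(p^2) - 1)/(n - 1)``.  Ranges from 20 (one
    codon per amino acid) to 61 (uniform synonymous usage).
CAI
    Geometric mean, over query codon occurrences, of the relative
    adaptiveness ``w_c = f_ref(c) / max_{c' syn c} f_ref(c')``; Met, Trp
    and stops excluded.  1 means the query uses only each family's most
    common reference codon.
RCDI
    Mean, over query codon occurrences, of the ratio of query to
    reference per-amino-acid conditional codon frequencies.  1 when the
    two usages coincide; grows as the query deoptimizes.
eCAI / eRCDI
    Monte-Carlo expectations of CAI / RCDI under random codon usage at
    the query's base composition (eRCDI additionally preserves the
    query's amino-acid sequence).
"""

from __future__ import annotations

import dataclasses
import math
from collections import Counter
from typing import Iterable, Literal

import numpy as np

from .genetic_code import (
    AA_TO_CODONS,
    CODON_TO_AA,
    DEGENERACY_CLASSES,
    SENSE_CODONS,
    STOP_CODONS,
)
from .seq_io import CodingSequence, codons_of, validate_orf

#: pseudo-count added to zero reference counts within a family the query uses
ZERO_REF_PSEUDOCOUNT = 0.5


@dataclasses.dataclass
class CodonUsageTable:
    """Counts over the 61 sense codons plus per-family conditional frequencies."""

    counts: dict[str, int]
    source: str = "query_sequence"

    def __post_init__(self) -> None:
        bad = set(self.counts) - set(SENSE_CODONS)
        if bad:
            raise ValueError(f"non-sense codons in table: {sorted(bad)}")
        self.counts = {c: int(self.counts.get(c, 0)) for c in SENSE_CODONS}

    @classmethod
    def from_codons(cls, codons: Iterable[str], source: str = "query_sequence") -> "CodonUsageTable":
        tally = Counter(c for c in codons if c in CODON_TO_AA)
        return cls(counts=dict(tally), source=source)

    @classmethod
    def from_sequence(cls, seq: CodingSequence) -> "CodonUsageTable":
        return cls.from_codons(codons_of(seq))

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def family_total(self, aa: str) -> int:
        return sum(self.counts[c] for c in AA_TO_CODONS[aa])

    def cond_freq(self, pseudo_for: "CodonUsageTable | None" = None) -> dict[str, float]:
        """Per-codon frequency conditional on its amino acid.

        With ``pseudo_for`` given, families in which that query table uses
        a codon this table never counted get ``ZERO_REF_PSEUDOCOUNT``
        added to each of their zero-count codons before normalizing, so
        downstream ratios stay finite.
        """
        freq: dict[str, float] = {}
        for aa, codons in AA_TO_CODONS.items():
            counts = {c: float(self.counts[c]) for c in codons}
            if pseudo_for is not None:
                query_uses_zero = any(
                    pseudo_for.counts[c] > 0 and counts[c] == 0 for c in codons
                )
                if query_uses_zero:
                    for c in codons:
                        if counts[c] == 0:
                            counts[c] = ZERO_REF_PSEUDOCOUNT
            tot = sum(counts.values())
            for c in codons:
                freq[c] = counts[c] / tot if tot > 0 else float("nan")
        return freq


def build_reference_table(cds_set: Iterable[CodingSequence]) -> CodonUsageTable:
    """Pooled codon counts over a host CDS set (RefSeq-style reference)."""
    pooled: Counter[str] = Counter()
    n_ok = 0
    for seq in cds_set:
        v = seq if seq.frame_validated else validate_orf(seq)
        if not v.frame_validated:
            continue
        pooled.update(c for c in codons_of(v) if c in CODON_TO_AA)
        n_ok += 1
    if n_ok == 0:
        raise ValueError("no validated CDS in reference set")
    return CodonUsageTable(counts=dict(pooled), source="host_reference")


def rscu(table: CodonUsageTable) -> dict[str, float | None]:
    """Relative synonymous codon usage; ``None`` for codons of empty families."""
    out: dict[str, float | None] = {}
    for aa, codons in AA_TO_CODONS.items():
        tot = table.family_total(aa)
        size = len(codons)
        for c in codons:
            out[c] = (table.counts[c] / (tot / size)) if tot > 0 else None
    return out


def effective_number_of_codons(
    table: CodonUsageTable, sample_correction: bool = False
) -> float:
    """Wright's Nc, clipped to [20, 61].

    ``sample_correction=False`` (default) uses frequency-based family
    homozygosity ``F = sum(p^2)`` so the definitional extremes 20 and 61
    hold exactly; ``True`` uses the corrected ``(n*sum(p^2)-1)/(n-1)``.
    A degeneracy class with no countable family borrows the mean F of
    the families that were observed.
    """
    if table.total == 0:
        raise ValueError("empty codon-usage table")
    family_f: dict[str, float] = {}
    for aa, codons in AA_TO_CODONS.items():
        if len(codons) == 1:
            continue
        n = table.family_total(aa)
        if n == 0:
            continue
        p2 = sum((table.counts[c] / n) ** 2 for c in codons)
        if sample_correction:
            if n < 2:
                continue
            f = (n * p2 - 1) / (n - 1)
            if f <= 0:
                continue
        else:
            f = p2
        family_f[aa] = f

    if not family_f:
        raise ValueError("no degenerate family with countable codons")
    fallback = sum(family_f.values()) / len(family_f)

    nc = 2.0  # Met and Trp each contribute exactly one codon
    for k, aas in DEGENERACY_CLASSES.items():
        if k == 1:
            continue
        fs = [family_f[aa] for aa in aas if aa in family_f]
        f_bar = sum(fs) / len(fs) if fs else fallback
        nc += len(aas) / f_bar
    return float(min(61.0, max(20.0, nc)))


def _weights(reference: CodonUsageTable, query: CodonUsageTable) -> dict[str, float]:
    """Relative adaptiveness w_c of every sense codon vs the reference."""
    ref_freq = reference.cond_freq(pseudo_for=query)
    w: dict[str, float] = {}
    for aa, codons in AA_TO_CODONS.items():
        fmax = max(ref_freq[c] for c in codons)
        for c in codons:
            w[c] = ref_freq[c] / fmax if fmax > 0 else float("nan")
    return w


def cai(query: CodonUsageTable, reference: CodonUsageTable) -> float:
    """Codon adaptation index of the query against the reference usage."""
    w = _weights(reference, query)
    log_sum = 0.0
    n = 0
    for codon, count in query.counts.items():
        if count == 0 or len(AA_TO_CODONS[CODON_TO_AA[codon]]) == 1:
            continue
        if w[codon] <= 0:
            raise ValueError(f"codon {codon} has zero reference weight")
        log_sum += count * math.log(w[codon])
        n += count
    if n == 0:
        raise ValueError("query has no codons from degenerate families")
    return math.exp(log_sum / n)


def rcdi(query: CodonUsageTable, reference: CodonUsageTable) -> float:
    """Relative codon deoptimization index of the query against the reference."""
    ref_freq = reference.cond_freq(pseudo_for=query)
    query_freq = query.cond_freq()
    total = 0.0
    n = 0
    for codon, count in query.counts.items():
        if count == 0:
            continue
        if ref_freq[codon] <= 0:
            raise ValueError(f"codon {codon} has zero reference frequency")
        total += count * (query_freq[codon] / ref_freq[codon])
        n += count
    if n == 0:
        raise ValueError("empty query table")
    return total / n


def _mono_freqs(seq: CodingSequence) -> dict[str, float]:
    counts = Counter(ch for ch in seq.sequence if ch in "ACGT")
    tot = sum(counts.values())
    if tot == 0:
        raise ValueError("sequence has no unambiguous bases")
    return {b: counts[b] / tot for b in "ACGT"}


def _codon_probs_from_composition(mono: dict[str, float]) -> np.ndarray:
    """Probability of each sense codon under independent draws of its bases."""
    probs = np.array(
        [mono[c[0]] * mono[c[1]] * mono[c[2]] for c in SENSE_CODONS], dtype=float
    )
    tot = probs.sum()
    if tot <= 0:
        raise ValueError("degenerate base composition: only stop codons reachable")
    return probs / tot


def expected_cai(
    query: CodingSequence,
    reference: CodonUsageTable,
    n_random: int = 500,
    seed: int = 0,
    summary: Literal["mean", "q95"] = "mean",
) -> float:
    """Expected CAI under random codon usage at the query's base composition.

    Each of ``n_random`` replicates draws the query's codon count of
    sense codons with probability proportional to the product of the
    query's mononucleotide frequencies (stop codons excluded,
    renormalized); returns the mean or 95th percentile of the replicate
    CAI distribution.  Fixed seeds reproduce bit-identically.
    """
    if n_random < 100:
        raise ValueError("n_random must be >= 100")
    n_codons = len(codons_of(query))
    probs = _codon_probs_from_composition(_mono_freqs(query))
    rng = np.random.default_rng(seed)
    values = np.empty(n_random)
    for i in range(n_random):
        counts = rng.multinomial(n_codons, probs)
        table = CodonUsageTable(counts=dict(zip(SENSE_CODONS, counts)))
        values[i] = cai(table, reference)
    if summary == "q95":
        return float(np.quantile(values, 0.95))
    return float(values.mean())


def expected_rcdi(
    query: CodingSequence,
    reference: CodonUsageTable,
    n_random: int = 500,
    seed: int = 0,
) -> float:
    """Expected RCDI preserving the query's amino-acid sequence.

    Each replicate keeps the query's translation and redraws every codon
    among its synonyms with probability proportional to the product of
    the query's mononucleotide frequencies; returns the mean replicate
    RCDI.
    """
    if n_random < 100:
        raise ValueError("n_random must be >= 100")
    mono = _mono_freqs(query)
    # per-amino-acid synonym sampling distribution and site counts
    aa_sites = Counter(
        CODON_TO_AA[c] for c in codons_of(query) if c in CODON_TO_AA
    )
    fam_probs: dict[str, np.ndarray] = {}
    for aa in aa_sites:
        codons = AA_TO_CODONS[aa]
        p = np.array([mono[c[0]] * mono[c[1]] * mono[c[2]] for c in codons])
        if p.sum() <= 0:
            p = np.ones(len(codons))
        fam_probs[aa] = p / p.sum()
    rng = np.random.default_rng(seed)
    values = np.empty(n_random)
    for i in range(n_random):
        counts: dict[str, int] = {}
        for aa, n_sites in aa_sites.items():
            draw = rng.multinomial(n_sites, fam_probs[aa])
            for codon, k in zip(AA_TO_CODONS[aa], draw):
                if k:
                    counts[codon] = counts.get(codon, 0) + int(k)
        table = CodonUsageTable(counts=counts)
        values[i] = rcdi(table, reference)
    return float(values.mean())


@dataclasses.dataclass
class CodonBiasReport:
    """Per-sequence codon-bias summary (one Table-style row)."""

    seq_id: str
    nc: float
    cai: float
    ecai: float
    rcdi: float
    ercdi: float


def codon_bias_report(
    query: CodingSequence,
    reference: CodonUsageTable,
    n_random: int = 500,
    seed: int = 0,
    ecai_summary: Literal["mean", "q95"] = "mean",
) -> CodonBiasReport:
    """Compute Nc, CAI, eCAI, RCDI and eRCDI of one validated query."""
    table = CodonUsageTable.from_sequence(query)
    return CodonBiasReport(
        seq_id=query.id,
        nc=effective_number_of_codons(table),
        cai=cai(table, reference),
        ecai=expected_cai(query, reference, n_random=n_random, seed=seed, summary=ecai_summary),
        rcdi=rcdi(table, reference),
        ercdi=expected_rcdi(query, reference, n_random=n_random, seed=seed),
    )
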