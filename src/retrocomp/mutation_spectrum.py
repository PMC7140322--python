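"""De novo mutation spectra of element families from aligned genomic copies.

The procedure takes each family's consensus (treated as the ancestral
state — the families analyzed are young, so ancestral/derived polarity
is unambiguous) and its aligned genomic copies, calls substitutions per
copy, drops mutations shared by two or more copies (likely inherited
from a common progenitor rather than de novo), classifies C→* and G→*
changes by CpG context on the consensus, normalizes counts by the
mutational opportunity (source-base count in the consensus) and
summarizes the GC→AT excess.

Indel columns and columns containing N are skipped throughout; only
substitutions are tabulated.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Iterable, Literal, Sequence

from .genetic_code import NUCLEOTIDES, SUBSTITUTIONS
from .seq_io import FamilyBundle

Variant = tuple[int, str, str]  # (consensus position, from base, to base)

#: substitutions pooled in the numerator (GC→AT) / denominator (AT→GC)
GC_TO_AT: tuple[Variant, ...] = (("C", "T"), ("C", "A"), ("G", "A"), ("G", "T"))  # type: ignore[assignment]
AT_TO_GC: tuple[Variant, ...] = (("T", "C"), ("A", "C"), ("A", "G"), ("T", "G"))  # type: ignore[assignment]


def call_variants(bundle: FamilyBundle) -> list[list[Variant]]:
    """Per-copy substitution lists in consensus (ungapped, 0-based) coordinates.

    Alignment columns where either the consensus or the copy carries a
    gap or an N are skipped.
    """
    # map alignment column -> consensus coordinate
    col_to_pos: list[int | None] = []
    pos = 0
    for ch in bundle.consensus_aligned:
        if ch == "-":
            col_to_pos.append(None)
        else:
            col_to_pos.append(pos)
            pos += 1
    out: list[list[Variant]] = []
    for copy in bundle.copies:
        variants: list[Variant] = []
        for col, (a, b) in enumerate(zip(bundle.consensus_aligned, copy)):
            if a in "-N" or b in "-N":
                continue
            if a != b:
                variants.append((col_to_pos[col], a, b))  # type: ignore[arg-type]
        out.append(variants)
    return out


def filter_singletons(per_copy_variants: Sequence[Sequence[Variant]]) -> list[Variant]:
    """Keep (position, from, to) triples observed in exactly one copy.

    Two *different* substitutions at the same position remain singletons;
    sharing means the identical triple in two or more copies.
    """
    if len(per_copy_variants) < 2:
        raise ValueError("singleton filtering needs at least 2 copies")
    tally: Counter[Variant] = Counter()
    for variants in per_copy_variants:
        tally.update(set(variants))
    return [v for variants in per_copy_variants for v in variants if tally[v] == 1]


def classify_cpg_context(variant: Variant, consensus: str) -> Literal["CpG", "nonCpG"]:
    """CpG-context call from the consensus (ancestral) sequence.

    A C→* change is CpG-context iff the consensus has G immediately 3';
    a G→* change iff the consensus has C immediately 5'.  At a sequence
    edge the single available neighbor decides.
    """
    pos, from_base, _ = variant
    if from_base == "C":
        return "CpG" if pos + 1 < len(consensus) and consensus[pos + 1] == "G" else "nonCpG"
    if from_base == "G":
        return "CpG" if pos - 1 >= 0 and consensus[pos - 1] == "C" else "nonCpG"
    return "nonCpG"


@dataclasses.dataclass
class MutationSpectrum:
    """Singleton mutation spectrum of one family (or a pooled group).

    ``raw_counts``/``cpg_counts``/``non_cpg_counts`` map each of the 12
    substitutions to its singleton count (CpG counts are nonzero only
    for C→* and G→* changes); ``normalized_pct`` rescales the
    opportunity-normalized rates to sum to 100.
    """

    raw_counts: dict[tuple[str, str], int]
    cpg_counts: dict[tuple[str, str], int]
    non_cpg_counts: dict[tuple[str, str], int]
    normalized_pct: dict[tuple[str, str], float]
    rates: dict[tuple[str, str], float]
    gc_to_at_excess: float
    n_copies: int
    n_singletons: int


def normalize_spectrum(
    counts: dict[tuple[str, str], int], base_counts: dict[str, int]
) -> tuple[dict[tuple[str, str], float], dict[tuple[str, str], float]]:
    """Opportunity-normalized rates and their percentage rescaling.

    ``rate(X→Y) = count / count of X in the consensus``; substitutions
    whose source base is absent from the consensus are excluded (rate
    undefined).  Percentages sum to 100 over the defined substitutions.
    """
    rates: dict[tuple[str, str], float] = {}
    for sub in SUBSTITUTIONS:
        src = sub[0]
        if base_counts.get(src, 0) > 0:
            rates[sub] = counts.get(sub, 0) / base_counts[src]
    total = sum(rates.values())
    if total > 0:
        pct = {sub: 100.0 * r / total for sub, r in rates.items()}
    else:
        pct = {sub: 0.0 for sub in rates}
    return rates, pct


def gc_to_at_excess(rates: dict[tuple[str, str], float]) -> float:
    """Pooled GC→AT rate over pooled AT→GC rate; ``inf`` on a zero denominator."""
    num = sum(rates.get(sub, 0.0) for sub in GC_TO_AT)
    den = sum(rates.get(sub, 0.0) for sub in AT_TO_GC)
    if den == 0:
        return float("inf")
    return num / den


def family_spectrum(bundle: FamilyBundle) -> MutationSpectrum:
    """Full singleton spectrum of one family: call, filter, classify, normalize."""
    consensus = bundle.consensus.sequence
    singletons = filter_singletons(call_variants(bundle))
    raw: Counter[tuple[str, str]] = Counter()
    cpg: Counter[tuple[str, str]] = Counter()
    non_cpg: Counter[tuple[str, str]] = Counter()
    for variant in singletons:
        sub = (variant[1], variant[2])
        raw[sub] += 1
        if classify_cpg_context(variant, consensus) == "CpG":
            cpg[sub] += 1
        else:
            non_cpg[sub] += 1
    base_counts = Counter(ch for ch in consensus if ch in NUCLEOTIDES)
    rates, pct = normalize_spectrum(dict(raw), dict(base_counts))
    return MutationSpectrum(
        raw_counts={s: raw.get(s, 0) for s in SUBSTITUTIONS},
        cpg_counts={s: cpg.get(s, 0) for s in SUBSTITUTIONS},
        non_cpg_counts={s: non_cpg.get(s, 0) for s in SUBSTITUTIONS},
        normalized_pct=pct,
        rates=rates,
        gc_to_at_excess=gc_to_at_excess(rates),
        n_copies=bundle.n_copies,
        n_singletons=len(singletons),
    )


def pooled_spectrum(bundles: Iterable[FamilyBundle]) -> MutationSpectrum:
    """Spectrum pooled over several families (counts and opportunities summed)."""
    raw: Counter[tuple[str, str]] = Counter()
    cpg: Counter[tuple[str, str]] = Counter()
    non_cpg: Counter[tuple[str, str]] = Counter()
    base_counts: Counter[str] = Counter()
    n_copies = 0
    n_singletons = 0
    for bundle in bundles:
        spec = family_spectrum(bundle)
        raw.update(spec.raw_counts)
        cpg.update(spec.cpg_counts)
        non_cpg.update(spec.non_cpg_counts)
        base_counts.update(
            ch for ch in bundle.consensus.sequence if ch in NUCLEOTIDES
        )
        n_copies += spec.n_copies
        n_singletons += spec.n_singletons
    rates, pct = normalize_spectrum(dict(raw), dict(base_counts))
    return MutationSpectrum(
        raw_counts={s: raw.get(s, 0) for s in SUBSTITUTIONS},
        cpg_counts={s: cpg.get(s, 0) for s in SUBSTITUTIONS},
        non_cpg_counts={s: non_cpg.get(s, 0) for s in SUBSTITUTIONS},
        normalized_pct=pct,
        rates=rates,
        gc_to_at_excess=gc_to_at_excess(rates),
        n_copies=n_copies,
        n_singletons=n_singletons,
    )


def filter_families_by_divergence(
    bundles: Iterable[FamilyBundle], max_divergence: float = 0.05
) -> tuple[list[FamilyBundle], int]:
    """Keep families whose mean copy divergence is below the threshold.

    Restricting to young families (default < 5% divergence from the
    consensus) keeps the consensus a reliable ancestral state.  Returns
    (retained bundles, number dropped).
    """
    kept, dropped = [], 0
    for bundle in bundles:
        if bundle.mean_divergence() < max_divergence:
            kept.append(bundle)
        else:
            dropped += 1
    return kept, dropped


def context_opportunities(consensus: str) -> tuple[dict[str, int], dict[str, int]]:
    """Base counts of the consensus split by CpG context.

    Returns ``(cpg, non_cpg)`` dicts: a C counts as CpG-context when
    followed by G, a G when preceded by C; A and T are always non-CpG.
    """
    cpg: Counter[str] = Counter()
    non_cpg: Counter[str] = Counter()
    for i, ch in enumerate(consensus):
        if ch not in NUCLEOTIDES:
            continue
        in_cpg = (
            ch == "C" and i + 1 < len(consensus) and consensus[i + 1] == "G"
        ) or (ch == "G" and i > 0 and consensus[i - 1] == "C")
        (cpg if in_cpg else non_cpg)[ch] += 1
    return dict(cpg), dict(non_cpg)


def branch_mutation_probability(
    singleton_count: int, opportunity: int, n_copies: int
) -> float:
    """Per-copy, per-site mutation probability from a singleton count.

    A mutation is retained as a singleton only when it occurred in
    exactly one copy, so the observed per-copy singleton rate is
    ``r = q (1-q)^(n-1)`` for true branch probability ``q``; at high
    rates (CpG sites) recurrent hits are silently removed by the
    singleton filter and the raw rate underestimates ``q``.  This
    inverts the retention curve on ``(0, 1/n]`` (rates beyond the curve
    maximum are clipped to ``1/n``).
    """
    from scipy.optimize import brentq

    if opportunity <= 0 or n_copies < 2:
        raise ValueError("need positive opportunity and >= 2 copies")
    r = singleton_count / (opportunity * n_copies)
    if r <= 0:
        return 0.0
    q_max = 1.0 / n_copies  # mode of q(1-q)^(n-1)
    if q_max * (1 - q_max) ** (n_copies - 1) <= r:
        return q_max
    return float(brentq(lambda q: q * (1 - q) ** (n_copies - 1) - r, 1e-15, q_max))


def corrected_context_rates(
    bundles: Sequence[FamilyBundle],
) -> tuple[dict[tuple[str, str], float], dict[tuple[str, str], float], float]:
    """Recurrence-corrected substitution probabilities split by CpG context.

    Pools singleton counts and context-specific opportunities over the
    families, inverts the singleton-retention curve per substitution,
    and returns ``(non_cpg_rates, cpg_rates, cpg_multiplier)`` where the
    multiplier averages the CpG/non-CpG rate ratio of the two deamination
    channels C→T and G→A.
    """
    cpg_counts: Counter[tuple[str, str]] = Counter()
    non_cpg_counts: Counter[tuple[str, str]] = Counter()
    cpg_opp: Counter[str] = Counter()
    non_cpg_opp: Counter[str] = Counter()
    n_copies_total = 0
    for bundle in bundles:
        spec = family_spectrum(bundle)
        cpg_counts.update(spec.cpg_counts)
        non_cpg_counts.update(spec.non_cpg_counts)
        c, nc = context_opportunities(bundle.consensus.sequence)
        cpg_opp.update(c)
        non_cpg_opp.update(nc)
        n_copies_total += bundle.n_copies
    n_bar = round(n_copies_total / len(bundles))
    non_cpg_rates: dict[tuple[str, str], float] = {}
    cpg_rates: dict[tuple[str, str], float] = {}
    for sub in SUBSTITUTIONS:
        src = sub[0]
        if non_cpg_opp.get(src, 0) > 0:
            non_cpg_rates[sub] = branch_mutation_probability(
                non_cpg_counts[sub], non_cpg_opp[src], n_bar
            )
        if cpg_opp.get(src, 0) > 0:
            cpg_rates[sub] = branch_mutation_probability(
                cpg_counts[sub], cpg_opp[src], n_bar
            )
    ratios = [
        cpg_rates[sub] / non_cpg_rates[sub]
        for sub in (("C", "T"), ("G", "A"))
        if cpg_rates.get(sub) and non_cpg_rates.get(sub)
    ]
    multiplier = sum(ratios) / len(ratios) if ratios else float("nan")
    return non_cpg_rates, cpg_rates, multiplier


def divergence_matched_subsets(
    group_a: Sequence[FamilyBundle],
    group_b: Sequence[FamilyBundle],
    seed: int = 0,
) -> tuple[list[FamilyBundle], list[FamilyBundle]]:
    """Greedy nearest-divergence pairing of two family groups.

    Used to compare spectra of two clades at matched ages: each family of
    the smaller group is paired with the unused family of the other group
    whose mean divergence is closest (ties broken by input order; the
    seed only fixes the processing order).
    """
    import random

    rng = random.Random(seed)
    small, large = (group_a, group_b) if len(group_a) <= len(group_b) else (group_b, group_a)
    order = list(range(len(small)))
    rng.shuffle(order)
    available = list(range(len(large)))
    pairs: list[tuple[int, int]] = []
    for i in order:
        d = small[i].mean_divergence()
        j = min(available, key=lambda k: abs(large[k].mean_divergence() - d))
        available.remove(j)
        pairs.append((i, j))
    sel_small = [small[i] for i, _ in sorted(pairs)]
    sel_large = [large[j] for _, j in sorted(pairs)]
    if len(group_a) <= len(group_b):
        return sel_small, sel_large
    return sel_large, sel_small
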