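"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators mirror the three real inputs:

* :func:`simulate_host_cds` — a host CDS set drawn from a chosen
  per-amino-acid codon-usage profile (stands in for a RefSeq CDS
  download) from which the reference codon-usage table is built;
* :func:`simulate_element_consensus` — an element ORF of target base
  composition (e.g. the A-biased, 67%-AT lizard-L1-like default);
* :func:`simulate_family` — diverged genomic copies of a consensus
  under a 4x4 substitution matrix with CpG hypermutability and a
  controllable shared (ancestral) vs unique (singleton) mutation split,
  returning both the family bundle and a complete injection log.

Mutations are independent per-site Bernoulli events — adequate in the
young-family regime (< 5% divergence) the analyses restrict to, where
back-mutation is negligible.  Everything is bit-reproducible under a
fixed seed.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .genetic_code import AA_TO_CODONS, AMINO_ACIDS, NUCLEOTIDES, STOP_CODONS
from .seq_io import CodingSequence, FamilyBundle, validate_orf

#: lizard-L1-like target composition: 67% AT with a strong A bias
DEFAULT_TARGET_BASE_FREQS: dict[str, float] = {"A": 0.43, "C": 0.17, "G": 0.16, "T": 0.24}

#: transition-biased substitution weights (rows exclude self, normalized on
#: use); GC rows lean toward AT targets, giving a GC→AT excess of 1.7
DEFAULT_SUBSTITUTION_MATRIX: dict[str, dict[str, float]] = {
    "A": {"C": 0.20, "G": 0.30, "T": 0.50},
    "C": {"A": 0.25, "G": 0.15, "T": 0.60},
    "G": {"A": 0.60, "C": 0.15, "T": 0.25},
    "T": {"A": 0.50, "C": 0.30, "G": 0.20},
}


@dataclasses.dataclass
class FamilySimConfig:
    """Ground-truth parameters for one simulated family.

    ``shared_fraction`` is the fraction of the expected divergence placed
    on the ancestral branch of a star tree (those mutations appear in
    every copy and must be removed by the singleton filter);
    ``cpg_multiplier`` scales the per-site mutation rate of C and G in
    CpG context, mirroring the 10-50x hypermutability of methylated CpG.
    """

    n_copies: int = 10
    expected_divergence: float = 0.03
    substitution_matrix: dict[str, dict[str, float]] = dataclasses.field(
        default_factory=lambda: {b: dict(r) for b, r in DEFAULT_SUBSTITUTION_MATRIX.items()}
    )
    cpg_multiplier: float = 10.0
    shared_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_copies < 2:
            raise ValueError("n_copies must be >= 2")
        if not 0 <= self.shared_fraction < 1:
            raise ValueError("shared_fraction must be in [0, 1)")
        if self.expected_divergence > 0.5:
            raise ValueError("expected_divergence > 0.5: the no-back-mutation model breaks")
        if self.cpg_multiplier < 1:
            raise ValueError("cpg_multiplier must be >= 1")
        for base, row in self.substitution_matrix.items():
            if base in row:
                raise ValueError(f"substitution matrix row {base} contains a self-transition")


def matrix_gc_to_at_excess(matrix: dict[str, dict[str, float]]) -> float:
    """Analytic GC→AT excess implied by a substitution matrix.

    With uniform per-site rates the opportunity-normalized rate of X→Y
    is proportional to the normalized row weight P(Y|X), so the excess
    reduces to a ratio of row-weight sums.
    """
    rows = {
        b: {t: w / sum(matrix[b].values()) for t, w in matrix[b].items()}
        for b in matrix
    }
    num = rows["C"]["T"] + rows["C"]["A"] + rows["G"]["A"] + rows["G"]["T"]
    den = rows["T"]["C"] + rows["A"]["C"] + rows["A"]["G"] + rows["T"]["G"]
    return num / den


def uniform_codon_profile() -> dict[str, dict[str, float]]:
    """Per-amino-acid profile with equal synonym frequencies."""
    return {
        aa: {c: 1.0 / len(codons) for c in codons}
        for aa, codons in AA_TO_CODONS.items()
    }


def gc_preferring_codon_profile(strength: float = 3.0) -> dict[str, dict[str, float]]:
    """Host-exome-like profile preferring G/C-ending synonyms.

    Each codon is weighted by ``strength`` raised to the number of G/C
    bases at its third position (0 or 1), then renormalized per family.
    """
    profile = {}
    for aa, codons in AA_TO_CODONS.items():
        weights = {c: strength if c[2] in "GC" else 1.0 for c in codons}
        tot = sum(weights.values())
        profile[aa] = {c: w / tot for c, w in weights.items()}
    return profile


def _check_profile(profile: dict[str, dict[str, float]]) -> None:
    for aa, codons in AA_TO_CODONS.items():
        if aa not in profile:
            raise ValueError(f"profile missing amino acid {aa}")
        fam = profile[aa]
        if set(fam) - set(codons):
            raise ValueError(f"profile for {aa} lists non-synonymous codons")
        tot = sum(fam.values())
        if not np.isclose(tot, 1.0, atol=1e-6):
            raise ValueError(f"profile for {aa} sums to {tot}, expected 1")


def simulate_host_cds(
    codon_profile: dict[str, dict[str, float]] | None = None,
    n_genes: int = 50,
    mean_length: int = 400,
    seed: int = 0,
) -> list[CodingSequence]:
    """Simulate a host CDS set under a per-amino-acid codon-usage profile.

    Genes start with ATG, end with a stop codon, contain no internal
    stop, and have Poisson-distributed codon lengths around
    ``mean_length``.  Amino acids of internal codons are drawn uniformly.
    """
    profile = codon_profile if codon_profile is not None else gc_preferring_codon_profile()
    _check_profile(profile)
    rng = np.random.default_rng(seed)
    fam_codons = {aa: list(profile[aa]) for aa in profile}
    fam_probs = {aa: np.array([profile[aa][c] for c in fam_codons[aa]]) for aa in profile}
    stops = sorted(STOP_CODONS)
    genes = []
    for g in range(n_genes):
        n_codons = max(10, int(rng.poisson(mean_length)))
        aas = rng.choice(len(AMINO_ACIDS), size=n_codons)
        codons = ["ATG"]
        for ai in aas:
            aa = AMINO_ACIDS[ai]
            codons.append(rng.choice(fam_codons[aa], p=fam_probs[aa]))
        codons.append(stops[rng.integers(len(stops))])
        seq = CodingSequence(
            id=f"hostgene_{g:04d}", sequence="".join(codons), host="synthetic_host"
        )
        genes.append(validate_orf(seq))
    return genes


def simulate_element_consensus(
    target_base_freqs: dict[str, float] | None = None,
    length_codons: int = 1000,
    seed: int = 0,
    id: str = "consensus",
    clade: str = "synthetic",
    host: str = "synthetic_host",
    orf_label: str = "ORF2",
) -> CodingSequence:
    """Simulate an element ORF of target base composition.

    Codons are drawn base-by-base from ``target_base_freqs``; stop codons
    are rejection-resampled so the result is a valid ORF.  For lengths of
    1,000 codons or more the realized composition lands within about 2
    percentage points of the target.
    """
    freqs = dict(target_base_freqs or DEFAULT_TARGET_BASE_FREQS)
    if set(freqs) != set(NUCLEOTIDES):
        raise ValueError("target_base_freqs must key A, C, G, T")
    p = np.array([freqs[b] for b in NUCLEOTIDES])
    if not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise ValueError(f"target base frequencies sum to {p.sum()}, expected 1")
    rng = np.random.default_rng(seed)
    codons = ["ATG"]
    for _ in range(length_codons - 1):
        for _attempt in range(1000):
            codon = "".join(np.array(NUCLEOTIDES)[rng.choice(4, size=3, p=p)])
            if codon not in STOP_CODONS:
                codons.append(codon)
                break
        else:
            raise ValueError("target composition yields only stop codons")
    seq = CodingSequence(
        id=id, sequence="".join(codons), clade=clade, host=host, orf_label=orf_label
    )
    return validate_orf(seq)


def _cpg_flags(sequence: str) -> np.ndarray:
    """True at positions whose base sits in a CpG dinucleotide."""
    flags = np.zeros(len(sequence), dtype=bool)
    for i in range(len(sequence) - 1):
        if sequence[i] == "C" and sequence[i + 1] == "G":
            flags[i] = True
            flags[i + 1] = True
    return flags


def _mutate_branch(
    ancestor: str,
    per_site_divergence: float,
    config: FamilySimConfig,
    rng: np.random.Generator,
    branch: str,
) -> tuple[str, list[dict]]:
    """Apply one branch of per-site Bernoulli mutations; CpG context is
    evaluated on the branch's ancestral sequence at injection time."""
    n = len(ancestor)
    weights = np.ones(n)
    weights[_cpg_flags(ancestor)] = config.cpg_multiplier
    probs = np.clip(per_site_divergence * weights / weights.mean(), 0.0, 1.0)
    hits = np.nonzero(rng.random(n) < probs)[0]
    seq = list(ancestor)
    log = []
    for pos in hits:
        src = ancestor[pos]
        row = config.substitution_matrix.get(src)
        if not row:
            continue
        targets = sorted(row)
        w = np.array([row[t] for t in targets], dtype=float)
        dst = targets[rng.choice(len(targets), p=w / w.sum())]
        seq[pos] = dst
        log.append({"branch": branch, "position": int(pos), "from": src, "to": dst})
    return "".join(seq), log


def simulate_family(
    consensus: CodingSequence, config: FamilySimConfig | None = None
) -> tuple[FamilyBundle, list[dict]]:
    """Simulate a family of diverged copies on a star tree.

    A fraction ``shared_fraction`` of the expected divergence accrues on
    the ancestral branch (mutations shared by every copy); each copy
    then accrues independent mutations for the remainder.  Returns the
    bundle (gap-free alignment, consensus first by convention) and the
    injection log recording every (branch, position, from, to).
    """
    config = config or FamilySimConfig()
    rng = np.random.default_rng(config.seed)
    d = config.expected_divergence
    ancestor, log = _mutate_branch(
        consensus.sequence, config.shared_fraction * d, config, rng, "ancestral"
    )
    copies, copy_ids = [], []
    for i in range(config.n_copies):
        branch = f"copy_{i:03d}"
        copy, branch_log = _mutate_branch(
            ancestor, (1 - config.shared_fraction) * d, config, rng, branch
        )
        copies.append(copy)
        copy_ids.append(f"{consensus.id}_{branch}")
        log.extend(branch_log)
    bundle = FamilyBundle(
        consensus=consensus,
        consensus_aligned=consensus.sequence,
        copies=copies,
        copy_ids=copy_ids,
    )
    return bundle, log


def simulate_family_set(
    n_families: int = 20,
    length_codons: int = 1000,
    config: FamilySimConfig | None = None,
    target_base_freqs: dict[str, float] | None = None,
    seed: int = 0,
    clade: str = "synthetic",
    host: str = "synthetic_host",
) -> list[tuple[FamilyBundle, list[dict]]]:
    """Simulate several families with fresh consensi, one derived seed each."""
    base = config or FamilySimConfig()
    out = []
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_families)
    for i, child in enumerate(children):
        fam_seed = int(child.generate_state(1)[0] % (2**31))
        consensus = simulate_element_consensus(
            target_base_freqs,
            length_codons=length_codons,
            seed=fam_seed,
            id=f"{clade}_fam{i:03d}",
            clade=clade,
            host=host,
        )
        cfg = dataclasses.replace(base, seed=fam_seed + 1)
        out.append(simulate_family(consensus, cfg))
    return out
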