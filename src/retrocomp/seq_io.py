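"""FASTA input/output, ORF validation and codon iteration.

Coding sequences are carried around as :class:`CodingSequence` records:
the nucleotide sequence on the element's positive strand plus the
metadata the analyses group by (clade, host organism, ORF label).
Metadata rides in FASTA headers as ``key=value`` tokens after the id,
e.g. ``>L1-3_AC clade=L1 host=lizard orf=ORF2``; unknown keys are
ignored and missing ones default to ``"unknown"``.

Internally all coordinates are 0-based half-open; human-readable
reports use 1-based positions.
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetic_code import STOP_CODONS

_VALID_CHARS = re.compile(r"^[ACGTN]*$")


@dataclasses.dataclass
class CodingSequence:
    """One ORF sequence with its grouping metadata.

    ``frame_validated`` is only set by :func:`validate_orf`; when true the
    sequence length is a multiple of 3, contains no internal stop codon,
    and any trailing stop codon has been trimmed.
    """

    id: str
    sequence: str
    clade: str = "unknown"
    host: str = "unknown"
    orf_label: str = "unknown"
    frame_validated: bool = False

    def __len__(self) -> int:
        return len(self.sequence)


@dataclasses.dataclass
class FamilyBundle:
    """A consensus plus its aligned genomic copies.

    All aligned strings (``consensus_aligned`` and every entry of
    ``copies``) have identical length; gap characters are ``-``.
    ``per_copy_divergence`` is mismatches over compared columns (columns
    with a gap or N in either sequence are not compared).
    """

    consensus: CodingSequence
    consensus_aligned: str
    copies: list[str]
    copy_ids: list[str]

    def __post_init__(self) -> None:
        lengths = {len(self.consensus_aligned)} | {len(c) for c in self.copies}
        if len(lengths) > 1:
            raise ValueError(
                f"family {self.consensus.id}: aligned sequences have unequal lengths {sorted(lengths)}"
            )

    @property
    def n_copies(self) -> int:
        return len(self.copies)

    def per_copy_divergence(self) -> list[float]:
        """Mismatch fraction of each copy vs the consensus, gaps/N excluded."""
        out = []
        for copy in self.copies:
            compared = mismatches = 0
            for a, b in zip(self.consensus_aligned, copy):
                if a in "-N" or b in "-N":
                    continue
                compared += 1
                if a != b:
                    mismatches += 1
            out.append(mismatches / compared if compared else 0.0)
        return out

    def mean_divergence(self) -> float:
        div = self.per_copy_divergence()
        return sum(div) / len(div) if div else 0.0


def _parse_header(description: str) -> tuple[str, dict[str, str]]:
    tokens = description.split()
    rec_id = tokens[0] if tokens else ""
    meta = {}
    for tok in tokens[1:]:
        if "=" in tok:
            key, _, value = tok.partition("=")
            meta[key.lower()] = value
    return rec_id, meta


def read_cds_fasta(path: str | Path) -> list[CodingSequence]:
    """Read a multi-FASTA of coding sequences with header metadata.

    Sequences are uppercased (soft-masking discarded); ``N`` is allowed.
    Raises ``ValueError`` on an empty file or on non-nucleotide characters,
    naming the offending record.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not _VALID_CHARS.match(seq):
            bad = sorted(set(seq) - set("ACGTN"))
            raise ValueError(
                f"record {rec.id!r}: non-nucleotide characters {bad}"
            )
        rec_id, meta = _parse_header(rec.description)
        records.append(
            CodingSequence(
                id=rec_id,
                sequence=seq,
                clade=meta.get("clade", "unknown"),
                host=meta.get("host", "unknown"),
                orf_label=meta.get("orf", "unknown"),
            )
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_cds_fasta(records: Iterable[CodingSequence], path: str | Path) -> None:
    """Write records with metadata serialized back into the header."""
    out = []
    for rec in records:
        desc = f"clade={rec.clade} host={rec.host} orf={rec.orf_label}"
        out.append(SeqRecord(Seq(rec.sequence), id=rec.id, description=desc))
    SeqIO.write(out, str(path), "fasta")


def read_alignment_fasta(path: str | Path) -> FamilyBundle:
    """Read a per-family gapped alignment; the consensus is the first record."""
    recs = list(SeqIO.parse(str(path), "fasta"))
    if len(recs) < 2:
        raise ValueError(f"{path}: alignment needs a consensus plus >=1 copy")
    cons_aligned = str(recs[0].seq).upper()
    cons_id, meta = _parse_header(recs[0].description)
    consensus = CodingSequence(
        id=cons_id,
        sequence=cons_aligned.replace("-", ""),
        clade=meta.get("clade", "unknown"),
        host=meta.get("host", "unknown"),
        orf_label=meta.get("orf", "unknown"),
    )
    return FamilyBundle(
        consensus=consensus,
        consensus_aligned=cons_aligned,
        copies=[str(r.seq).upper() for r in recs[1:]],
        copy_ids=[r.id for r in recs[1:]],
    )


def write_alignment_fasta(bundle: FamilyBundle, path: str | Path) -> None:
    cons = bundle.consensus
    desc = f"clade={cons.clade} host={cons.host} orf={cons.orf_label}"
    recs = [SeqRecord(Seq(bundle.consensus_aligned), id=cons.id, description=desc)]
    for cid, copy in zip(bundle.copy_ids, bundle.copies):
        recs.append(SeqRecord(Seq(copy), id=cid, description=""))
    SeqIO.write(recs, str(path), "fasta")


def validate_orf(seq: CodingSequence) -> CodingSequence:
    """Check reading frame and stop codons; trim a trailing stop.

    Returns a new record with ``frame_validated`` set.  Validation passes
    iff the length is a multiple of 3 and no internal stop codon occurs;
    a terminal stop codon, if present, is removed so that downstream
    codon statistics see only sense codons.
    """
    if not seq.sequence:
        return dataclasses.replace(seq, frame_validated=False)
    s = seq.sequence
    if len(s) % 3 != 0:
        return dataclasses.replace(seq, frame_validated=False)
    codons = [s[i : i + 3] for i in range(0, len(s), 3)]
    if any(c in STOP_CODONS for c in codons[:-1]):
        return dataclasses.replace(seq, frame_validated=False)
    if codons and codons[-1] in STOP_CODONS:
        s = s[:-3]
    return dataclasses.replace(seq, sequence=s, frame_validated=True)


def iter_codons(seq: CodingSequence) -> Iterator[tuple[str, bool]]:
    """Yield ``(codon, has_n)`` pairs in order over a validated sequence.

    ``has_n`` flags codons containing N; callers exclude those from codon
    statistics.  Raises ``ValueError`` on unvalidated input.
    """
    if not seq.frame_validated:
        raise ValueError(f"sequence {seq.id!r} has not passed ORF validation")
    for i in range(0, len(seq.sequence), 3):
        codon = seq.sequence[i : i + 3]
        yield codon, "N" in codon


def codons_of(seq: CodingSequence, *, skip_n: bool = True) -> list[str]:
    """Codon list of a validated sequence, N-containing codons dropped by default."""
    return [c for c, has_n in iter_codons(seq) if not (skip_n and has_n)]
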