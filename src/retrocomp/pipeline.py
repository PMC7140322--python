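"""End-to-end analysis stages producing the report tables.

Each stage consumes the standard inputs (consensus CDS FASTA, per-family
alignment FASTAs, host CDS FASTA), runs the corresponding module and
returns pandas DataFrames; the writers serialize them as TSV with a
commented header recording the seed and parameters so reruns are
byte-identical.

Aggregation key for group summaries is ``(clade, host)``; families are
weighted equally within a group (unweighted mean ± sd).
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

from . import composition as comp
from . import codon_usage as cu
from . import mutation_spectrum as ms
from . import stats_compare as sc
from .genetic_code import CODON_TO_AA, SENSE_CODONS, SUBSTITUTIONS
from .seq_io import (
    CodingSequence,
    codons_of,
    read_alignment_fasta,
    read_cds_fasta,
    validate_orf,
)


def _validated(records: Iterable[CodingSequence]) -> list[CodingSequence]:
    out = []
    for rec in records:
        v = validate_orf(rec)
        if v.frame_validated:
            out.append(v)
    return out


def write_tsv(df: pd.DataFrame, path: str | Path, header_lines: Sequence[str] = ()) -> None:
    """TSV with ``#``-commented provenance header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def composition_table(records: Iterable[CodingSequence]) -> pd.DataFrame:
    """Per-sequence composition rows: %AT/%GC/%A, GC1-3, polyA, dinucleotide ratios."""
    rows = []
    for rec in _validated(records):
        profile = comp.full_profile(rec)
        row = {
            "id": rec.id,
            "clade": rec.clade,
            "host": rec.host,
            "orf": rec.orf_label,
            "length": len(rec.sequence),
            "pct_AT": profile.pct_AT,
            "pct_GC": profile.pct_GC,
            "pct_A": profile.pct_A,
            "GC1": profile.gc1,
            "GC2": profile.gc2,
            "GC3": profile.gc3,
            "polyA": profile.polyA_count,
            "dinuc_chi2": profile.chi2,
            "dinuc_chi2_p": profile.chi2_p,
        }
        for d in comp.DINUCLEOTIDES:
            row[f"ratio_{d[0]}p{d[1]}"] = profile.dinucleotide_ratio[d]
        rows.append(row)
    return pd.DataFrame(rows)


def group_summary(per_seq: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    """Unweighted mean ± sd per (clade, host) for the requested columns."""
    if per_seq.empty:
        return pd.DataFrame(columns=["clade", "host", "N"])
    grouped = per_seq.groupby(["clade", "host"])
    out = grouped.size().rename("N").reset_index()
    for col in columns:
        agg = grouped[col].agg(["mean", "std"]).reset_index()
        out[f"{col}_mean"] = agg["mean"]
        out[f"{col}_sd"] = agg["std"]
    return out


def codon_bias_table(
    records: Iterable[CodingSequence],
    reference: cu.CodonUsageTable,
    n_random: int = 500,
    seed: int = 0,
    ecai_summary: Literal["mean", "q95"] = "mean",
) -> pd.DataFrame:
    """Per-sequence Nc, CAI, eCAI, RCDI, eRCDI against the host reference."""
    rows = []
    for i, rec in enumerate(_validated(records)):
        rep = cu.codon_bias_report(
            rec, reference, n_random=n_random, seed=seed + i, ecai_summary=ecai_summary
        )
        rows.append(
            {
                "id": rec.id,
                "clade": rec.clade,
                "host": rec.host,
                "orf": rec.orf_label,
                "Nc": rep.nc,
                "CAI": rep.cai,
                "eCAI": rep.ecai,
                "RCDI": rep.rcdi,
                "eRCDI": rep.ercdi,
            }
        )
    return pd.DataFrame(rows)


def rscu_matrix(groups: dict[str, Iterable[CodingSequence]]) -> pd.DataFrame:
    """RSCU per codon (rows) by sequence group (columns), concatenated per group."""
    data: dict[str, list] = {}
    for name, records in groups.items():
        pooled = cu.CodonUsageTable.from_codons(
            c for rec in _validated(records) for c in codons_of(rec)
        )
        values = cu.rscu(pooled)
        data[name] = [values[c] for c in SENSE_CODONS]
    df = pd.DataFrame(data, index=list(SENSE_CODONS))
    df.insert(0, "aa", [CODON_TO_AA[c] for c in SENSE_CODONS])
    return df.rename_axis("codon").reset_index()


def spectrum_table(spectrum: ms.MutationSpectrum, label: str = "") -> pd.DataFrame:
    """12-row spectrum: raw, CpG and non-CpG counts plus normalized percent."""
    rows = []
    for sub in SUBSTITUTIONS:
        rows.append(
            {
                "group": label,
                "substitution": f"{sub[0]}>{sub[1]}",
                "raw": spectrum.raw_counts[sub],
                "CpG": spectrum.cpg_counts[sub],
                "nonCpG": spectrum.non_cpg_counts[sub],
                "normalized_pct": spectrum.normalized_pct.get(sub, float("nan")),
            }
        )
    return pd.DataFrame(rows)


def run_composition(consensus_fasta: str | Path, out_dir: str | Path) -> pd.DataFrame:
    records = read_cds_fasta(consensus_fasta)
    per_seq = composition_table(records)
    out_dir = Path(out_dir)
    digest = file_digest(consensus_fasta)
    header = [f"input={consensus_fasta} sha256={digest}"]
    write_tsv(per_seq, out_dir / "composition_per_sequence.tsv", header)
    summary = group_summary(
        per_seq, ["pct_AT", "pct_GC", "pct_A", "GC1", "GC2", "GC3", "polyA"]
    )
    write_tsv(summary, out_dir / "composition_by_group.tsv", header)
    return per_seq


def run_codon(
    consensus_fasta: str | Path,
    host_cds_fasta: str | Path,
    out_dir: str | Path,
    n_random: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    records = read_cds_fasta(consensus_fasta)
    reference = cu.build_reference_table(read_cds_fasta(host_cds_fasta))
    per_seq = codon_bias_table(records, reference, n_random=n_random, seed=seed)
    out_dir = Path(out_dir)
    header = [
        f"input={consensus_fasta} host={host_cds_fasta}",
        f"n_random={n_random} seed={seed}",
    ]
    write_tsv(per_seq, out_dir / "codon_bias_per_sequence.tsv", header)
    write_tsv(
        group_summary(per_seq, ["Nc", "CAI", "eCAI", "RCDI", "eRCDI"]),
        out_dir / "codon_bias_by_group.tsv",
        header,
    )
    groups: dict[str, list[CodingSequence]] = {}
    for rec in records:
        groups.setdefault(f"{rec.clade}.{rec.host}", []).append(rec)
    write_tsv(rscu_matrix(groups), out_dir / "rscu_matrix.tsv", header)
    return per_seq


def run_mutation(
    alignment_fastas: Sequence[str | Path],
    out_dir: str | Path,
    max_divergence: float = 0.05,
    min_copies: int = 8,
) -> tuple[pd.DataFrame, ms.MutationSpectrum]:
    bundles = [read_alignment_fasta(p) for p in alignment_fastas]
    bundles = [b for b in bundles if b.n_copies >= min_copies]
    bundles, n_dropped = ms.filter_families_by_divergence(bundles, max_divergence)
    if not bundles:
        raise ValueError("no family passes the copy-number and divergence filters")
    tables = []
    for bundle in bundles:
        spec = ms.family_spectrum(bundle)
        tables.append(spectrum_table(spec, label=bundle.consensus.id))
    pooled = ms.pooled_spectrum(bundles)
    tables.append(spectrum_table(pooled, label="pooled"))
    df = pd.concat(tables, ignore_index=True)
    header = [
        f"families_used={len(bundles)} families_dropped_by_divergence={n_dropped}",
        f"max_divergence={max_divergence} min_copies={min_copies}",
        f"pooled_gc_to_at_excess={pooled.gc_to_at_excess:.4f} pooled_singletons={pooled.n_singletons}",
    ]
    write_tsv(df, Path(out_dir) / "mutation_spectrum.tsv", header)
    return df, pooled


def run_orf_compare(consensus_fasta: str | Path, out_dir: str | Path) -> pd.DataFrame:
    """Paired ORF1-vs-ORF2 composition; ORFs of one family share a record id."""
    records = _validated(read_cds_fasta(consensus_fasta))
    by_family: dict[str, dict[str, CodingSequence]] = {}
    for rec in records:
        by_family.setdefault(rec.id, {})[rec.orf_label] = rec
    rows = []
    for fam, orfs in by_family.items():
        if "ORF1" in orfs and "ORF2" in orfs:
            p1 = comp.base_composition(orfs["ORF1"])
            p2 = comp.base_composition(orfs["ORF2"])
            rows.append(
                {
                    "family": fam,
                    "clade": orfs["ORF2"].clade,
                    "host": orfs["ORF2"].host,
                    "pct_AT_ORF1": p1.pct_AT,
                    "pct_AT_ORF2": p2.pct_AT,
                    "diff_AT": p2.pct_AT - p1.pct_AT,
                }
            )
    df = pd.DataFrame(rows)
    header = [f"input={consensus_fasta}"]
    if len(df) >= 2 and df["diff_AT"].std() > 0:
        test = sc.compare_groups(
            {"ORF1": df["pct_AT_ORF1"].tolist(), "ORF2": df["pct_AT_ORF2"].tolist()},
            test="t_test",
            grouping="ORF1 vs ORF2 %AT",
        )
        header.append(
            f"t={test.statistic:.4f} dof={test.dof:.0f} p={test.p_value:.3g}"
        )
    write_tsv(df, Path(out_dir) / "orf1_vs_orf2.tsv", header)
    return df
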