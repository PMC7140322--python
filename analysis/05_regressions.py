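#!/usr/bin/env python
"""Composition-driven regressions across the synthetic consensi:
polyA-signal count vs %AT and RCDI vs GC3.

Reads the per-sequence tables written by 02/03 and reports slopes, r²
and p-values; both relationships are predicted by the base-composition
model (more AT -> more chance polyA hexamers; less GC3 -> stronger codon
deoptimization against a GC-preferring host).
"""

from pathlib import Path

import pandas as pd

from retrocomp.stats_compare import regress

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    comp = pd.read_csv(ROOT / "composition_per_sequence.tsv", sep="\t", comment="#")
    codon = pd.read_csv(ROOT / "codon_bias_per_sequence.tsv", sep="\t", comment="#")
    merged = comp.merge(codon[["id", "RCDI"]], on="id")

    r1 = regress(merged["pct_AT"], merged["polyA"])
    print(f"polyA ~ %AT: slope {r1.slope:+.3f}, r2 = {r1.r2:.2f}, p = {r1.p_value:.2e}")
    r2 = regress(merged["GC3"], merged["RCDI"])
    print(f"RCDI ~ GC3: slope {r2.slope:+.4f}, r2 = {r2.r2:.2f}, p = {r2.p_value:.2e}")

    out = ROOT / "regressions.tsv"
    pd.DataFrame(
        [
            {"model": "polyA~pctAT", "slope": r1.slope, "r2": r1.r2, "p": r1.p_value, "n": r1.n},
            {"model": "RCDI~GC3", "slope": r2.slope, "r2": r2.r2, "p": r2.p_value, "n": r2.n},
        ]
    ).to_csv(out, sep="\t", index=False, float_format="%.6g")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
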