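#!/usr/bin/env python
"""Generate the synthetic study dataset: element consensi for four clades
with contrasting base compositions, a GC-preferring host CDS set, and
young families of diverged genomic copies with known ground truth.

Writes FASTA inputs plus the injection log under results/data/.
"""

import json
from pathlib import Path

from retrocomp.seq_io import write_alignment_fasta, write_cds_fasta
from retrocomp.synthetic_data import (
    FamilySimConfig,
    simulate_family_set,
    simulate_host_cds,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 2024

# clade -> (target base freqs, n families); compositions span the AT-rich,
# A-biased L1 regime down to a GC-rich L2-like regime
CLADES = {
    "L1": ({"A": 0.43, "C": 0.17, "G": 0.16, "T": 0.24}, 6),
    "CR1": ({"A": 0.31, "C": 0.23, "G": 0.23, "T": 0.23}, 4),
    "Penelope": ({"A": 0.36, "C": 0.19, "G": 0.19, "T": 0.26}, 4),
    "L2": ({"A": 0.21, "C": 0.28, "G": 0.27, "T": 0.24}, 6),
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    host = simulate_host_cds(n_genes=60, mean_length=350, seed=SEED)
    write_cds_fasta(host, OUT / "host_cds.fasta")
    print(f"host CDS set: {len(host)} genes -> {OUT / 'host_cds.fasta'}")

    consensi, logs = [], {}
    cfg = FamilySimConfig(n_copies=10)
    for k, (clade, (freqs, n_fam)) in enumerate(CLADES.items()):
        fams = simulate_family_set(
            n_families=n_fam,
            length_codons=800,
            config=cfg,
            target_base_freqs=freqs,
            seed=SEED + 1 + k,
            clade=clade,
            host="lizard",
        )
        for bundle, log in fams:
            write_alignment_fasta(bundle, OUT / f"{bundle.consensus.id}_alignment.fasta")
            consensi.append(bundle.consensus)
            logs[bundle.consensus.id] = log
        print(f"{clade}: {n_fam} families x {cfg.n_copies} copies, target AT "
              f"{100 * (freqs['A'] + freqs['T']):.0f}%")
    write_cds_fasta(consensi, OUT / "consensi.fasta")
    (OUT / "injection_log.json").write_text(json.dumps(logs))
    print(f"{len(consensi)} consensi -> {OUT / 'consensi.fasta'}")


if __name__ == "__main__":
    main()
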