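#!/usr/bin/env python
"""Simulate the sequence database: three Cyc2 cluster families plus decoys.

Writes FASTA files and a truth table under results/. The families carry the
Cyc2 architecture (signal peptide, AXPXFAR[Q/K][T/Y] motif, 5-residue
spacer, CXXCH, 4-residue spacer, PXL, weakly conserved porin tail); the
decoy classes each ablate one screening rule.
"""

import json
from pathlib import Path

from cycscreen import synthetic
from cycscreen.screen import write_fasta

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 11
CLUSTERS = ["1", "2", "3"]


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    manifest = {}
    all_records = []
    for c in CLUSTERS:
        records, truth = synthetic.gen_cluster_family(
            synthetic.FamilyConfig(cluster_label=c, n_members=20, seed=SEED)
        )
        write_fasta(records, RESULTS / f"family_cluster{c}.fasta")
        manifest[f"cluster_{c}"] = {"n": len(records), "cxxch_start": truth["cxxch_start"]}
        all_records += records
    for kind in ("no_heme_porin", "short_fragment", "plain_cytochrome"):
        decoys = synthetic.gen_decoys(kind, 20, seed=SEED)
        write_fasta(decoys, RESULTS / f"decoys_{kind}.fasta")
        manifest[kind] = {"n": len(decoys)}
        all_records += decoys
    write_fasta(all_records, RESULTS / "all_sequences.fasta")
    (RESULTS / "simulation_manifest.json").write_text(json.dumps(manifest, indent=2))
    print(f"wrote {len(all_records)} sequences "
          f"({len(CLUSTERS)} families x 20 members + 3 decoy classes x 20) -> {RESULTS}")


if __name__ == "__main__":
    main()
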