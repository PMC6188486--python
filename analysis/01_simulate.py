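"""Generate the synthetic two-group RNA-seq study used by the whole analysis.

Default scenario: 200 mRNAs, 50 circRNAs, 30 miRNAs, 3 case vs 3 control
samples; 20 planted competing circRNA-mRNA pairs each sharing 5 miRNAs
(one circRNA carries several pairs and is the planted hub) over a sparse
Bernoulli(0.01) interaction background.  Writes counts, interactions, gene
sets and the ground truth under results/analysis/inputs/.
"""

import sys
from pathlib import Path

from cernet import synth

OUT = Path("results/analysis/inputs")


def main(seed: int = 1) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = synth.SynthConfig(seed=seed)
    matrices, truth = synth.generate_counts(cfg)
    for cls, mat in matrices.items():
        mat.write_tsv(OUT / f"counts_{cls}.tsv")
    (OUT / "samples.tsv").write_text(
        "sample_id\tgroup\n"
        + "".join(f"{s}\t{g}\n" for s, g in matrices["mRNA"].groups.items())
    )
    inter = synth.generate_interactions(cfg, truth)
    inter.to_tsv(OUT / "interactions.tsv")
    synth.generate_gene_sets(cfg, truth).to_gmt(OUT / "gene_sets.gmt")
    truth.to_json(OUT / "ground_truth.json")
    print(f"seed {seed}: wrote counts for "
          f"{cfg.n_mrna} mRNAs / {cfg.n_mirna} miRNAs / {cfg.n_circ} circRNAs, "
          f"{len(inter)} interaction records, "
          f"{len(truth.planted_pairs)} planted pairs (hub {truth.hub_circ})")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
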