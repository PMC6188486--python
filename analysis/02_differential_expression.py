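"""Call differentially expressed features in each RNA class.

Features with counts below 2 in every sample are removed; fold changes are
computed on CPM with a pseudo-count of 1; features pass at |log2FC| > 1 and
p <= 0.05.  Writes the annotated table to results/analysis/de_table.tsv.
"""

from pathlib import Path

import pandas as pd

from cernet import expression

IN = Path("results/analysis/inputs")
OUT = Path("results/analysis")


def main() -> None:
    frames = []
    for cls in ("mRNA", "miRNA", "circRNA"):
        mat = expression.read_counts(IN / f"counts_{cls}.tsv", IN / "samples.tsv", cls)
        mat = expression.filter_low_counts(mat, min_count=2)
        frames.append(expression.test_de(mat))
    records = pd.concat(frames, ignore_index=True)
    up, down, annotated = expression.filter_de(records, expression.DEThresholds())
    annotated.to_csv(OUT / "de_table.tsv", sep="\t", index=False)
    for cls in ("mRNA", "miRNA", "circRNA"):
        sub = annotated[annotated["feature_class"] == cls]
        print(
            f"{cls}: {int((sub['status'] == 'UP').sum())} up, "
            f"{int((sub['status'] == 'DOWN').sum())} down of {len(sub)}"
        )


if __name__ == "__main__":
    main()
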