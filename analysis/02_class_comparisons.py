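"""Rank-sum comparison of D_KL between the four sequence classes.

Reads the cohort table produced by 01_cohort_entropy.py, tests every class
pair with the two-sided Mann-Whitney test, and reports whether the median
ordering chromosome > island > phage > plasmid holds.
"""

from pathlib import Path

import pandas as pd

from entroseq.stats import compare_classes

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = pd.read_csv(RESULTS / "cohort_entropy.tsv", sep="\t").merge(
        pd.read_csv(RESULTS / "cohort_metadata.tsv", sep="\t"), on="id")
    out = compare_classes(table)
    out.to_csv(RESULTS / "class_comparisons.tsv", sep="\t", index=False,
               float_format="%.6g")
    print(out.to_string(index=False))

    medians = table.groupby("class")["dkl"].median()
    ordered = (medians["chromosome"] > medians["island"]
               > medians["phage"] > medians["plasmid"])
    print(f"\nmedian ordering chromosome > island > phage > plasmid: "
          f"{'holds' if ordered else 'VIOLATED'}")
    print(f"largest pairwise p-value: {out['p_value'].max():.3g}")
    print("wrote", RESULTS / "class_comparisons.tsv")


if __name__ == "__main__":
    main()
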