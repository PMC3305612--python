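"""Paired comparison of conserved gene sets under mutational decay.

Emulates the contrast between a facultative pathogen and an obligate
intracellular relative: both gene sets descend from the same biased
ancestors, but one has accumulated heavy AT-biased substitution (decay).
The decayed set should show systematically lower per-gene D_KL (paired
signed-rank test) and higher AT content; an exchangeable control (both
sets lightly and identically mutated) should show no consistent shift.

Writes results/conserved_gene_decay.tsv.
"""

from pathlib import Path

import pandas as pd

from entroseq.workflows import ortholog_decay_summary

SEED = 7
RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    decay = ortholog_decay_summary(seed=SEED, n_genes=100, gene_length=1000,
                                   decay_rate=0.15, at_bias=0.7)
    control = ortholog_decay_summary(seed=SEED, decay_rate=0.01, at_bias=0.0)

    table = pd.DataFrame([
        {"condition": "decayed_vs_reference", **decay},
        {"condition": "exchangeable_control", **control},
    ])
    table.to_csv(RESULTS / "conserved_gene_decay.tsv", sep="\t", index=False,
                 float_format="%.6g")

    print("decayed set (rate 0.15, AT-biased) vs reference (rate 0.01):")
    print(f"  median per-gene D_KL: {decay['median_dkl_b']:.3f} vs "
          f"{decay['median_dkl_a']:.3f}  (paired p = {decay['p_value']:.3g})")
    print(f"  mean AT content:      {decay['mean_at_b']:.3f} vs "
          f"{decay['mean_at_a']:.3f}")
    print(f"control (identical treatment): paired p = "
          f"{control['p_value']:.3f} -- no consistent difference expected")
    print("wrote", RESULTS / "conserved_gene_decay.tsv")


if __name__ == "__main__":
    main()
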