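"""Generate the four-class synthetic cohort and compute per-sequence D_KL.

Writes results/cohort_entropy.tsv (one row per sequence: length, AT/GC
content, D_KL, D_OUV) and results/cohort_metadata.tsv, and reports the
median relative entropy per class.
"""

from pathlib import Path

from entroseq import io as eio
from entroseq.signature import analyze_sequence
from entroseq.simulate import make_class_ensemble

SEED = 42
RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    records, meta = make_class_ensemble(seed=SEED)
    results = [analyze_sequence(r) for r in records]
    eio.write_entropy_tsv(results, RESULTS / "cohort_entropy.tsv")
    meta.to_csv(RESULTS / "cohort_metadata.tsv", sep="\t", index=False)

    table = eio.cohort_table(results, meta)
    print(f"analyzed {len(table)} sequences (seed {SEED})")
    print("\nmedian D_KL (nats) per class:")
    print(table.groupby("class")["dkl"].median().round(4).to_string())
    print("\nwrote", RESULTS / "cohort_entropy.tsv")


if __name__ == "__main__":
    main()
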