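"""Generate the synthetic three-tissue NanoString study.

Draws one 800-probe count matrix with 32 thyroid, 12 glioma and 12 bone
marrow samples, five planted stable miRNAs and overdispersed counts, and
writes the count/annotation tables plus the planted ground truth under
results/data/.
"""

import json
from pathlib import Path

from mirstab import make_fixture
from mirstab.io import write_count_table

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 20220217


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    matrix, truth = make_fixture("paper_like", seed=SEED)
    write_count_table(
        matrix, OUT / "counts.tsv", OUT / "probes.tsv", OUT / "samples.tsv"
    )
    (OUT / "truth.json").write_text(
        json.dumps(
            {
                "stable_set": sorted(truth.stable_set),
                "variable_set": sorted(truth.variable_set),
                "seed": SEED,
            },
            indent=2,
        )
        + "\n"
    )
    groups = matrix.samples["group"].value_counts().to_dict()
    print(f"simulated {len(matrix.probe_ids)} probes x {len(matrix.sample_ids)} samples")
    print(f"groups: {groups}")
    print(f"planted stable miRNAs: {sorted(truth.stable_set)}")
    print(f"wrote counts, annotations and truth to {OUT}")


if __name__ == "__main__":
    main()
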