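"""Compare the top-5 composite normalizer against the next-5, pooled group.

The five most stable miRNAs by combined rank sum form a composite
normalizer (mean of logs = log of the geometric mean); the five next most
stable form a second composite. The paired Grambsch (variances) and
Bonett-Seier (mean absolute deviations from the median) tests ask whether
the first composite is genuinely tighter, under housekeeping and under
total-miRNA normalization. Results go to results/composite_tests.json.
"""

import dataclasses
import json
from pathlib import Path

from mirstab import compare_top5_next5
from mirstab.io import read_count_table

ROOT = Path(__file__).resolve().parent.parent / "results"
DATA = ROOT / "data"


def main() -> None:
    matrix = read_count_table(DATA / "counts.tsv", DATA / "probes.tsv", DATA / "samples.tsv")
    payload = {}
    for strategy in ("housekeeping", "total_mirna"):
        gram, bs = compare_top5_next5(matrix, "pooled", strategy)
        payload[strategy] = [dataclasses.asdict(gram), dataclasses.asdict(bs)]
        print(f"\nnormalization to {strategy} (n = {gram.n_pairs} samples):")
        for r in (gram, bs):
            verdict = "dispersions differ" if r.p_value < 0.05 else "no significant difference"
            print(f"  {r.method}: statistic = {r.statistic:.3f}, p = {r.p_value:.2g} -> {verdict}")
    (ROOT / "composite_tests.json").write_text(json.dumps(payload, indent=2) + "\n")
    print(f"\nwrote {ROOT / 'composite_tests.json'}")


if __name__ == "__main__":
    main()
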