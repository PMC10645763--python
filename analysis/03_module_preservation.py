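"""Test detected modules for preservation in an independent replicate cohort.

Zsummary > 10 is strong evidence of preservation, 2-10 weak-to-moderate,
< 2 none (100 label permutations).
"""

import sys
from pathlib import Path

import pandas as pd

from fetomod.io_formats import AnalysisConfig
from fetomod.pipeline import run_pipeline
from fetomod.benchmarks import demo_params

OUT = Path(__file__).resolve().parents[1] / "results" / "pipeline"


def main(seed: int = 1) -> None:
    run_pipeline(AnalysisConfig(seed=seed), demo_params(seed), OUT,
                 stages=("simulate", "network", "preserve"))
    table = pd.read_csv(OUT / "preservation.tsv", sep="\t")
    print(table.to_string(index=False))
    strong = (table["class"] == "strong").sum()
    print(f"{strong}/{len(table)} modules strongly preserved in the replicate")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
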