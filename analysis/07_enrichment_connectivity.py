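"""Overlap enrichment of gene lists in the target module and ARACNE
mutual-information connectivity of the module's genes."""

import sys
from pathlib import Path

import pandas as pd

from fetomod.io_formats import AnalysisConfig
from fetomod.pipeline import run_pipeline
from fetomod.benchmarks import demo_params

OUT = Path(__file__).resolve().parents[1] / "results" / "pipeline"


def main(seed: int = 1) -> None:
    run_pipeline(AnalysisConfig(seed=seed), demo_params(seed), OUT,
                 stages=("simulate", "network", "enrich", "connectivity"))
    enrich = pd.read_csv(OUT / "enrichment.tsv", sep="\t")
    print("overlap enrichment in the target module:")
    print(enrich.to_string(index=False))
    degree = pd.read_csv(OUT / "connectivity.tsv", sep="\t")
    print(f"\nARACNE network over {len(degree)} module genes; "
          f"median degree {degree['degree'].median():.0f}, "
          f"max {degree['degree'].max()}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
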