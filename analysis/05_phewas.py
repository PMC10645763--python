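"""Phenome scan of the module PGS against a battery of outcomes.

The synthetic battery is 20 null outcomes plus one outcome causally
downstream of the PGS; BH FDR should flag only the planted one.
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
                 stages=("simulate", "network", "pgs", "phewas"))
    table = pd.read_csv(OUT / "phewas.tsv", sep="\t")
    sig = table[table["q"] < 0.05]
    print(f"fitted {len(table)} outcomes; {len(sig)} pass FDR < 0.05:")
    cols = ["outcome", "family", "beta", "p", "q", "signed_mlog10p"]
    print(sig[cols].to_string(index=False) if len(sig) else "  (none)")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
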