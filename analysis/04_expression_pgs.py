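"""Build the eQTL-weighted module PGS and validate it against ssGSEA scores.

Mirrors the target-vs-negative-control design: the target-module PGS
should predict the target module's ssGSEA score while size-matched-module,
random-gene, and alternative-tissue control scores stay null.  The
specificity benchmark (Monte-Carlo power and type-I rates) lives in
scripts/acceptance.py; this driver shows one cohort end to end.
"""

import json
import sys
from pathlib import Path

from fetomod.io_formats import AnalysisConfig
from fetomod.pipeline import run_pipeline
from fetomod.benchmarks import demo_params

OUT = Path(__file__).resolve().parents[1] / "results" / "pipeline"


def main(seed: int = 1) -> None:
    run_pipeline(AnalysisConfig(seed=seed), demo_params(seed), OUT,
                 stages=("simulate", "network", "pgs", "score"))
    sidecar = json.loads((OUT / "ssgsea_scores.tsv.json").read_text())
    v = sidecar["validation"]
    print(f"target-module PGS -> target ssGSEA regression: "
          f"beta={v['beta']:.4g}, se={v['se']:.3g}, p={v['p']:.3g}, n={v['n']}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
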