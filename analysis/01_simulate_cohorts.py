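"""Simulate the study system: two genotyped cohorts with planted modules.

Writes the exposure cohort's expression and dosages, the planted-module
GMT, and the outcome cohort's phenotype under results/pipeline/.  The
demonstration system (see fetomod.benchmarks.demo_params): 1000 genes,
three modules of 30/80/60 genes with strong placental-grade cis-eQTLs, 2000 SNPs
in 200 LD blocks, two cohorts of 2000, causal effect -0.15 of the
30-gene target module's genetic activity on the outcome.
"""

import sys
from pathlib import Path

from fetomod.io_formats import AnalysisConfig
from fetomod.pipeline import run_pipeline
from fetomod.benchmarks import demo_params

OUT = Path(__file__).resolve().parents[1] / "results" / "pipeline"


def main(seed: int = 1) -> None:
    manifest = run_pipeline(AnalysisConfig(seed=seed),
                            demo_params(seed), OUT,
                            stages=("simulate",))
    stage = manifest["stages"]["simulate"]
    print(f"simulated cohorts (seed {seed}) -> {OUT}")
    print(f"  wall time {stage['wall_seconds']} s; artifacts: "
          f"{', '.join(stage['outputs'])}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
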