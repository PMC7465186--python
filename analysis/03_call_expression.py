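#!/usr/bin/env python
"""Call whole-blood expression status from the qPCR Cq table.

Imputes no-amplification reactions to Cq 46, normalizes to GUSB, derives
per-gene thresholds from the healthy controls' minimum ΔCq, and calls
patients strictly below threshold positive.  Outputs under results/demo/qpcr/.
"""

from pathlib import Path

from liquidmix.pipeline import RunConfig, stage_qpcr

RUN_DIR = Path("results/demo")


def main() -> None:
    res = stage_qpcr(RunConfig(outdir=RUN_DIR), RUN_DIR / "inputs" / "cq.csv", RUN_DIR / "qpcr")
    print("positivity thresholds (lowest control ΔCq per gene):")
    for gene, thr in res["thresholds"].items():
        print(f"  {gene}: {thr:.2f} cycles")
    calls = res["calls"]
    for gene, sub in calls.groupby("gene"):
        print(f"{gene}: {int(sub['positive'].sum())}/{len(sub)} patients positive")
    if res["unevaluable"]:
        print(f"unevaluable samples (reference failed): {res['unevaluable']}")


if __name__ == "__main__":
    main()
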