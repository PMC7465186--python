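#!/usr/bin/env python
"""Combine the three assays into the per-patient multi-analyte summary.

Assembles the tri-state patients × assays ledger from the stage outputs and
reports informativeness, resistance-marker detection and exclusivity,
in situ vs qPCR concordance, and per-assay positivity.  Outputs under
results/demo/integration/.
"""

import json
from pathlib import Path

from liquidmix.integrate import integration_report
from liquidmix.pipeline import ledger_from_output_files

RUN_DIR = Path("results/demo")


def main() -> None:
    ledger = ledger_from_output_files(RUN_DIR)
    outdir = RUN_DIR / "integration"
    outdir.mkdir(parents=True, exist_ok=True)
    ledger.to_csv(outdir / "ledger.tsv", sep="\t")
    report = integration_report(ledger)
    (outdir / "integration_report.json").write_text(json.dumps(report, indent=2, default=str))

    inf = report["informative"]
    print(f"informative patients: {inf['n_informative']}/{inf['n_patients']} ({inf['percent']}%)")
    res = report["resistance"]
    print(
        f"resistance markers (AR-V7 or AR amplification): "
        f"{res['n_resistant']}/{res['n_patients']} ({res['resistant_pct']}%)"
    )
    if res["exclusive_pct"] is not None:
        print(
            f"  detected by exactly one assay in {res['n_exclusive']}/{res['n_resistant']} "
            f"resistant patients ({res['exclusive_pct']}%)"
        )
    for marker, conc in report["concordance"].items():
        if conc:
            print(f"in situ vs qPCR concordance, {marker}: "
                  f"{conc['n_agree']}/{conc['n_co_assayed']} ({conc['percent']}%)")


if __name__ == "__main__":
    main()
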