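"""Group statistics: band x stream LMM ANOVAs (Satterthwaite dfs), Tukey
post-hocs, and paired ventral-vs-lateral tests on size and density slope.
"""

import json
from pathlib import Path

from prfconn.pipeline import run_pipeline

OUTDIR = Path(__file__).resolve().parents[1] / "results" / "run"

if __name__ == "__main__":
    run_pipeline({"seed": 0}, OUTDIR, stages=["stats"])
    report = json.loads((OUTDIR / "stats_report.json").read_text())
    for table in ("center_band_proportions", "endpoint_band_proportions"):
        inter = next(r for r in report[table]["anova"]
                     if r["effect"] == "band:stream")
        print(f"{table}: band x stream interaction "
              f"F({inter['df1']:.0f}, {inter['df2']:.1f}) = {inter['F']:.1f}, "
              f"p = {inter['p']:.2e}, partial eta^2 = {inter['partial_eta_sq']:.2f}")
    for key in ("paired_median_size", "paired_slope"):
        if key in report:
            r = report[key]
            print(f"{key}: t({r['df']}) = {r['t']:.2f}, p = {r['p']:.4f}, "
                  f"d = {r['cohens_d']:.2f}")
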