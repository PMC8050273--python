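"""Visual-field-coverage analytics on the fitted pRFs.

Applies the inclusion criteria (VE > 20 %, sigma off the 0.21 deg floor,
>= 10 voxels), then computes per subject/stream: eccentricity-band
proportions of pRF centers, coverage maps, density-vs-eccentricity curves
with linear and logistic fits, laterality indices, and median pRF sizes.
"""

from pathlib import Path

import pandas as pd

from prfconn.pipeline import run_pipeline

OUTDIR = Path(__file__).resolve().parents[1] / "results" / "run"

if __name__ == "__main__":
    run_pipeline({"seed": 0}, OUTDIR, stages=["coverage"])
    summary = pd.read_csv(OUTDIR / "coverage_summary.tsv", sep="\t")
    by_stream = summary.groupby("stream")[["slope", "median_size"]].mean()
    print("mean density slope and median pRF size by stream:")
    print(by_stream.round(3).to_string())
    bands = pd.read_csv(OUTDIR / "center_band_proportions.tsv", sep="\t")
    foveal = bands[bands["band"] == "0-5"].groupby("stream")["value"].mean()
    print("\nmean proportion of pRF centers in the 0-5 deg band:")
    print(foveal.round(3).to_string())
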