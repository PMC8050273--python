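"""Simulate the study's raw data: bar aperture, ground-truth voxel
populations for a ventral-like and a lateral-like region per subject, and
noisy BOLD responses.

Writes aperture.nii.gz, truth_*.tsv and bold_*.tsv under results/run/.
"""

from pathlib import Path

from prfconn.pipeline import run_pipeline

OUTDIR = Path(__file__).resolve().parents[1] / "results" / "run"

if __name__ == "__main__":
    report = run_pipeline({"seed": 0}, OUTDIR, stages=["simulate"])
    truths = [n for n in report["outputs"] if n.startswith("truth_")]
    print(f"simulated {len(truths)} subject/stream populations -> {OUTDIR}")
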