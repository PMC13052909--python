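"""Generate a seeded synthetic multimodal stroke dataset and inspect it.

Builds paired tabular records and grayscale images with a fixed class
mix, writes them to disk, and reads them back.
"""

import tempfile
from pathlib import Path

import fedstroke as fs

ds = fs.generate_multimodal(
    n=200, stroke_fraction=0.38, missing_rate=0.05, height=32, width=32, seed=42
)
labels = ds.labels
n_missing = sum(
    rec["bmi"] is None or rec["avg_glucose_level"] is None for rec, _ in ds.pairs
)
print(f"pairs generated:      {len(ds)}")
print(f"stroke-positive:      {labels.sum()} ({100 * labels.mean():.1f}%)")
print(f"records w/ a missing clinical value: {n_missing}")

with tempfile.TemporaryDirectory() as tmp:
    out = Path(tmp) / "dataset"
    fs.write_dataset(out, ds, packed=False)
    back = fs.read_dataset(out)
    print(f"round trip through {out.name}/ (CSV + PNGs): {len(back)} pairs back")

# The stroke fraction mirrors the 950/2501 class mix of a public
# brain-CT collection; missing values land only in bmi / glucose, the
# two fields that are incomplete in real stroke EHR data.
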