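"""Generate a small labelled synthetic HEp-2 dataset and inspect it.

Each positive well carries three images sharing one staining pattern and
one non-negative intensity; negative wells carry one dim-cell image.
Ground truth (cell masks, pattern, mitosis annotations) is written as a
JSON sidecar next to each image.
"""

from pathlib import Path

import hep2cad as h

out = Path("example_output/dataset")
manifest = h.generate_dataset(
    {"centromere": 3, "nucleolar": 3, "homogeneous": 3},
    negative_fraction=0.10,
    seed=42,
    out_dir=out,
)

n_wells = manifest["well_id"].nunique()
n_negative = (manifest["intensity_label"] == "negative").sum()
print(f"wells: {n_wells}, images: {len(manifest)}, negative images: {n_negative}")
print(manifest.head(6).to_string(index=False))

truth = h.simulate.load_sidecar(out / (manifest["image_path"].iloc[0] + ".truth.json"))
print(f"first image holds {len(truth)} cells, "
      f"{sum(c.mitosis is not None for c in truth)} mitotic")
# Expect 10 wells (9 positive + 1 negative), 28 images: positive wells
# contribute 3 images each and every positive image contains a mitotic
# figure so the well quality-control rule can fire downstream.
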