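"""Process and label a multi-voxel grid, then export it as exchange XML.

Generates a 4x4 grid of brain-like voxels with a small "lesion" patch,
applies a uniform normalisation pipeline, labels the lesion voxels 't',
exports to XML and reads the file back as a flat 2-D array.
"""

import numpy as np

from mrsxml import (
    AcquisitionParams,
    blank_template,
    export_dataset,
    gen_mv_grid,
    read_dataset,
    run_pipeline,
    set_voxel_label,
    validate,
)

params = AcquisitionParams(63.86, 1300.0, 512, 4.7)
lesion = np.zeros((4, 4), dtype=bool)
lesion[1:3, 1:3] = True  # a 2x2 abnormal patch

grid, truth = gen_mv_grid(4, 4, params, lesion_mask=lesion, seed=3)

config = blank_template().with_identity("Example User", "Example Lab")
config.normalization.enabled = True
dataset = run_pipeline(grid, config)

for r in range(4):
    for c in range(4):
        if lesion[r, c]:
            set_voxel_label(dataset.payload, r + 1, c + 1, "t")

export_dataset(dataset, "scratch_grid.xml")
print("violations:", validate("scratch_grid.xml"))

back = read_dataset("scratch_grid.xml")
flat = back.payload.flat()
print(f"grid: {back.payload.rows}x{back.payload.cols}, flat view {flat.shape}")
labels = [[back.payload.voxel(r + 1, c + 1).label for c in range(4)] for r in range(4)]
for row in labels:
    print(" ".join(f"{l:>3}" for l in row))

# Voxels keep their 1-based grid positions (top-left = [1,1], Zaxis always 1)
# and their labels through the XML round trip; unlabelled voxels stay "***".
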