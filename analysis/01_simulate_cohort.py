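#!/usr/bin/env python
"""Generate the 15-subject synthetic placebo/drug cohort and write it to disk.

Each subject contributes four datasets — {placebo, drug} x {voxel-level,
ROI-level} — written as delimited three-file bundles under results/cohort/.
The drug-like arm plants temporally variable voxel-network coupling in the
four association networks post-infusion and faster/wider regime switching in
the 4-ROI system; the placebo-like arm is stationary throughout. Downstream
scripts regenerate the same cohort in memory from the root seed, so this
step is only needed if you want to inspect the raw data.
"""

from pathlib import Path

from neuroentropy.config import GeneratorConfig
from neuroentropy.io import write_matrix_dataset, write_region_dataset
from neuroentropy.synthetic import generate_condition_pair

ROOT_SEED = 1
N_SUBJECTS = 15
OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"


def main():
    cfg = GeneratorConfig(seed=ROOT_SEED)
    pairs = generate_condition_pair(cfg, N_SUBJECTS)
    OUT.mkdir(parents=True, exist_ok=True)
    n_files = 0
    for pair in pairs:
        for cond, arm in (("placebo", pair.placebo), ("drug", pair.drug)):
            stem = OUT / f"sub-{pair.subject_id}_{cond}"
            n_files += len(write_matrix_dataset(arm.voxel, stem))
            n_files += len(write_region_dataset(arm.roi.series, f"{stem}_roi"))
    print(f"wrote {n_files} files for {N_SUBJECTS} subjects to {OUT}")
    print(f"geometry: {cfg.n_networks} networks x {cfg.voxels_per_network} voxels, "
          f"{cfg.n_timepoints} timepoints at {cfg.sampling_interval}s, "
          f"infusion [{cfg.infusion_onset}, {cfg.infusion_onset + cfg.infusion_duration})")


if __name__ == "__main__":
    main()
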