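"""Generate the synthetic study cohort and write every raw artifact.

Emulates the study design: 26 stroke participants (19 right- / 7
left-hemisphere lesions, per-tract lesion counts SLF I=3, SLF II=6,
SLF III=8, AF=20, MdLF=9, six participants with no lesion on any tract of
interest) and 7 healthy controls.  Writes exam trial tables, demographics,
diffusion metrics, connectome edge lists, and all masks as NIfTI under
results/study/.
"""

import sys
from pathlib import Path

import numpy as np

from propriomap.synthetic import (
    connectomes_to_csv, demographics_to_frame, exams_to_csv, simulate_study,
)
from propriomap.tracts import MaskVolume

SEED = 0
OUT = Path("results/study")


def main() -> int:
    out = OUT
    masks_dir = out / "masks"
    masks_dir.mkdir(parents=True, exist_ok=True)

    study = simulate_study(rng=np.random.default_rng(SEED))
    exams_to_csv(study.exams, out / "exams.csv")
    demographics_to_frame(study.demographics).to_csv(out / "demographics.csv")
    study.tract_metrics.to_csv(out / "tract_metrics.csv", index=False)
    connectomes_to_csv(study.connectomes, out / "connectomes.csv")
    study.ground_truth.damage_fraction.to_csv(out / "planted_damage.csv")

    vox = study.config.grid.voxel_size_mm
    for (tract, hemi), masks in study.control_tract_masks.items():
        for i, m in enumerate(masks):
            MaskVolume(m, vox).to_nifti(masks_dir / f"tract_{tract}_{hemi}_c{i}.nii.gz")
    for pid, m in study.lesion_masks.items():
        MaskVolume(m, vox).to_nifti(masks_dir / f"lesion_{pid}.nii.gz")

    n_exams = len(study.exams)
    planted = (study.ground_truth.damage_fraction > 0).sum()
    print(f"wrote {n_exams} exams ({len(study.stroke_ids)} stroke, "
          f"{len(study.control_ids)} control) under {out}")
    print("planted lesion counts per tract:")
    for tract, n in planted.items():
        print(f"  {tract}: {n}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
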