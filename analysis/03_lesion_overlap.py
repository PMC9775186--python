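"""Build control tract templates and quantify lesion-tract overlap.

Templates keep voxels present in at least 6 of the 7 control tract masks.
Each stroke participant's lesion is intersected with the templates of the
lesioned hemisphere, yielding percent damage and lesioned / non-lesioned
groups per tract.  Writes results/study/lesion_overlap.csv.
"""

import sys
from pathlib import Path

from propriomap.synthetic import TRACTS, demographics_from_csv
from propriomap.tracts import (
    MaskVolume, assign_lesion_groups, build_template, lesion_overlap,
    overlaps_to_frame,
)

AGREEMENT_K = 6
N_CONTROLS = 7
OUT = Path("results/study")


def main() -> int:
    masks_dir = OUT / "masks"
    demos = demographics_from_csv(OUT / "demographics.csv")

    templates = {}
    for tract in TRACTS:
        for hemi in ("L", "R"):
            controls = [
                MaskVolume.from_nifti(masks_dir / f"tract_{tract}_{hemi}_c{i}.nii.gz")
                for i in range(N_CONTROLS)
            ]
            templates[(tract, hemi)] = build_template(
                controls, AGREEMENT_K, tract=tract, hemisphere=hemi
            )

    results = []
    stroke_ids = [p for p, d in demos.items() if d.group == "stroke"]
    for pid in stroke_ids:
        lesion = MaskVolume.from_nifti(masks_dir / f"lesion_{pid}.nii.gz")
        hemi = demos[pid].lesioned_hemisphere
        for tract in TRACTS:
            results.append(lesion_overlap(templates[(tract, hemi)], lesion, pid))

    groups = assign_lesion_groups(overlaps_to_frame(results))
    groups.to_csv(OUT / "lesion_overlap.csv", index=False)

    print(f"templates built at {AGREEMENT_K}-of-{N_CONTROLS} agreement "
          f"({round(100 * AGREEMENT_K / N_CONTROLS)}%)")
    print("lesion group sizes:")
    for tract in TRACTS:
        sub = groups[groups["tract"] == tract]
        n = int(sub["lesioned"].sum())
        dmg = sub.loc[sub["lesioned"], "percent_damage"]
        print(f"  {tract}: {n} lesioned (median damage "
              f"{dmg.median():.1f}% of template)" if n else f"  {tract}: 0 lesioned")
    return 0


if __name__ == "__main__":
    sys.exit(main())
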