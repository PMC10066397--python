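"""Track an OPT region of interest into physical cryosections, and back.

A follicle selected in the 3D reconstruction occupies slices 100-119 of a
500-slice, 10-um-voxel volume. With 25-um sections cut from the proximal
end, the ROI lands in a predictable window of section indices; a
high-density section observed under the confocal is matched back to it.
"""

import numpy as np

from gutopt import (
    RoiRecord, SectionPlan, cell_density, make_section_image, match_sections,
    opt_visible, roi_axial_distance, section_indices,
)

roi_voxels = np.array([[z, 32, 32] for z in range(100, 120)])
roi = roi_axial_distance((500, 64, 64), voxel_size_um=10.0,
                         roi_voxels=roi_voxels, roi_id="ILF-1")
print(f"ROI axial extent: {roi.axial_start_um:.0f}-{roi.axial_end_um:.0f} um "
      "from the proximal end")

plan = SectionPlan(section_thickness_um=25.0, sample_length_um=5000.0)
window = section_indices(roi, plan)
print(f"collect 25-um sections {window[0]}..{window[-1]} "
      f"({len(window)} sections) to find it")

# a confocal image of one of those sections: 400 CD45+ cells per mm^2 of DAPI
_, mask, truth = make_section_image(400, tissue_mask_area_mm2=1.0,
                                    pixel_size_um=1.0, seed=3)
density = cell_density(truth.cell_coords_um, mask, pixel_size_um=1.0)
print(f"section cell density: {density:.0f} cells/mm^2 -> "
      f"OPT-visible: {opt_visible(density)} (threshold 400)")

report = match_sections([roi], [(window[3], density)], plan)
print(f"high-density section {window[3]} assigned to ROI "
      f"{report.assignments[window[3]]!r}; unexplained: {report.unexplained_sections}")
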