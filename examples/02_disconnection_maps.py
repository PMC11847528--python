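"""Build a probabilistic structural disconnection map (pSDM) for one patient.

A patient's lesion is embedded in each normative subject's tractogram:
streamlines passing through the lesion are 'cut', and every voxel they
traverse counts as disconnected for that subject.  The pSDM is the
across-subject frequency; thresholding at Pth keeps voxels disconnected in
at least round(Pth * N) subjects.
"""

from dyspredict import build_psdm, generate_cohort, generate_lesions, lesion_volume, threshold_psdm
from dyspredict.synthetic import default_grid

grid = default_grid(32, 3.0)
_, tractograms, _ = generate_cohort(
    grid, n_parcels=30, n_subjects=10, bundles=12, seed=7
)
lesion = generate_lesions(grid, n_patients=1, size_range=(50, 120), seed=8)[0]

psdm = build_psdm(tractograms, lesion)
print(f"patient {lesion.patient_id}: lesion {lesion.n_voxels} voxels "
      f"({lesion_volume(lesion):.2f} cm^3)")
print(f"pSDM over N={psdm.n_subjects} subjects: "
      f"{int((psdm.counts > 0).sum())} voxels with nonzero disconnection probability")
for pth in (0.1, 0.3, 0.5, 0.7, 0.9):
    t = threshold_psdm(psdm, pth)
    print(f"  tSDM Pth={pth}: >= {t.min_count} subjects -> {t.n_voxels} voxels")
print("Voxel counts shrink monotonically with Pth: higher thresholds keep only")
print("disconnections consistent across the normative cohort.")
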