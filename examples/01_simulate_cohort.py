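"""Generate a small synthetic normative cohort and patient lesion set.

The cohort stands in for a normative imaging sample: a parcellated
ellipsoidal "brain", per-subject streamline bundles between parcel pairs
(with subject-level geometric jitter), parcel time series with covariance
structure following the bundle graph, and connected lesion blobs of varied
size for the patients.
"""

import numpy as np

from dyspredict import generate_cohort, generate_lesions
from dyspredict.synthetic import default_grid, filter_streamlines_by_length

grid = default_grid(32, voxel_mm=3.0)
atlas, tractograms, timeseries = generate_cohort(
    grid, n_parcels=30, n_subjects=8, bundles=12, n_timepoints=120, seed=42
)
lesions = generate_lesions(grid, n_patients=10, size_range=(10, 200), seed=43)

print(f"atlas: {atlas.n_parcels} parcels, "
      f"{int((atlas.labels > 0).sum())} brain voxels of {grid.n_voxels}")
t0 = tractograms[0]
lengths = t0.arc_lengths()
print(f"subject {t0.subject_id}: {len(t0)} streamlines, "
      f"arc length {lengths.min():.0f}-{lengths.max():.0f} mm "
      f"(median {np.median(lengths):.0f} mm)")
kept = filter_streamlines_by_length(t0, 30.0, 300.0)
print(f"after the 30-300 mm length filter: {len(kept)} streamlines kept")
sizes = [m.n_voxels for m in lesions]
print(f"lesions: {len(lesions)} patients, size {min(sizes)}-{max(sizes)} voxels")
print("Each lesion is one connected blob; streamline counts and lengths are")
print("what the disconnection mapping below consumes.")
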