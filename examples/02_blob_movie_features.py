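"""Extract blob features from a synthetic super-resolution-like movie.

Renders 50 Gaussian blobs with heterogeneous sizes drifting over 6
frames under Poisson-Gaussian noise, segments them with the marker-
assisted watershed, and compares detected centroids, NND and optical-
flow magnitudes against the generator's ground truth.
"""

import numpy as np
from scipy.spatial import cKDTree

from stgranger import SyntheticMovieSpec, compute_nnd, generate_blob_movie, segment_blobs
from stgranger.features import build_blob_table

rng = np.random.default_rng(7)
spec = SyntheticMovieSpec(
    n_blobs=50,
    n_frames=6,
    blob_sigma_px=(1.5, 3.0),
    drift_px=rng.uniform(-0.7, 0.7, size=(50, 2)),
    margin_px=14,
    min_separation_px=10,
    seed=7,
)
movie, truth = generate_blob_movie(spec)
print(f"movie: {movie.shape[0]} frames of {movie.shape[1:]}, pixel size {spec.pixel_size_nm} nm")

labels, detected = segment_blobs(movie[0])
gt0 = truth.blob_tables[truth.blob_tables.frame == 0]
d, _ = cKDTree(detected[["row_px", "col_px"]].to_numpy()).query(
    gt0[["row_px", "col_px"]].to_numpy()
)
print(f"frame 0: {len(detected)} blobs detected of {len(gt0)} true; "
      f"recall within 2 px = {(d <= 2).mean():.2f}")

nnd = compute_nnd(detected[["row_px", "col_px"]].to_numpy(), pitch_nm=spec.pixel_size_nm)
print(f"detected NND: mean {nnd.mean():.1f} nm (truth {gt0.nnd_nm.mean():.1f} nm)")

table = build_blob_table(movie, pitch_nm=spec.pixel_size_nm, dt_s=spec.dt_s)
r = np.corrcoef(
    table["flow_px"],
    truth.blob_tables["disp_px"].to_numpy()[
        cKDTree(truth.blob_tables[["row_px", "col_px"]].to_numpy()).query(
            table[["row_px", "col_px"]].to_numpy()
        )[1]
    ],
)[0, 1]
print(f"per-blob optical-flow magnitude vs true displacement: Pearson r = {r:.2f}")
print("Segmentation recovers essentially every blob; NND and flow track the ground truth,")
print("so the rasterized fields downstream carry real structural/dynamic signal.")
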