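"""Summary images and seeding: correlation image, max-correlation image
and greedy initialization on a synthetic movie."""

import numpy as np

from caldemix import InitParams, SynthParams, correlation_image, generate_movie, max_correlation_image
from caldemix.initialization import greedy_roi

movie, truth = generate_movie(
    SynthParams(fov_dims=(32, 32), n_frames=600, n_neurons=5, seed=6)
)

ci = correlation_image(movie, neighborhood=8)
mx = max_correlation_image(movie, batch_seconds=10)
print(f"correlation image: mean {ci.values.mean():.3f}, max {ci.values.max():.3f}")
print(f"max-correlation image: mean {mx.values.mean():.3f}, max {mx.values.max():.3f}")
# Active somata light up as local maxima; the max-CI variant also keeps
# neurons that are active only briefly.

A0, C0 = greedy_roi(movie, InitParams(n_components=5, gaussian_width=3))
print(f"greedy seeds found: {A0.shape[1]}")
for k in range(A0.shape[1]):
    peak = np.unravel_index(A0[:, k].argmax(), movie.fov_dims)
    dist = min(np.hypot(peak[0] - c[0], peak[1] - c[1]) for c in truth.centers)
    print(f"  seed {k} at {tuple(int(v) for v in peak)}, "
          f"{dist:.1f} px from the nearest true center")
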