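"""Component quality metrics and dF/F extraction.

Plugs the ground-truth decomposition of a synthetic movie into the
quality battery (peak-SNR, spatial consistency, shape score), then
converts the traces to dF/F units.
"""

import numpy as np

from caldemix import DffParams, QualityThresholds, SynthParams, generate_movie
from caldemix.model import BackgroundModel, ComponentSet
from caldemix.postproc import extract_dff
from caldemix.quality import evaluate_components, residual_traces

movie, truth = generate_movie(
    SynthParams(fov_dims=(32, 32), n_frames=600, n_neurons=5, seed=4)
)
components = ComponentSet(truth.footprints, truth.traces)
background = BackgroundModel(
    kind="low_rank",
    spatial=truth.background_spatial,
    temporal=truth.background_temporal,
)

report = evaluate_components(movie, components, background, QualityThresholds())
for i in range(components.n_components):
    print(f"component {i}: SNR {report.snr[i]:5.1f}  "
          f"space corr {report.space_correlation[i]:.2f}  "
          f"shape score {report.classifier_score[i]:.2f}  "
          f"accepted={bool(report.accepted[i])}")

res = residual_traces(movie, components, background)
dff = extract_dff(components, background, residuals=res,
                  params=DffParams(), frame_rate=movie.frame_rate)
print(f"peak dF/F per component: {np.round(dff.max(axis=1), 2)}")
# dF/F expresses each transient as a fraction of the component's
# baseline fluorescence (its own resting level plus the neuropil seen
# through its footprint).
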