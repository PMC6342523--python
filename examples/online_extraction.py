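"""Streaming (frame-by-frame) source extraction.

Starts from a bare initialization (background plus two components fit on
the first 200 frames) and discovers the remaining neurons on the fly
from the residual buffer, over two passes through the movie.
"""

from caldemix import OnlineParams, SynthParams, generate_movie
from caldemix.online import run_online
from caldemix.postproc import match_components

movie, truth = generate_movie(SynthParams(seed=1))
components, background, timing = run_online(movie, OnlineParams(seed=1, epochs=2))

print(f"components after streaming: {components.n_components}")
print(f"init {timing['init']:.1f}s, streaming {timing['stream']:.1f}s "
      f"({2 * (movie.n_frames - 200)} frames processed)")

res = match_components(components, truth.footprints, match_threshold=0.7)
print(f"precision {res.precision:.3f}  recall {res.recall:.3f}  F1 {res.f1:.3f}")
# The second epoch replays the movie so components detected late get
# their earlier activity back-filled.
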