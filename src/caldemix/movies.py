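"""Movie I/O and the pixel-major memory-mapped on-disk representation.

A movie is viewed throughout the package as a matrix ``Y`` of shape
``(d, T)``: each row is one pixel's time series, each column one frame.
Pixel index is row-major over the field of view, ``p = row * cols + col``;
all coordinates are 0-based and all ranges half-open.

For patch processing the movie is stored on disk *pixel-major* (the time
series of one pixel occupies one contiguous byte range), so that reading a
spatial patch over all frames touches only the bytes of its pixels.  The
on-disk container is a minimal ``.pmap`` file: a 128-byte header (magic,
dims, dtype code) followed by the raw float32 array of shape ``(d, T)`` in
C order.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import h5py
import numpy as np
import tifffile

__all__ = [
    "Movie",
    "MemmapMovie",
    "write_memmap",
    "read_patch",
    "load_movie",
    "iter_frames",
    "save_movie",
]

_PMAP_MAGIC = b"PMAPMOV1"
_PMAP_HEADER_BYTES = 128
_DTYPE_CODES = {0: np.dtype("<f4")}


@dataclass
class Movie:
    """In-memory movie: pixels x time matrix plus FOV geometry."""

    data: np.ndarray  # (d, T)
    fov_dims: tuple[int, int]
    frame_rate: float = 30.0
    source_path: str | None = None

    def __post_init__(self) -> None:
        rows, cols = self.fov_dims
        if self.data.shape[0] != rows * cols:
            raise ValueError(
                f"data has {self.data.shape[0]} pixels but FOV {self.fov_dims} implies {rows * cols}"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("movie contains non-finite values")

    @property
    def n_pixels(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    def frame(self, t: int) -> np.ndarray:
        return self.data[:, t].reshape(self.fov_dims)

    def frames(self) -> Iterator[np.ndarray]:
        for t in range(self.n_frames):
            yield self.frame(t)


@dataclass
class MemmapMovie:
    """Handle to a pixel-major ``.pmap`` file on disk."""

    path: str
    dims: tuple[int, int, int]  # rows, cols, T
    frame_rate: float = 30.0
    layout: str = field(default="pixel-major")
    dtype: np.dtype = field(default_factory=lambda: np.dtype("<f4"))

    @property
    def fov_dims(self) -> tuple[int, int]:
        return self.dims[0], self.dims[1]

    @property
    def n_pixels(self) -> int:
        return self.dims[0] * self.dims[1]

    @property
    def n_frames(self) -> int:
        return self.dims[2]

    def as_array(self, writable: bool = False) -> np.memmap:
        """Memory-mapped (d, T) view; nothing is read until indexed."""
        mode = "r+" if writable else "r"
        return np.memmap(
            self.path, dtype=self.dtype, mode=mode,
            offset=_PMAP_HEADER_BYTES, shape=(self.n_pixels, self.n_frames),
        )

    def to_movie(self) -> Movie:
        return Movie(
            data=np.array(self.as_array()),
            fov_dims=self.fov_dims,
            frame_rate=self.frame_rate,
            source_path=self.path,
        )


def _pack_header(rows: int, cols: int, T: int) -> bytes:
    header = bytearray(_PMAP_HEADER_BYTES)
    header[:8] = _PMAP_MAGIC
    header[8:40] = np.array([rows, cols, T, 0], dtype="<i8").tobytes()
    return bytes(header)


def _read_header(path: str | Path) -> tuple[int, int, int, np.dtype]:
    with open(path, "rb") as fh:
        header = fh.read(_PMAP_HEADER_BYTES)
    if header[:8] != _PMAP_MAGIC:
        raise ValueError(f"{path} is not a .pmap movie (bad magic)")
    rows, cols, T, code = np.frombuffer(header[8:40], dtype="<i8")
    return int(rows), int(cols), int(T), _DTYPE_CODES[int(code)]


def open_memmap(path: str | Path, frame_rate: float = 30.0) -> MemmapMovie:
    rows, cols, T, dtype = _read_header(path)
    expected = _PMAP_HEADER_BYTES + rows * cols * T * dtype.itemsize
    if os.path.getsize(path) != expected:
        raise ValueError(f"{path}: size {os.path.getsize(path)} != expected {expected}")
    return MemmapMovie(path=str(path), dims=(rows, cols, T), frame_rate=frame_rate, dtype=dtype)


def iter_frames(source: str | Path) -> Iterator[np.ndarray]:
    """Stream frames (rows x cols) from a multi-page TIFF or an HDF5 file
    holding a dataset named "mov" shaped (T, rows, cols).  Never loads the
    whole file."""
    path = Path(source)
    suffix = path.suffix.lower()
    if suffix in {".tif", ".tiff"}:
        with tifffile.TiffFile(str(path)) as tif:
            for page in tif.pages:
                yield np.asarray(page.asarray())
    elif suffix in {".h5", ".hdf5"}:
        with h5py.File(str(path), "r") as fh:
            dset = fh["mov"]
            for t in range(dset.shape[0]):
                yield dset[t]
    elif suffix == ".pmap":
        mm = open_memmap(path)
        arr = mm.as_array()
        for t in range(mm.n_frames):
            yield arr[:, t].reshape(mm.fov_dims)
    else:
        raise ValueError(f"unsupported movie format: {path}")


def write_memmap(
    frame_source: Iterable[np.ndarray] | Sequence[str | Path],
    out_path: str | Path,
    chunk_size: int = 256,
    frame_rate: float = 30.0,
) -> MemmapMovie:
    """Write frames to a pixel-major ``.pmap`` file in chunks.

    ``frame_source`` is either an iterator/sequence of 2-D frames or a list
    of movie file paths (streamed with :func:`iter_frames`).  Frames are
    cast to float32.  The file contents are independent of ``chunk_size``:
    writing in k chunks is bit-identical to a single-pass write.
    """
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")

    def frames() -> Iterator[np.ndarray]:
        first = next(iter(frame_source), None)
        if first is None:
            raise ValueError("empty frame source")
        if isinstance(first, (str, Path)):
            for f in frame_source:  # type: ignore[union-attr]
                yield from iter_frames(f)
        else:
            yield np.asarray(first)
            it = iter(frame_source)
            next(it)  # skip the first, already yielded
            for f in it:
                yield np.asarray(f)

    # Sequences allow the two-pass form above; general iterators need care.
    if not isinstance(frame_source, Sequence):
        frame_source = list(frame_source)

    out_path = Path(out_path)
    gen = frames()
    first = next(gen)
    if first.ndim != 2:
        raise ValueError("frames must be 2-D (rows, cols)")
    fov = first.shape
    d = fov[0] * fov[1]

    # Phase 1: spill fixed-size chunks of frames to per-chunk temporaries.
    chunk_paths: list[Path] = []
    chunk_lengths: list[int] = []

    def flush(chunk: list[np.ndarray]) -> None:
        block = np.stack(chunk).astype("<f4").reshape(len(chunk), d)
        p = out_path.with_suffix(out_path.suffix + f".chunk{len(chunk_paths)}.npy")
        np.save(p, block)
        chunk_paths.append(p)
        chunk_lengths.append(len(chunk))

    chunk: list[np.ndarray] = [first]
    for frame in gen:
        if frame.shape != fov:
            raise ValueError(
                f"frame shape {frame.shape} in chunk {len(chunk_paths)} differs from first frame {fov}"
            )
        chunk.append(frame)
        if len(chunk) == chunk_size:
            flush(chunk)
            chunk = []
    if chunk:
        flush(chunk)
    T = sum(chunk_lengths)

    # Phase 2: concatenate the chunk temporaries, pixel-major, into the
    # final file.  The result is bit-identical regardless of chunking.
    with open(out_path, "wb") as fh:
        fh.write(_pack_header(fov[0], fov[1], T))
        fh.truncate(_PMAP_HEADER_BYTES + d * T * 4)
    mm = np.memmap(out_path, dtype="<f4", mode="r+", offset=_PMAP_HEADER_BYTES, shape=(d, T))
    t0 = 0
    for p, n in zip(chunk_paths, chunk_lengths):
        block = np.load(p)  # (n, d) frame-major
        mm[:, t0 : t0 + n] = block.T
        t0 += n
        p.unlink()
    mm.flush()
    del mm
    return MemmapMovie(path=str(out_path), dims=(fov[0], fov[1], T), frame_rate=frame_rate)


def read_patch(
    movie: MemmapMovie,
    rows: tuple[int, int],
    cols: tuple[int, int],
    frames: tuple[int, int] | None = None,
) -> np.ndarray:
    """Dense ((dr*dc) x dt) sub-tensor of a memory-mapped movie.

    Ranges are half-open; pixels are flattened row-major within the patch.
    Peak extra memory is proportional to the patch, not the file: only the
    byte ranges of the requested pixel rows are touched.
    """
    R, Cc, T = movie.dims
    if frames is None:
        frames = (0, T)
    r0, r1 = rows
    c0, c1 = cols
    f0, f1 = frames
    for name, (lo, hi), limit in (("rows", rows, R), ("cols", cols, Cc), ("frames", frames, T)):
        if not (0 <= lo < hi <= limit):
            raise IndexError(f"{name} range [{lo}, {hi}) out of bounds for size {limit}")
    arr = movie.as_array()
    out = np.empty(((r1 - r0) * (c1 - c0), f1 - f0), dtype=arr.dtype)
    width = c1 - c0
    for i, r in enumerate(range(r0, r1)):
        p0 = r * Cc + c0
        out[i * width : (i + 1) * width] = arr[p0 : p0 + width, f0:f1]
    return out


def load_movie(path: str | Path, frame_rate: float = 30.0) -> Movie:
    """Load a TIFF / HDF5("mov") / .pmap movie fully into memory."""
    path = Path(path)
    if path.suffix.lower() == ".pmap":
        return open_memmap(path, frame_rate).to_movie()
    frames = [np.asarray(f, dtype=np.float64) for f in iter_frames(path)]
    stack = np.stack(frames)
    T, rows, cols = stack.shape
    return Movie(
        data=stack.reshape(T, rows * cols).T.copy(),
        fov_dims=(rows, cols),
        frame_rate=frame_rate,
        source_path=str(path),
    )


def save_movie(movie: Movie, path: str | Path, ground_truth=None) -> None:
    """Write a movie as multi-page TIFF or HDF5 (dataset "mov", frames
    first); ground truth, when given, is stored alongside in HDF5."""
    path = Path(path)
    stack = movie.data.T.reshape(movie.n_frames, *movie.fov_dims)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(str(path), stack.astype(np.float32))
        return
    if path.suffix.lower() in {".h5", ".hdf5"}:
        with h5py.File(str(path), "w") as fh:
            fh.create_dataset("mov", data=stack.astype(np.float32))
            fh.attrs["frame_rate"] = movie.frame_rate
            if ground_truth is not None:
                fh.create_dataset("A", data=ground_truth.footprints)
                fh.create_dataset("C", data=ground_truth.traces)
                fh.create_dataset("S", data=ground_truth.spikes)
                fh.create_dataset("b", data=ground_truth.background_spatial)
                fh.create_dataset("f", data=ground_truth.background_temporal)
                fh.attrs["noise_sigma"] = ground_truth.noise_sigma
                fh.attrs["seed"] = ground_truth.seed
        return
    raise ValueError(f"unsupported output format: {path}")
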