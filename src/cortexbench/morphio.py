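"""FreeSurfer per-vertex morphometry ("curv") file interchange.

New-format layout: 3-byte magic 0xFF 0xFF 0xFF, then three big-endian int32s
(vertex count, face count, values per vertex = 1), then vertex count
big-endian float32 values.  Writing delegates to nibabel; reading validates
the layout byte-by-byte so malformed files fail with the offending offset.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
from nibabel.freesurfer.io import write_morph_data

_MAGIC = b"\xff\xff\xff"
_HEADER_LEN = 15  # magic (3) + 3 * int32


class MorphFormatError(ValueError):
    """Raised when a morphometry file violates the 'curv' binary layout."""


def write_morph_file(values: np.ndarray, path) -> None:
    """Write a per-vertex scalar map in FreeSurfer new 'curv' format."""
    values = np.asarray(values, dtype=np.float64).ravel()
    if not np.all(np.isfinite(values)):
        raise ValueError("morphometry values must be finite")
    write_morph_data(str(path), values)


def read_morph_file(path, expected_n_vertices: int | None = None) -> np.ndarray:
    """Read a per-vertex scalar map, validating the binary layout.

    Raises :class:`MorphFormatError` naming the byte offset of the first
    violation, and a mismatch error when `expected_n_vertices` disagrees with
    the file's vertex count.
    """
    data = Path(path).read_bytes()
    if len(data) < 3 or data[:3] != _MAGIC:
        raise MorphFormatError(
            f"{path}: bad magic number at byte offset 0 "
            f"(expected ff ff ff, got {data[:3].hex() or 'EOF'})"
        )
    if len(data) < _HEADER_LEN:
        raise MorphFormatError(
            f"{path}: truncated header at byte offset {len(data)} "
            f"(need {_HEADER_LEN} bytes)"
        )
    n_vertices, n_faces, vals_per_vertex = struct.unpack(">iii", data[3:_HEADER_LEN])
    if n_vertices < 0:
        raise MorphFormatError(f"{path}: negative vertex count at byte offset 3")
    if vals_per_vertex != 1:
        raise MorphFormatError(
            f"{path}: values-per-vertex must be 1 at byte offset 11, got {vals_per_vertex}"
        )
    expected_len = _HEADER_LEN + 4 * n_vertices
    if len(data) < expected_len:
        raise MorphFormatError(
            f"{path}: truncated data at byte offset {len(data)} "
            f"(expected {expected_len} bytes for {n_vertices} vertices)"
        )
    if expected_n_vertices is not None and n_vertices != expected_n_vertices:
        raise ValueError(
            f"{path}: file has {n_vertices} vertices, target mesh has "
            f"{expected_n_vertices}"
        )
    values = np.frombuffer(data[_HEADER_LEN:expected_len], dtype=">f4")
    return values.astype(np.float64)
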