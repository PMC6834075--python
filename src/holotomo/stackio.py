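"""Multi-page TIFF stacks with plain-text metadata sidecars.

Frames travel as 32-bit float multi-page TIFF; acquisition metadata lives in
a diff-able ``<path>.meta.txt`` sidecar of ``key=value`` lines rather than
TIFF tags.  Keys carry their unit as a suffix (``pitch_um``, ``z_mm``,
``energy_kev``); values are stored with full float precision.
"""

from __future__ import annotations

import os

import numpy as np
import tifffile

__all__ = ["read_stack", "write_stack", "sidecar_path", "MissingMetadataError"]


class MissingMetadataError(KeyError):
    """A required sidecar key is absent."""


def sidecar_path(path) -> str:
    return f"{path}.meta.txt"


def _format_value(value) -> str:
    if isinstance(value, float):
        return repr(value)
    if isinstance(value, (list, tuple, np.ndarray)):
        return ",".join(_format_value(v) for v in value)
    return str(value)


def _parse_value(text: str):
    if "," in text:
        return [_parse_value(t) for t in text.split(",")]
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            continue
    return text


def write_stack(frames, metadata: dict, path) -> str:
    """Write frames as float32 multi-page TIFF plus a metadata sidecar.

    Output is deterministic for fixed input: frames are written without
    timestamps and sidecar keys are sorted.
    """
    frames = np.asarray(frames, dtype=np.float32)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise ValueError("frames must be a 2D image or a 3D stack")
    if frames.shape[0] == 0:
        raise ValueError("refusing to write an empty stack")
    tifffile.imwrite(path, frames, photometric="minisblack")
    meta = dict(metadata)
    meta["n_frames"] = frames.shape[0]
    meta["frame_shape"] = (frames.shape[1], frames.shape[2])
    meta["dtype"] = "float32"
    with open(sidecar_path(path), "w") as fh:
        for key in sorted(meta):
            fh.write(f"{key}={_format_value(meta[key])}\n")
    return str(path)


def read_stack(path, required: tuple[str, ...] = ("pitch_um",)):
    """Read a stack and its sidecar; returns (frames, metadata dict).

    Raises :class:`MissingMetadataError` naming any absent required key and
    a format error if the sidecar frame count disagrees with the file.
    """
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    side = sidecar_path(path)
    if not os.path.exists(side):
        raise MissingMetadataError(f"sidecar {side} not found")
    meta: dict = {}
    with open(side) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            meta[key.strip()] = _parse_value(value.strip())
    for key in required:
        if key not in meta:
            raise MissingMetadataError(
                f"required metadata key {key!r} missing from {side}"
            )
    if "n_frames" in meta and meta["n_frames"] != frames.shape[0]:
        raise ValueError(
            f"sidecar says {meta['n_frames']} frames but file holds "
            f"{frames.shape[0]}"
        )
    return frames, meta
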