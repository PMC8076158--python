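"""Reading and writing the package's file formats.

Images travel as multi-page grayscale TIFF; tabular results as CSV; run
configuration and provenance as YAML.  Physical calibration (pixel size,
frame interval) always comes from the user's configuration — it is never
guessed silently from file headers.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .ddm import ImageSequence, StructureFunctionTable

__all__ = [
    "read_stack",
    "write_stack",
    "write_structure_table",
    "read_structure_table",
    "write_config_echo",
    "read_config",
]


def read_stack(path: str | Path, pixel_size: float, dt: float) -> ImageSequence:
    """Read a multi-page grayscale TIFF into an ImageSequence.

    Frames are returned in acquisition order; integer data are promoted to
    float32.  RGB/multi-sample pages and inconsistent frame shapes are
    errors; a truncated file raises naming the failing page.
    """
    path = Path(path)
    frames = []
    with tifffile.TiffFile(path) as tif:
        for i, page in enumerate(tif.pages):
            if getattr(page, "samplesperpixel", 1) > 1:
                raise ValueError(
                    f"{path.name}: page {i} has {page.samplesperpixel} samples "
                    "per pixel; only grayscale stacks are supported"
                )
            try:
                arr = page.asarray()
            except Exception as exc:
                raise IOError(f"{path.name}: failed to read page {i}: {exc}") from exc
            if arr.ndim != 2:
                raise ValueError(f"{path.name}: page {i} is not a 2D grayscale image")
            if frames and arr.shape != frames[0].shape:
                raise ValueError(
                    f"{path.name}: page {i} shape {arr.shape} differs from "
                    f"page 0 shape {frames[0].shape}"
                )
            frames.append(arr)
    if not frames:
        raise ValueError(f"{path.name}: no image pages found")
    stack = np.stack(frames)
    if np.issubdtype(stack.dtype, np.integer):
        stack = stack.astype(np.float32)
    return ImageSequence(frames=stack, dt=dt, pixel_size=pixel_size)


def write_stack(path: str | Path, sequence: ImageSequence | np.ndarray) -> None:
    """Write frames as a float32 multi-page TIFF."""
    frames = sequence.frames if isinstance(sequence, ImageSequence) else np.asarray(sequence)
    tifffile.imwrite(str(path), np.asarray(frames, dtype=np.float32))


def write_structure_table(path: str | Path, table: StructureFunctionTable) -> None:
    """Write D(q, tau) in long CSV format (q, tau, D, count)."""
    table.to_frame().to_csv(path, index=False)


def read_structure_table(
    path: str | Path, pixel_size: float = 0.0, label: str = "DDM"
) -> StructureFunctionTable:
    df = pd.read_csv(path)
    return StructureFunctionTable.from_frame(df, pixel_size=pixel_size, label=label)


def write_config_echo(path: str | Path, config: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
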