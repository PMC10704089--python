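"""TIFF stack reading/writing used throughout the pipeline."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile

__all__ = ["read_stack", "write_stack"]


def read_stack(path) -> tuple[np.ndarray, dict]:
    """Read a grayscale TIFF as a (pages, rows, cols) stack plus metadata.

    8/16-bit integer and float pages are accepted; RGB(A) pages are
    rejected with an error naming the offending page and its shape, and a
    corrupt file raises a distinct error from a missing one.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such TIFF file: {path}")
    try:
        data = tifffile.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise ValueError(f"could not parse {path} as TIFF (corrupt file?): {exc}") from exc
    arr = np.asarray(data)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected single- or multi-page 2D grayscale, got shape {arr.shape}")
    if arr.shape[-1] in (3, 4) and arr.shape[-1] < min(arr.shape[:-1]):
        raise ValueError(
            f"{path}: page 0 looks like RGB/RGBA (shape {arr.shape[1:]}); "
            "only grayscale TIFFs are supported"
        )
    meta = {"dtype": str(arr.dtype), "pages": int(arr.shape[0]), "shape": tuple(arr.shape[1:])}
    return arr.astype(float), meta


def write_stack(path, stack: np.ndarray, dtype: str = "float32") -> None:
    """Write a (pages, rows, cols) or 2D array as a multi-page TIFF.

    float32 by default (HiLo output is not integer ADU); pass "uint16" to
    quantize, in which case values are written as-is and must already be in
    range.
    """
    arr = np.asarray(stack)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"stack must be 2D or 3D, got shape {arr.shape}")
    tifffile.imwrite(path, arr.astype(np.dtype(dtype)))
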