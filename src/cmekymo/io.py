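"""File formats: multi-page TIFF stacks with JSON calibration sidecars,
and versioned CSV tables."""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import DEFAULT_FRAME_INTERVAL_S, DEFAULT_PIXEL_SIZE_NM, FormatError, FrameStack

SCHEMA_PREFIX = "# cmekymo-schema:"
SCHEMA_VERSIONS = {
    "contours": "1.0",
    "traces": "1.0",
    "summaries": "1.0",
    "events": "1.0",
    "report": "1.0",
    "comparison": "1.0",
    "puncta": "1.0",
}


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: FrameStack, path) -> None:
    """Write a stack as multi-page TIFF plus a JSON calibration sidecar.

    Integer-valued data are stored as 16-bit unsigned (values clipped to
    the representable range); anything else as float32.
    """
    path = Path(path)
    pixels = stack.pixels
    if np.issubdtype(pixels.dtype, np.integer) or np.allclose(pixels, np.round(pixels)):
        data = np.clip(np.round(pixels), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    else:
        data = pixels.astype(np.float32)
    tifffile.imwrite(path, data, photometric="minisblack")
    meta = {
        "pixel_size_nm": stack.pixel_size_nm,
        "frame_interval_s": stack.frame_interval_s,
        "channel_name": stack.channel_name,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_stack(path) -> FrameStack:
    """Read a multi-page TIFF into a FrameStack.

    Accepts 8/16-bit integer or float32 grayscale pages; RGB TIFFs are
    rejected. Calibration comes from the JSON sidecar written by
    :func:`write_stack`; if absent, package defaults are applied with a
    warning.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            if page.samplesperpixel and page.samplesperpixel > 1:
                raise FormatError(f"{path}: RGB/multi-sample TIFF not supported; provide grayscale pages")
            pixels = tif.asarray()
    except FormatError:
        raise
    except Exception as exc:  # tifffile raises various errors on non-TIFFs
        raise FormatError(f"{path}: not a readable TIFF ({exc})") from exc
    if pixels.ndim == 2:
        pixels = pixels[None]
    if pixels.ndim != 3:
        raise FormatError(f"{path}: expected T x Y x X pages, got shape {pixels.shape}")
    if pixels.dtype not in (np.uint8, np.uint16, np.int16, np.int32, np.float32, np.float64):
        raise FormatError(f"{path}: unsupported dtype {pixels.dtype}")
    sidecar = _sidecar(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    else:
        warnings.warn(f"{path}: no calibration sidecar; applying defaults (65 nm, 1 s)")
        meta = {}
    return FrameStack(
        pixels=np.asarray(pixels, dtype=float),
        pixel_size_nm=float(meta.get("pixel_size_nm", DEFAULT_PIXEL_SIZE_NM)),
        frame_interval_s=float(meta.get("frame_interval_s", DEFAULT_FRAME_INTERVAL_S)),
        channel_name=str(meta.get("channel_name", "ch1")),
    )


def write_mask(mask: np.ndarray, path) -> None:
    tifffile.imwrite(Path(path), np.asarray(mask).astype(np.uint16), photometric="minisblack")


def read_mask(path) -> np.ndarray:
    from .cell_geometry import validate_mask

    arr = tifffile.imread(Path(path))
    return validate_mask(arr)


def write_table(df: pd.DataFrame, path, schema: str) -> None:
    """Write a CSV with a schema-version header line."""
    path = Path(path)
    version = SCHEMA_VERSIONS[schema]
    with open(path, "w") as fh:
        fh.write(f"{SCHEMA_PREFIX} {schema} v{version}\n")
        df.to_csv(fh, index=False)


def read_table(path, schema: str) -> pd.DataFrame:
    """Read a versioned CSV, rejecting unknown schema names or major versions."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith(SCHEMA_PREFIX):
            raise FormatError(f"{path}: missing schema header")
        name_ver = header[len(SCHEMA_PREFIX) :].strip().rsplit(" v", 1)
        if len(name_ver) != 2 or name_ver[0] != schema:
            raise FormatError(f"{path}: expected schema {schema!r}, found {header!r}")
        major = name_ver[1].split(".")[0]
        expected_major = SCHEMA_VERSIONS[schema].split(".")[0]
        if major != expected_major:
            raise FormatError(f"{path}: schema {schema} major version {major} not supported")
        return pd.read_csv(fh)
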