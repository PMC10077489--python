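"""TIFF I/O for two-channel image pairs with physical pixel-size tags."""
from __future__ import annotations

import numpy as np
import tifffile

from .profiles import ChannelImagePair

_UM_PER_CM = 1.0e4
_UM_PER_INCH = 2.54e4


def write_image_pair(path, pair: ChannelImagePair) -> None:
    """Write a two-page (glx, membrane) 16-bit TIFF with resolution tags."""
    stack = np.stack([pair.glx, pair.membrane])
    stack = np.clip(np.round(stack), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    px_per_cm = _UM_PER_CM / pair.pixel_size
    tifffile.imwrite(
        str(path),
        stack,
        photometric="minisblack",
        resolution=(px_per_cm, px_per_cm),
        resolutionunit=tifffile.RESUNIT.CENTIMETER,
    )


def read_image_pair(path) -> ChannelImagePair:
    """Read a two-page TIFF; pixel size is recovered from the resolution tags."""
    with tifffile.TiffFile(str(path)) as tif:
        arr = tif.asarray()
        page = tif.pages[0]
        tags = page.tags
        if "XResolution" not in tags or "ResolutionUnit" not in tags:
            raise ValueError(f"{path}: pixel-size metadata missing from TIFF tags")
        num, den = tags["XResolution"].value
        unit = tags["ResolutionUnit"].value
    if num == 0:
        raise ValueError(f"{path}: zero XResolution, cannot recover pixel size")
    px_per_unit = num / den
    if unit == tifffile.RESUNIT.CENTIMETER:
        pixel_size = _UM_PER_CM / px_per_unit
    elif unit == tifffile.RESUNIT.INCH:
        pixel_size = _UM_PER_INCH / px_per_unit
    else:
        raise ValueError(f"{path}: unsupported TIFF resolution unit {unit!r}")
    if arr.ndim != 3 or arr.shape[0] != 2:
        raise ValueError(
            f"{path}: expected a 2-page (glx, membrane) TIFF, got shape {arr.shape}"
        )
    return ChannelImagePair(
        glx=arr[0].astype(float), membrane=arr[1].astype(float), pixel_size=pixel_size
    )
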