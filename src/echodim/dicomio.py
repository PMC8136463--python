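"""Minimal DICOM metadata access: physical pixel spacing only."""

from __future__ import annotations

from pathlib import Path

import pydicom


def read_dicom_spacing(path: str | Path) -> tuple[float, float]:
    """Return (row, column) pixel spacing in mm from a DICOM file.

    Reads the PixelSpacing attribute (tag 0028,0030; row spacing first).
    Files without the tag, or with nonpositive values, are refused — supply
    the spacing manually in that case.
    """
    ds = pydicom.dcmread(str(path), stop_before_pixels=True, force=True)
    spacing = getattr(ds, "PixelSpacing", None)
    if spacing is None or len(spacing) < 2:
        raise ValueError(
            f"{path}: no PixelSpacing (0028,0030) metadata; "
            "enter the row/column spacing in mm manually"
        )
    row, col = float(spacing[0]), float(spacing[1])
    if row <= 0 or col <= 0:
        raise ValueError(f"{path}: nonpositive PixelSpacing {row}, {col}")
    return row, col
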