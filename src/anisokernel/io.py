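"""NIfTI volume and peak-table readers/writers."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .grid import VolumeGrid
from .meta import Peak, Study

PEAK_COLUMNS = ["study_id", "x", "y", "z", "value", "stat", "n1", "n2"]


def read_volume(path) -> VolumeGrid:
    """Read a 3D NIfTI-1 volume (optionally gzipped)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
    except Exception as exc:
        raise ValueError(f"could not parse NIfTI file {path}: {exc}") from exc
    if data.ndim == 4 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got {data.ndim}D")
    return VolumeGrid(data, img.affine)


def write_volume(grid: VolumeGrid, path) -> None:
    """Write a volume as 32-bit float NIfTI-1."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(
        nib.Nifti1Image(grid.data.astype(np.float32), grid.affine), str(path)
    )


def read_peaks(path) -> list[Study]:
    """Read a delimited peak table into Study records.

    Expected header: ``study_id x y z value stat n1 n2`` with
    ``stat in {t, d}`` and coordinates in MNI mm. Rows are grouped by
    study_id (first-appearance order); malformed rows raise errors
    carrying the offending line number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such peak table: {path}")
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    studies: dict[str, Study] = {}
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            coord = (float(row["x"]), float(row["y"]), float(row["z"]))
            value = float(row["value"])
            n1, n2 = int(row["n1"]), int(row["n2"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}:{line}: non-numeric field: {exc}") from exc
        stat = str(row["stat"]).strip()
        if stat not in ("t", "d"):
            raise ValueError(
                f"{path}:{line}: unsupported stat {stat!r} (expected 't' or 'd')"
            )
        sid = str(row["study_id"])
        peak = Peak(coord_mm=coord, value=value, stat=stat)
        if sid not in studies:
            try:
                studies[sid] = Study(study_id=sid, peaks=[peak], n1=n1, n2=n2)
            except ValueError as exc:
                raise ValueError(f"{path}:{line}: {exc}") from exc
        else:
            st = studies[sid]
            if (n1, n2) != (st.n1, st.n2):
                raise ValueError(
                    f"{path}:{line}: inconsistent group sizes for study {sid}"
                )
            st.peaks.append(peak)
    return list(studies.values())


def write_peaks(studies: list[Study], path) -> None:
    """Write studies back to the tab-delimited peak-table format."""
    rows = []
    for st in studies:
        for p in st.peaks:
            rows.append(
                {"study_id": st.study_id, "x": p.coord_mm[0],
                 "y": p.coord_mm[1], "z": p.coord_mm[2],
                 "value": p.value, "stat": p.stat, "n1": st.n1, "n2": st.n2}
            )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=PEAK_COLUMNS).to_csv(path, sep="\t", index=False)
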