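"""File I/O for the standard exchange formats the pipeline accepts.

Point clouds travel as XYZ text, PLY (via trimesh) or CSV with x,y,z
columns in mm; multi-echo stacks as 4-D NIfTI (echo on the last axis) or
multi-page TIFF (one page per echo); score, census and measurement tables
as tidy CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .t2map import EchoStack


def read_point_cloud(path) -> np.ndarray:
    """Load an (N, 3) mm point cloud from .xyz, .ply or .csv."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".xyz":
        pts = np.loadtxt(path)
    elif suffix == ".csv":
        df = pd.read_csv(path)
        pts = df[["x", "y", "z"]].to_numpy(float)
    elif suffix == ".ply":
        import trimesh

        pts = np.asarray(trimesh.load(path, process=False).vertices, float)
    else:
        raise ValueError(f"unsupported point-cloud format {suffix!r}")
    pts = np.atleast_2d(pts)
    if pts.shape[1] != 3:
        raise ValueError("point cloud must have three columns")
    return pts


def write_point_cloud(points: np.ndarray, path) -> None:
    path = Path(path)
    suffix = path.suffix.lower()
    points = np.asarray(points, float)
    if suffix == ".xyz":
        np.savetxt(path, points, fmt="%.6f")
    elif suffix == ".csv":
        pd.DataFrame(points, columns=["x", "y", "z"]).to_csv(path, index=False)
    elif suffix == ".ply":
        import trimesh

        trimesh.PointCloud(points).export(path)
    else:
        raise ValueError(f"unsupported point-cloud format {suffix!r}")


def write_echo_stack(stack: EchoStack, path) -> None:
    """Write a stack as 4-D NIfTI (.nii/.nii.gz) or multi-page TIFF."""
    path = Path(path)
    if path.suffix.lower() in (".nii", ".gz"):
        import nibabel as nib

        sig = stack.signal
        if sig.ndim == 3:  # 2-D image x echo -> x, y, 1, echo
            sig = sig[:, :, None, :]
        nib.save(nib.Nifti1Image(np.asarray(sig, np.float32), np.eye(4)), str(path))
    elif path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        # pages = echoes
        tifffile.imwrite(path, np.moveaxis(stack.signal, -1, 0).astype(np.float32))
    else:
        raise ValueError(f"unsupported stack format {path.suffix!r}")


def read_echo_stack(path, te_list_ms) -> EchoStack:
    path = Path(path)
    if path.suffix.lower() in (".nii", ".gz"):
        import nibabel as nib

        sig = np.asarray(nib.load(str(path)).get_fdata(), float)
        sig = np.squeeze(sig)
    elif path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        sig = np.moveaxis(np.asarray(tifffile.imread(path), float), 0, -1)
    else:
        raise ValueError(f"unsupported stack format {path.suffix!r}")
    return EchoStack(signal=sig, te_list_ms=np.asarray(te_list_ms, float))
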