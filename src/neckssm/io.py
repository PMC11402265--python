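"""Readers and writers for the pipeline's on-disk formats.

Inter-stage contracts are deliberately plain text:

- meshes: PLY/OBJ/STL via trimesh;
- centerline + markers: a JSON sidecar
  ``{"centerline": [[x,y,z],...], "renal": [...], "distal": [...]}`` in mm,
  patient axes x=left, y=anterior, z=cranial;
- landmark grids: one long CSV with columns
  subject_id, level, azimuth_deg, x, y, z;
- shape model: a JSON metadata file plus CSV matrices for the mean shape
  and the components;
- scores/measures/metrics: flat CSV tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from neckssm.errors import InvalidParameterError
from neckssm.parametrization import CenterLumenLine, LumenSurface, ParametrizedNeck
from neckssm.ssm import PCScores, ShapeModel

__all__ = [
    "read_mesh",
    "read_sidecar",
    "write_landmarks_csv",
    "read_landmarks_csv",
    "write_scores_csv",
    "read_scores_csv",
    "write_model",
    "read_model",
]


def read_mesh(path: str | Path) -> LumenSurface:
    """Load a PLY/OBJ/STL surface into a :class:`LumenSurface`."""
    mesh = trimesh.load_mesh(str(path), process=False)
    return LumenSurface.from_trimesh(mesh)


def read_sidecar(path: str | Path) -> tuple[CenterLumenLine, np.ndarray, np.ndarray]:
    """Load the centerline + marker JSON sidecar."""
    data = json.loads(Path(path).read_text())
    for key in ("centerline", "renal", "distal"):
        if key not in data:
            raise InvalidParameterError(f"sidecar missing key {key!r}")
    return (
        CenterLumenLine(np.asarray(data["centerline"], dtype=float)),
        np.asarray(data["renal"], dtype=float),
        np.asarray(data["distal"], dtype=float),
    )


def write_landmarks_csv(necks: list[ParametrizedNeck], path: str | Path) -> None:
    """Write landmark grids in the canonical long format."""
    frames = []
    for neck in necks:
        L, A, _ = neck.landmarks.shape
        lev, ang = np.meshgrid(np.arange(L), np.arange(A), indexing="ij")
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": neck.subject_id,
                    "group": neck.group,
                    "level": lev.ravel(),
                    "azimuth_deg": ang.ravel() * (360.0 / A),
                    "x": neck.landmarks[:, :, 0].ravel(),
                    "y": neck.landmarks[:, :, 1].ravel(),
                    "z": neck.landmarks[:, :, 2].ravel(),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_landmarks_csv(path: str | Path) -> list[ParametrizedNeck]:
    """Read the long landmark CSV back into per-subject grids."""
    df = pd.read_csv(path)
    necks = []
    for sid, g in df.groupby("subject_id", sort=False):
        levels = int(g["level"].max()) + 1
        angles = len(g) // levels
        g = g.sort_values(["level", "azimuth_deg"])
        grid = g[["x", "y", "z"]].to_numpy().reshape(levels, angles, 3)
        group = str(g["group"].iloc[0]) if "group" in g else ""
        necks.append(
            ParametrizedNeck(
                landmarks=grid,
                level_arclengths=np.zeros(levels),
                subject_id=str(sid),
                group="" if group == "nan" else group,
            )
        )
    return necks


def write_scores_csv(scores: PCScores, path: str | Path) -> None:
    k = scores.scores.shape[1]
    df = pd.DataFrame(scores.scores, columns=[f"pc{j + 1}" for j in range(k)])
    df.insert(0, "group", scores.groups)
    df.insert(0, "subject_id", scores.subject_ids)
    df.to_csv(path, index=False)


def read_scores_csv(path: str | Path) -> PCScores:
    df = pd.read_csv(path)
    pc_cols = [c for c in df.columns if c.startswith("pc")]
    return PCScores(
        scores=df[pc_cols].to_numpy(dtype=float),
        subject_ids=[str(s) for s in df["subject_id"]],
        groups=[str(g) for g in df["group"]],
    )


def write_model(model: ShapeModel, out_dir: str | Path) -> None:
    """Serialize the shape model as JSON metadata + CSV matrices."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "n_components": model.n_components,
        "n_retained": model.n_retained,
        "retention_threshold": model.retention_threshold,
        "grid_shape": list(model.grid_shape),
        "variances": model.variances.tolist(),
        "variance_fraction": model.variance_fraction.tolist(),
    }
    (out / "model.json").write_text(json.dumps(meta, indent=2))
    np.savetxt(out / "mean_shape.csv", model.mean_shape[None, :], delimiter=",")
    np.savetxt(out / "components.csv", model.components, delimiter=",")


def read_model(model_dir: str | Path) -> ShapeModel:
    d = Path(model_dir)
    meta = json.loads((d / "model.json").read_text())
    mean = np.loadtxt(d / "mean_shape.csv", delimiter=",").ravel()
    comps = np.atleast_2d(np.loadtxt(d / "components.csv", delimiter=","))
    return ShapeModel(
        mean_shape=mean,
        components=comps,
        variances=np.asarray(meta["variances"], dtype=float),
        variance_fraction=np.asarray(meta["variance_fraction"], dtype=float),
        n_retained=int(meta["n_retained"]),
        retention_threshold=float(meta["retention_threshold"]),
        grid_shape=tuple(meta["grid_shape"]),
    )
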