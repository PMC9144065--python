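"""Volume, mesh and config I/O.

Volumes are written as NIfTI (``.nii.gz``, via nibabel) or MetaImage
(``.mha``, via SimpleITK), with the label grid in a parallel
``*_labels`` volume.  Meshes and per-element fields are written as ASCII
VTU (XML unstructured grid) for inspection in ParaView.  Lesion sets and
study configs round-trip through JSON/YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk
import yaml

from .lesions import Lesion
from .volume import HUVolume


def _labels_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii", ".mha"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + "_labels" + suffix)
    raise ValueError(f"unsupported volume format: {path}")


def write_volume(volume: HUVolume, path) -> Path:
    """Write HU values plus a parallel ``*_labels`` integer volume."""
    path = Path(path)
    lpath = _labels_path(path)
    spacing = np.asarray(volume.spacing)
    # image origin is the center of voxel (0,0,0)
    origin = np.asarray(volume.origin) + spacing / 2.0
    if path.name.endswith((".nii.gz", ".nii")):
        affine = np.diag([*spacing, 1.0])
        affine[:3, 3] = origin
        nib.save(nib.Nifti1Image(volume.values, affine), str(path))
        nib.save(
            nib.Nifti1Image(volume.labels.astype(np.int16), affine), str(lpath)
        )
    else:
        for arr, p in ((volume.values, path), (volume.labels.astype(np.int16), lpath)):
            img = sitk.GetImageFromArray(np.ascontiguousarray(arr.T))
            img.SetSpacing(tuple(float(s) for s in spacing))
            img.SetOrigin(tuple(float(o) for o in origin))
            sitk.WriteImage(img, str(p))
    return path


def read_volume(path) -> HUVolume:
    """Read a volume written by :func:`write_volume` (values + labels)."""
    path = Path(path)
    lpath = _labels_path(path)
    if path.name.endswith((".nii.gz", ".nii")):
        img = nib.load(str(path))
        values = np.asarray(img.dataobj, dtype=float)
        labels = np.asarray(nib.load(str(lpath)).dataobj).astype(np.int8)
        spacing = tuple(float(s) for s in img.header.get_zooms()[:3])
        center0 = np.asarray(img.affine[:3, 3], dtype=float)
    else:
        img = sitk.ReadImage(str(path))
        values = sitk.GetArrayFromImage(img).T.astype(float)
        labels = sitk.GetArrayFromImage(sitk.ReadImage(str(lpath))).T.astype(np.int8)
        spacing = tuple(float(s) for s in img.GetSpacing())
        center0 = np.asarray(img.GetOrigin(), dtype=float)
    origin = tuple(center0 - np.asarray(spacing) / 2.0)
    return HUVolume(values, labels, spacing, origin)


def write_vtu(path, model, cell_data: dict | None = None) -> Path:
    """Write the hex mesh with per-element fields as ASCII VTU."""
    path = Path(path)
    nodes = model.nodes
    conn = model.conn
    n_cells = len(conn)
    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{len(nodes)}" NumberOfCells="{n_cells}">',
        "<Points>",
        '<DataArray type="Float64" NumberOfComponents="3" format="ascii">',
        "\n".join(" ".join(f"{v:.8g}" for v in row) for row in nodes),
        "</DataArray>",
        "</Points>",
        "<Cells>",
        '<DataArray type="Int64" Name="connectivity" format="ascii">',
        "\n".join(" ".join(str(int(v)) for v in row) for row in conn),
        "</DataArray>",
        '<DataArray type="Int64" Name="offsets" format="ascii">',
        " ".join(str(8 * (i + 1)) for i in range(n_cells)),
        "</DataArray>",
        '<DataArray type="UInt8" Name="types" format="ascii">',
        " ".join("12" for _ in range(n_cells)),
        "</DataArray>",
        "</Cells>",
    ]
    if cell_data:
        lines.append("<CellData>")
        for name, arr in cell_data.items():
            arr = np.asarray(arr, dtype=float).ravel()
            lines.append(
                f'<DataArray type="Float64" Name="{name}" format="ascii">'
            )
            lines.append(" ".join(f"{v:.8g}" for v in arr))
            lines.append("</DataArray>")
        lines.append("</CellData>")
    lines += ["</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    path.write_text("\n".join(lines))
    return path


def lesions_to_config(lesions) -> list[dict]:
    return [
        {
            "center": [float(c) for c in le.center],
            "radius": float(le.radius),
            "type": le.type,
            "Em": float(le.Em),
            "nu_m": float(le.nu_m),
            "tau_m": float(le.tau_m),
        }
        for le in lesions
    ]


def lesions_from_config(entries) -> list[Lesion]:
    out = []
    for e in entries:
        out.append(
            Lesion(
                center=tuple(e["center"]),
                radius=e["radius"],
                type=e.get("type", "osteolytic"),
                Em=e.get("Em"),
                nu_m=e.get("nu_m", 0.3),
                tau_m=e.get("tau_m", 1.0),
            )
        )
    return out


def load_config(path) -> dict:
    """Load a JSON or YAML config file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def save_config(data: dict, path) -> Path:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data))
    return path
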