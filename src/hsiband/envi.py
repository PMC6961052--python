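"""File I/O: ENVI cubes, ground-truth PNGs and tabular pixel datasets.

Cubes are written as a classic ENVI pair — a text ``.hdr`` with the wavelength
list and a raw binary file in BIL interleave (line, band, sample) — plus an
alternative single-file compressed ``.npz`` container.  Ground truth maps are
single-channel PNGs with the 0/1/2/3/255 class code.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .types import GroundTruthMap, HSCube, LabeledDataset, SpectralGrid

_DTYPE_TO_ENVI = {"uint8": 1, "int16": 2, "int32": 3, "float32": 4, "float64": 5, "uint16": 12}
_ENVI_TO_DTYPE = {v: k for k, v in _DTYPE_TO_ENVI.items()}

# ENVI byte order code: 0 little-endian, 1 big-endian
_BYTE_ORDER = 0


def write_envi(cube: HSCube, path: str | Path, dtype: str = "float32") -> Path:
    """Write ``path``.hdr + ``path``.raw (BIL). Returns the header path."""
    path = Path(path)
    if path.suffix == ".hdr":
        path = path.with_suffix("")
    rows, cols, bands = cube.shape
    if dtype not in _DTYPE_TO_ENVI:
        raise ValueError(f"unsupported dtype {dtype!r}")
    data = np.ascontiguousarray(cube.values.transpose(0, 2, 1).astype(dtype))  # BIL
    raw_path = path.with_suffix(".raw")
    data.tofile(raw_path)
    wl = ", ".join(f"{w:.6f}" for w in cube.grid.wavelengths)
    hdr = (
        "ENVI\n"
        f"description = {{{cube.image_id} (patient {cube.patient_id})}}\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_TO_ENVI[dtype]}\n"
        "interleave = bil\n"
        f"byte order = {_BYTE_ORDER}\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    hdr_path = path.with_suffix(".hdr")
    hdr_path.write_text(hdr)
    return hdr_path


def read_envi(path: str | Path) -> HSCube:
    """Read an ENVI .hdr/.raw pair written by :func:`write_envi`."""
    path = Path(path)
    hdr_path = path if path.suffix == ".hdr" else path.with_suffix(".hdr")
    fields = _parse_envi_header(hdr_path.read_text())
    rows, cols, bands = int(fields["lines"]), int(fields["samples"]), int(fields["bands"])
    dtype = _ENVI_TO_DTYPE[int(fields["data type"])]
    interleave = fields.get("interleave", "bil").lower()
    if interleave != "bil":
        raise ValueError(f"only BIL interleave supported, got {interleave!r}")
    raw = np.fromfile(hdr_path.with_suffix(".raw"), dtype=dtype)
    if raw.size != rows * cols * bands:
        raise ValueError("raw file size does not match header dimensions")
    values = raw.reshape(rows, bands, cols).transpose(0, 2, 1)
    wl = np.array([float(x) for x in fields["wavelength"].split(",")])
    desc = fields.get("description", "")
    m = re.match(r"(\S+) \(patient (\S+)\)", desc)
    image_id, patient_id = (m.group(1), m.group(2)) if m else ("unknown", "unknown")
    return HSCube(values, SpectralGrid(wl), patient_id=patient_id, image_id=image_id)


def _parse_envi_header(text: str) -> dict[str, str]:
    fields: dict[str, str] = {}
    # join { ... } blocks that span lines, then split on '='
    text = re.sub(r"\{([^}]*)\}", lambda m: m.group(1).replace("\n", " "), text)
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    return fields


def write_npz(cube: HSCube, gt: GroundTruthMap | None, path: str | Path) -> Path:
    """Single-file compressed container (values, wavelengths, ids, labels)."""
    path = Path(path).with_suffix(".npz")
    payload = {
        "values": cube.values.astype(np.float32),
        "wavelengths": cube.grid.wavelengths,
        "patient_id": np.str_(cube.patient_id),
        "image_id": np.str_(cube.image_id),
    }
    if gt is not None:
        payload["labels"] = gt.labels
    np.savez_compressed(path, **payload)
    return path


def read_npz(path: str | Path) -> tuple[HSCube, GroundTruthMap | None]:
    with np.load(path) as z:
        cube = HSCube(
            z["values"].astype(np.float64),
            SpectralGrid(z["wavelengths"]),
            patient_id=str(z["patient_id"]),
            image_id=str(z["image_id"]),
        )
        gt = GroundTruthMap(z["labels"]) if "labels" in z else None
    return cube, gt


def write_ground_truth_png(gt: GroundTruthMap, path: str | Path) -> Path:
    path = Path(path).with_suffix(".png")
    Image.fromarray(gt.labels, mode="L").save(path)
    return path


def read_ground_truth_png(path: str | Path) -> GroundTruthMap:
    return GroundTruthMap(np.asarray(Image.open(path).convert("L")))


def write_dataset(data: LabeledDataset, path: str | Path) -> Path:
    """One row per pixel: patient_id, image_id, class, then reflectances."""
    path = Path(path)
    cols = (
        [f"{w:.6f}" for w in data.grid.wavelengths]
        if data.grid is not None
        else [f"b{i}" for i in range(data.n_bands)]
    )
    df = pd.DataFrame(data.spectra, columns=cols)
    df.insert(0, "class", data.labels)
    df.insert(0, "image_id", data.image_ids)
    df.insert(0, "patient_id", data.patient_ids)
    if path.suffix in {".h5", ".hdf5"}:
        df.to_hdf(path, key="pixels", mode="w")
    else:
        df.to_csv(path, index=False)
    return path


def read_dataset(path: str | Path) -> LabeledDataset:
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        df = pd.read_hdf(path, key="pixels")
    else:
        df = pd.read_csv(path)
    meta = ["patient_id", "image_id", "class"]
    band_cols = [c for c in df.columns if c not in meta]
    try:
        wl = np.array([float(c) for c in band_cols])
        grid = SpectralGrid(wl)
    except ValueError:
        grid = None
    return LabeledDataset(
        df[band_cols].to_numpy(dtype=float),
        df["class"].to_numpy(),
        df["patient_id"].to_numpy(),
        df["image_id"].to_numpy(),
        grid=grid,
    )
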