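"""File formats: delimited spectra/reference tables, ENVI-style cubes, masks.

Spectra tables are plain delimited text with a wavelength header row and a
sample-id first column. Cubes use the ENVI convention: a small text header
(`samples`, `lines`, `bands`, `interleave = bsq`, `data type = 4`,
`wavelength = {...}`) next to a band-sequential float32 binary.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import HyperspectralCube, ReferenceVector, SpectraMatrix

__all__ = [
    "write_spectra",
    "read_spectra",
    "write_reference",
    "read_reference",
    "write_envi",
    "read_envi",
    "write_mask",
    "read_mask",
    "load_config_file",
]


def write_spectra(spectra: SpectraMatrix, path, sep: str = ",") -> None:
    spectra.to_dataframe().to_csv(path, sep=sep)


def read_spectra(path, sep: str = ",") -> SpectraMatrix:
    df = pd.read_csv(path, sep=sep, index_col=0)
    return SpectraMatrix.from_dataframe(df)


def write_reference(ref: ReferenceVector, path, sep: str = ",") -> None:
    pd.DataFrame({"sample_id": ref.sample_ids, "ssc": ref.ssc}).to_csv(
        path, sep=sep, index=False
    )


def read_reference(path, sep: str = ",") -> ReferenceVector:
    df = pd.read_csv(path, sep=sep)
    return ReferenceVector(df["ssc"].to_numpy(float), [str(s) for s in df["sample_id"]])


_ENVI_DTYPES = {1: np.uint8, 2: np.int16, 4: np.float32, 5: np.float64, 12: np.uint16}


def write_envi(cube: HyperspectralCube, base_path) -> tuple[Path, Path]:
    """Write ``base.hdr`` + ``base.raw`` (BSQ float32). Returns both paths."""
    base = Path(base_path)
    hdr, raw = base.with_suffix(".hdr"), base.with_suffix(".raw")
    rows, cols, bands = cube.shape
    wl = ", ".join(f"{w:.6f}" for w in cube.wavelengths)
    hdr.write_text(
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        "data type = 4\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        f"wavelength = {{ {wl} }}\n"
    )
    cube.data.transpose(2, 0, 1).astype("<f4").tofile(raw)
    return hdr, raw


def read_envi(hdr_path) -> HyperspectralCube:
    """Read a BSQ ENVI header + binary pair into a cube (no references)."""
    hdr_path = Path(hdr_path)
    text = hdr_path.read_text()
    fields: dict[str, str] = {}
    for m in re.finditer(r"^\s*([a-z ]+?)\s*=\s*(\{[^}]*\}|[^\n]*)", text, re.M | re.S):
        fields[m.group(1).strip()] = m.group(2).strip()
    try:
        cols = int(fields["samples"])
        rows = int(fields["lines"])
        bands = int(fields["bands"])
        dtype_code = int(fields.get("data type", "4"))
        interleave = fields.get("interleave", "bsq").lower()
    except KeyError as exc:
        raise ValueError(f"ENVI header {hdr_path} is missing key {exc}") from exc
    if interleave != "bsq":
        raise ValueError(f"only BSQ interleave is supported, got {interleave!r}")
    if dtype_code not in _ENVI_DTYPES:
        raise ValueError(f"unsupported ENVI data type code {dtype_code}")
    wl_text = fields.get("wavelength", "")
    wavelengths = np.array(
        [float(v) for v in re.findall(r"[-+0-9.eE]+", wl_text)], dtype=float
    )
    if wavelengths.size != bands:
        raise ValueError(
            f"header lists {wavelengths.size} wavelengths for {bands} bands"
        )
    raw = hdr_path.with_suffix(".raw")
    if not raw.exists():
        raise FileNotFoundError(f"ENVI binary {raw} not found")
    offset = int(fields.get("header offset", "0"))
    data = np.fromfile(raw, dtype=_ENVI_DTYPES[dtype_code], offset=offset)
    if data.size != rows * cols * bands:
        raise ValueError(
            f"{raw} holds {data.size} values, expected {rows * cols * bands}"
        )
    cube_data = data.reshape(bands, rows, cols).transpose(1, 2, 0).astype(float)
    return HyperspectralCube(cube_data, wavelengths)


def write_mask(mask: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(mask, dtype=int), fmt="%d")


def read_mask(path) -> np.ndarray:
    return np.loadtxt(path, dtype=int).astype(bool)


def load_config_file(path) -> dict:
    """Load a YAML or JSON experiment-config mapping."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return data
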