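"""Reading and writing the package's on-disk formats.

Image stacks are stored as multi-page TIFF (page order round → channel → z)
with a JSON sidecar carrying geometry, optics and the bit map; ground truth
and decoded molecules are plain CSV tables.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .decode import DecodedMolecule
from .simulate import FieldGeometry, GroundTruth, ImageStack, OpticsModel

__all__ = [
    "write_stack",
    "read_stack",
    "write_truth_csv",
    "read_truth_csv",
    "write_molecules_csv",
    "read_molecules_csv",
    "write_probes_tsv",
]


def _sidecar_path(tiff_path: Path) -> Path:
    return tiff_path.with_suffix(tiff_path.suffix + ".json")


def write_stack(stack: ImageStack, path) -> None:
    path = Path(path)
    n_r, n_c, nz, ny, nx = stack.data.shape
    pages = stack.data.reshape(n_r * n_c * nz, ny, nx).astype(np.float32)
    tifffile.imwrite(path, pages)
    meta = {
        "shape": list(stack.data.shape),
        "geometry": dataclasses.asdict(stack.geometry),
        "optics": dataclasses.asdict(stack.optics),
        "bit_map": [[b // n_c, b % n_c] for b in range(n_r * n_c)],
        "bead_xy": None if stack.bead_xy is None else stack.bead_xy.tolist(),
        "drift": None if stack.drift is None else np.asarray(stack.drift).tolist(),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_stack(path) -> ImageStack:
    path = Path(path)
    meta = json.loads(_sidecar_path(path).read_text())
    pages = tifffile.imread(path)
    data = np.asarray(pages, dtype=np.float64).reshape(meta["shape"])
    opt = meta["optics"]
    if opt.get("per_round_drift") is not None:
        opt["per_round_drift"] = tuple(tuple(d) for d in opt["per_round_drift"])
    return ImageStack(
        data=data,
        geometry=FieldGeometry(**meta["geometry"]),
        optics=OpticsModel(**opt),
        bead_xy=None if meta["bead_xy"] is None else np.array(meta["bead_xy"]),
        drift=None if meta["drift"] is None else np.array(meta["drift"]),
    )


def _bits_str(bits: np.ndarray) -> str:
    return "".join(str(int(b)) for b in bits)


def write_truth_csv(truth: GroundTruth, path) -> None:
    df = pd.DataFrame(
        {
            "molecule_id": np.arange(len(truth)),
            "species": truth.species,
            "barcode_id": truth.barcode_idx,
            "x_um": truth.x,
            "y_um": truth.y,
            "z_um": truth.z,
            "bits_true": [_bits_str(b) for b in truth.bits_true],
            "bits_realized": [_bits_str(b) for b in truth.bits_realized],
        }
    )
    df.to_csv(path, index=False)


def read_truth_csv(path, geometry: FieldGeometry) -> GroundTruth:
    df = pd.read_csv(path, dtype={"bits_true": str, "bits_realized": str})
    to_bits = lambda col: np.array([[int(c) for c in s] for s in df[col]], dtype=np.uint8)
    return GroundTruth(
        species=df["species"].to_numpy(dtype=object),
        barcode_idx=df["barcode_id"].to_numpy(),
        bits_true=to_bits("bits_true"),
        bits_realized=to_bits("bits_realized"),
        x=df["x_um"].to_numpy(),
        y=df["y_um"].to_numpy(),
        z=df["z_um"].to_numpy(),
        geometry=geometry,
    )


def write_molecules_csv(molecules: list[DecodedMolecule], path) -> None:
    df = pd.DataFrame(
        [
            {
                "barcode_id": m.barcode_id,
                "label": m.label,
                "x_um": m.x_um,
                "y_um": m.y_um,
                "z_um": m.z_um,
                "n_pixels": m.n_pixels,
                "distance": m.distance,
                "was_corrected": m.was_corrected,
                "cell_id": m.cell_id,
            }
            for m in molecules
        ]
    )
    df.to_csv(path, index=False)


def read_molecules_csv(path) -> list[DecodedMolecule]:
    df = pd.read_csv(path)
    return [
        DecodedMolecule(
            barcode_id=int(r.barcode_id),
            label="" if pd.isna(r.label) else str(r.label),
            x_um=float(r.x_um),
            y_um=float(r.y_um),
            z_um=float(r.z_um),
            n_pixels=int(r.n_pixels),
            distance=float(r.distance),
            was_corrected=bool(r.was_corrected),
            cell_id=int(r.cell_id),
        )
        for r in df.itertuples()
    ]


def write_probes_tsv(probes, path) -> None:
    """`gene probe_index start end readout_a readout_b product_sequence full_sequence`."""
    df = pd.DataFrame(
        [
            {
                "gene": p.gene,
                "probe_index": i,
                "start": p.tile.start,
                "end": p.tile.end,
                "readout_a": p.readout_a,
                "readout_b": p.readout_b,
                "product_sequence": p.product_sequence,
                "full_sequence": p.full_sequence,
            }
            for i, p in enumerate(probes)
        ]
    )
    df.to_csv(path, sep="\t", index=False)
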