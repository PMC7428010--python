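"""Readers and writers shared by the pipeline.

CSV dialect: UTF-8, comma-separated, '.' decimal, mandatory header row,
missing values as empty fields.  Every written table gets a provenance
sidecar ``<name>.provenance.json`` recording the config hash and catalog
version.  Images are single-channel TIFF or PNG (8/16-bit or float).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .network import IntensityImage, NetworkElements

logger = logging.getLogger(__name__)

__all__ = [
    "read_image",
    "write_table",
    "read_plate_map",
    "read_annotations",
    "read_fingerprints",
    "read_expression",
    "element_table",
    "edge_list",
    "write_overlay_png",
]


def read_image(path: str | Path, pixel_size: float = 1.0) -> IntensityImage:
    """Read a single-channel TIFF or PNG well image."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if arr.shape[2] not in (1, 3, 4):
            raise ValueError(f"{path}: expected single-channel image")
        arr = arr[..., 0]
    return IntensityImage(pixels=arr.astype(float), pixel_size=pixel_size)


def write_table(df: pd.DataFrame, path: str | Path, config: RunConfig | None = None,
                catalog_version: str = "1.0", index: bool = True) -> None:
    """Write a CSV plus its provenance sidecar JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index)
    if config is not None:
        side = path.with_suffix(path.suffix + ".provenance.json")
        side.write_text(json.dumps(config.provenance(catalog_version), indent=1))


def read_plate_map(path: str | Path) -> pd.DataFrame:
    """Plate map CSV: plate, well, compound, replicate, is_dmso[, excluded]."""
    df = pd.read_csv(path)
    req = {"plate", "well", "compound", "replicate", "is_dmso"}
    missing = req - set(df.columns)
    if missing:
        raise ValueError(f"plate map missing columns: {sorted(missing)}")
    df["is_dmso"] = df["is_dmso"].astype(bool)
    return df.set_index("well")


def read_annotations(path: str | Path) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Annotation CSV: compound, term[, parent_term] -> (annotations, hierarchy)."""
    df = pd.read_csv(path)
    if not {"compound", "term"} <= set(df.columns):
        raise ValueError("annotation CSV needs columns: compound, term")
    ann: dict[str, set[str]] = {}
    hier: dict[str, str] = {}
    for _, row in df.iterrows():
        ann.setdefault(str(row["compound"]), set()).add(str(row["term"]))
        parent = row.get("parent_term")
        if isinstance(parent, str) and parent:
            hier[str(row["term"])] = parent
    return ann, hier


def read_fingerprints(path: str | Path) -> dict[str, str]:
    """Fingerprint CSV: compound, bits (0/1 string or hex with 0x prefix)."""
    df = pd.read_csv(path, dtype=str)
    if not {"compound", "bits"} <= set(df.columns):
        raise ValueError("fingerprint CSV needs columns: compound, bits")
    out = {}
    for _, row in df.iterrows():
        bits = row["bits"].strip()
        if bits.lower().startswith("0x"):
            nbits = (len(bits) - 2) * 4
            bits = bin(int(bits, 16))[2:].zfill(nbits)
        if set(bits) - {"0", "1"}:
            raise ValueError(f"{row['compound']}: fingerprint is not a bitstring")
        out[str(row["compound"])] = bits
    return out


def read_expression(expr_path: str | Path, meta_path: str | Path,
                    gene_set_paths: dict[str, str | Path] | None = None):
    """Expression TSV (genes x samples) + metadata CSV + gene-set text files."""
    from .omics import ExpressionStudy

    expr = pd.read_csv(expr_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path).set_index("sample")
    gene_sets = {}
    for name, p in (gene_set_paths or {}).items():
        gene_sets[name] = [ln.strip() for ln in Path(p).read_text().splitlines()
                           if ln.strip()]
    return ExpressionStudy(expression=expr, metadata=meta, gene_sets=gene_sets)


def element_table(elements: NetworkElements, well_id: str = "well") -> pd.DataFrame:
    """One row per element (tube / node / mesh) with class and measurements."""
    rows = []
    g = elements.graph
    for eid, e in g.edges.items():
        rows.append({"well": well_id, "element": "tube", "id": f"t{eid}",
                     "class": elements.tubes.classes[eid],
                     "master": bool(elements.tubes.master_segment.get(eid, False)),
                     "length_px": e.length,
                     "thickness_px": elements.thickness.get(eid, np.nan)})
    for vid, cls in elements.nodes.classes.items():
        r, c = g.vertices[vid]
        rows.append({"well": well_id, "element": "node", "id": f"n{vid}",
                     "class": cls, "degree": elements.nodes.degrees[vid],
                     "row": r, "col": c})
    for i, m in enumerate(elements.meshes):
        rows.append({"well": well_id, "element": "mesh", "id": f"m{i}",
                     "class": "mesh", "area_px2": m.area,
                     "perimeter_px": m.perimeter})
    return pd.DataFrame(rows)


def edge_list(elements: NetworkElements) -> pd.DataFrame:
    """Graph edges as a CSV-ready table."""
    g = elements.graph
    rows = []
    for eid, e in g.edges.items():
        rows.append({"edge": eid, "vertex_a": e.u, "vertex_b": e.v,
                     "length_px": e.length, "n_pixels": e.n_pixels,
                     "class": elements.tubes.classes[eid]})
    return pd.DataFrame(rows)


def write_overlay_png(image: IntensityImage, elements: NetworkElements,
                      path: str | Path) -> None:
    """Skeleton overlay: image in grey, skeleton in the red channel."""
    import imageio.v3 as iio

    px = image.pixels
    lo, hi = px.min(), px.max()
    norm = ((px - lo) / (hi - lo) * 255).astype(np.uint8) if hi > lo else \
        np.zeros(px.shape, dtype=np.uint8)
    rgb = np.stack([norm, norm, norm], axis=-1)
    for e in elements.graph.edges.values():
        rgb[e.path[:, 0], e.path[:, 1]] = (255, 0, 0)
    iio.imwrite(Path(path), rgb)
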