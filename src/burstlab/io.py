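"""Readers and writers for the file formats the pipeline exchanges.

Images and label masks are TIFF (16-bit for rendered images, integer labels
for masks); tables are CSV; gene lists are one-symbol-per-line text; count
matrices are MatrixMarket (with row/column name sidecars) or dense CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy.io import mmread


def write_image(path, image: np.ndarray, scale_to_uint16: bool = True) -> None:
    """Write an intensity image as TIFF (rescaled to the 16-bit range by default)."""
    img = np.asarray(image)
    if scale_to_uint16:
        lo, hi = float(img.min()), float(img.max())
        scale = 65535.0 / (hi - lo) if hi > lo else 1.0
        img = ((img - lo) * scale).astype(np.uint16)
    tifffile.imwrite(str(path), img)


def read_image(path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(float)


def write_mask(path, mask: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(mask).astype(np.uint16))


def read_mask(path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(np.int32)


def write_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json(path, obj) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")


def read_gene_list(path) -> list[str]:
    """One gene symbol per line; blank lines ignored."""
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def write_gene_list(path, genes) -> None:
    Path(path).write_text("\n".join(str(g) for g in genes) + "\n")


def read_count_matrix(path, genes_path=None, cells_path=None) -> pd.DataFrame:
    """Genes x cells counts from dense CSV (gene index in first column) or MTX.

    For MTX, ``genes_path`` and ``cells_path`` name one-identifier-per-line
    sidecar files for rows and columns.
    """
    path = Path(path)
    if path.suffix.lower() == ".mtx":
        mat = mmread(str(path)).toarray()
        genes = read_gene_list(genes_path) if genes_path else [f"G{i}" for i in range(mat.shape[0])]
        cells = read_gene_list(cells_path) if cells_path else [f"C{j}" for j in range(mat.shape[1])]
        return pd.DataFrame(mat, index=genes, columns=cells)
    return pd.read_csv(path, index_col=0)
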