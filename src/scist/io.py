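"""Readers and writers for the plain-text interchange formats.

Spot tables and metadata travel as TSV (pandas), expression matrices as
matrix-market sparse triplets with ``genes.tsv`` / ``barcodes.tsv`` sidecars
(scipy.io) or as dense TSV, and patches as PNG/TIFF (imageio / tifffile).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

SPOT_COLUMNS = ["spot_id", "section_id", "patient_id", "x", "y", "background"]


def read_spot_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"spot_id": str, "section_id": str,
                                            "patient_id": str})
    missing = [c for c in SPOT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"spot table {path} missing columns: {missing}")
    return df


def write_spot_table(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, columns=SPOT_COLUMNS)


def write_mtx(matrix, genes: list[str], barcodes: list[str], out_dir: str,
              prefix: str = "") -> None:
    """Write a barcodes x genes matrix as MTX plus sidecar gene/barcode lists."""
    os.makedirs(out_dir, exist_ok=True)
    m = sp.csr_matrix(np.asarray(matrix)) if not sp.issparse(matrix) else matrix
    scipy.io.mmwrite(os.path.join(out_dir, prefix + "matrix.mtx"), m)
    pd.Series(genes).to_csv(os.path.join(out_dir, prefix + "genes.tsv"),
                            sep="\t", index=False, header=False)
    pd.Series(barcodes).to_csv(os.path.join(out_dir, prefix + "barcodes.tsv"),
                               sep="\t", index=False, header=False)


def read_mtx(out_dir: str, prefix: str = "") -> tuple[np.ndarray, list[str], list[str]]:
    m = scipy.io.mmread(os.path.join(out_dir, prefix + "matrix.mtx"))
    genes = pd.read_csv(os.path.join(out_dir, prefix + "genes.tsv"),
                        sep="\t", header=None)[0].astype(str).tolist()
    barcodes = pd.read_csv(os.path.join(out_dir, prefix + "barcodes.tsv"),
                           sep="\t", header=None)[0].astype(str).tolist()
    return np.asarray(sp.csr_matrix(m).todense()), genes, barcodes


def read_expression_tsv(path: str) -> tuple[np.ndarray, list[str], list[str]]:
    """Dense TSV: rows = spots/cells (index column), columns = genes."""
    df = pd.read_csv(path, sep="\t", index_col=0,
                     float_precision="round_trip")
    return df.to_numpy(dtype=float), [str(c) for c in df.columns], \
        [str(i) for i in df.index]


def write_expression_tsv(matrix, genes: list[str], row_ids: list[str],
                         path: str) -> None:
    # %.17g round-trips float64 exactly through text
    pd.DataFrame(np.asarray(matrix), index=row_ids, columns=genes) \
        .to_csv(path, sep="\t", float_format="%.17g")


def read_image(path: str) -> np.ndarray:
    """Load a PNG or (pyramidal) TIFF as an RGB uint8 array."""
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile
        img = tifffile.imread(path)
    else:
        import imageio.v3 as iio
        img = iio.imread(path)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    return np.ascontiguousarray(img[..., :3])


def write_image(img: np.ndarray, path: str) -> None:
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile
        tifffile.imwrite(path, img)
    else:
        import imageio.v3 as iio
        iio.imwrite(path, img)


def read_gene_list(path: str) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes: list[str], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(genes) + "\n")
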