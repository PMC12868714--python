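"""Reading and writing the pipeline's on-disk formats.

Matrices travel as MatrixMarket (``matrix.mtx``) with ``features.tsv`` /
``barcodes.tsv`` sidecars (cells x features orientation is preserved via
the sidecar lengths); tables as TSV; run manifests as JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import anndata as ad
import pandas as pd
from scipy import io as scio
from scipy import sparse


def write_matrix_dir(adata: ad.AnnData, outdir: str | Path) -> None:
    """Write an AnnData as matrix.mtx + features.tsv + barcodes.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scio.mmwrite(str(outdir / "matrix.mtx"), sparse.coo_matrix(adata.X))
    adata.var.to_csv(outdir / "features.tsv", sep="\t")
    adata.obs.to_csv(outdir / "barcodes.tsv", sep="\t")


def read_matrix_dir(indir: str | Path) -> ad.AnnData:
    indir = Path(indir)
    X = sparse.csr_matrix(scio.mmread(str(indir / "matrix.mtx")))
    var = pd.read_csv(indir / "features.tsv", sep="\t", index_col=0)
    obs = pd.read_csv(indir / "barcodes.tsv", sep="\t", index_col=0)
    if X.shape != (len(obs), len(var)):
        raise ValueError(
            f"matrix shape {X.shape} does not match sidecars "
            f"({len(obs)} barcodes x {len(var)} features)")
    return ad.AnnData(X=X, obs=obs, var=var)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
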