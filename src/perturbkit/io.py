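"""Readers and writers for the pipeline's file interfaces.

Tabular interchange is TSV (MAGeCK-style count tables, library manifests,
sample metadata, cell annotations); guide-capture matrices are MatrixMarket
(features x cells, 1-based on disk) with barcode/feature sidecars;
localizations are CSV in nm.  Tabular outputs carry a header comment with
the tool version and, when available, the configuration hash.  All readers
reject malformed input with an error naming the offending record.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse
from shapely.geometry import Polygon, box

from . import __version__
from .cropseq import CellGuideCapture
from .screen import SAMPLE_COLUMNS, GuideLibrary, ScreenCounts
from .smlm import LocalizationSet

logger = logging.getLogger("perturbkit.io")


def _write_tsv(df: pd.DataFrame, path: str | Path, config_hash: str | None = None,
               index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        tag = f" config={config_hash}" if config_hash else ""
        fh.write(f"# perturbkit {__version__}{tag}\n")
        df.to_csv(fh, sep="\t", index=index)


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


# ---------------------------------------------------------------------------
# guide library


def write_library(library: GuideLibrary, path: str | Path,
                  config_hash: str | None = None) -> None:
    _write_tsv(library.table, path, config_hash)


def read_library(path: str | Path) -> GuideLibrary:
    df = _read_tsv(path, dtype={"guide_id": str, "gene": str})
    if "is_nontargeting" in df.columns:
        df["is_nontargeting"] = df["is_nontargeting"].astype(bool)
    return GuideLibrary(df)


# ---------------------------------------------------------------------------
# screen counts (MAGeCK-style: sgRNA, gene, then one column per sample)


def write_count_table(counts: ScreenCounts, library: GuideLibrary, path: str | Path,
                      config_hash: str | None = None) -> None:
    gene_of = dict(zip(library.table["guide_id"], library.table["gene"]))
    out = counts.counts.copy()
    out.insert(0, "gene", [gene_of[g] for g in out.index])
    out.insert(0, "sgRNA", out.index)
    _write_tsv(out, path, config_hash)


def write_sample_metadata(counts: ScreenCounts, path: str | Path,
                          config_hash: str | None = None) -> None:
    _write_tsv(counts.samples, path, config_hash)


def read_count_table(counts_path: str | Path, meta_path: str | Path) -> ScreenCounts:
    df = _read_tsv(counts_path)
    if "sgRNA" not in df.columns or "gene" not in df.columns:
        raise ValueError("count table must start with 'sgRNA' and 'gene' columns")
    if df["sgRNA"].duplicated().any():
        dup = df.loc[df["sgRNA"].duplicated(), "sgRNA"].iloc[0]
        raise ValueError(f"duplicate sgRNA row: {dup!r}")
    sample_cols = [c for c in df.columns if c not in ("sgRNA", "gene")]
    mat = df[sample_cols]
    as_float = mat.astype(float)
    if not np.allclose(as_float.to_numpy() % 1, 0):
        bad = [c for c in sample_cols if not np.allclose(as_float[c] % 1, 0)][0]
        raise ValueError(f"non-integer counts in sample column {bad!r}")
    counts = as_float.astype(int)
    counts.index = pd.Index(df["sgRNA"])
    meta = _read_tsv(meta_path, dtype={"sample_id": str})
    missing = set(SAMPLE_COLUMNS) - set(meta.columns)
    if missing:
        raise ValueError(f"sample metadata missing columns: {sorted(missing)}")
    meta["is_t0"] = meta["is_t0"].astype(bool)
    return ScreenCounts(counts, meta)


def library_from_count_table(counts_path: str | Path,
                             nontargeting_gene: str = "non-targeting") -> GuideLibrary:
    """Derive a library from a MAGeCK-style table, flagging guides whose gene
    label equals ``nontargeting_gene`` as controls."""
    df = _read_tsv(counts_path)
    return GuideLibrary(
        pd.DataFrame(
            {
                "guide_id": df["sgRNA"],
                "gene": df["gene"],
                "is_nontargeting": df["gene"] == nontargeting_gene,
            }
        )
    )


# ---------------------------------------------------------------------------
# CROP-seq capture matrix (MTX, features x cells on disk like Cell Ranger)


def write_capture_mtx(capture: CellGuideCapture, mtx_path: str | Path,
                      barcodes_path: str | Path, features_path: str | Path) -> None:
    Path(mtx_path).parent.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(mtx_path), sparse.coo_matrix(capture.umi_counts.T))
    pd.Series(capture.barcodes).to_csv(barcodes_path, index=False, header=False)
    pd.Series(capture.guide_ids).to_csv(features_path, index=False, header=False)


def read_capture_mtx(mtx_path: str | Path, barcodes_path: str | Path,
                     features_path: str | Path) -> CellGuideCapture:
    mat = sparse.csr_matrix(spio.mmread(str(mtx_path)).T)  # -> cells x guides
    barcodes = pd.read_csv(barcodes_path, header=None)[0].astype(str).tolist()
    features = pd.read_csv(features_path, header=None)[0].astype(str).tolist()
    if mat.shape[0] != len(barcodes):
        raise ValueError(
            f"matrix has {mat.shape[0]} cells but barcodes file lists {len(barcodes)}"
        )
    if mat.shape[1] != len(features):
        raise ValueError(
            f"matrix has {mat.shape[1]} guides but features file lists {len(features)}"
        )
    if mat.nnz == 0:
        logger.warning("capture matrix %s is empty", mtx_path)
    return CellGuideCapture(mat, barcodes, features)


def write_cell_annotation(cells: pd.DataFrame, path: str | Path,
                          config_hash: str | None = None) -> None:
    _write_tsv(cells, path, config_hash)


def read_cell_annotation(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, dtype={"cell": str, "sample": str})
    for col in ("cell", "sample", "total_umis", "mito_fraction"):
        if col not in df.columns:
            raise ValueError(f"cell annotation missing column {col!r}")
    return df


# ---------------------------------------------------------------------------
# localizations


def write_localizations(locs: LocalizationSet, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(locs.points, columns=["x_nm", "y_nm"]).to_csv(path, index=False)


_X_ALIASES = ("x_nm", "x [nm]", "x")
_Y_ALIASES = ("y_nm", "y [nm]", "y")


def read_localizations(path: str | Path, roi: Polygon) -> LocalizationSet:
    """Read a localization CSV (ThunderSTORM-style headers tolerated) and
    drop points outside the ROI, logging the count."""
    df = pd.read_csv(path)
    cols = {c.strip().lower(): c for c in df.columns}
    xcol = next((cols[a] for a in _X_ALIASES if a in cols), None)
    ycol = next((cols[a] for a in _Y_ALIASES if a in cols), None)
    if xcol is None:
        raise ValueError("localization file is missing an x coordinate column ('x_nm')")
    if ycol is None:
        raise ValueError("localization file is missing a y coordinate column ('y_nm')")
    pts = df[[xcol, ycol]].to_numpy(dtype=float)
    import shapely

    inside = shapely.covers(roi, shapely.points(pts)) if len(pts) else np.array([], bool)
    n_dropped = int((~inside).sum())
    if n_dropped:
        logger.warning("dropping %d localization(s) outside the ROI", n_dropped)
    return LocalizationSet(pts[inside], roi)


def roi_from_spec(spec: str | Path) -> Polygon:
    """ROI from 'xmin,ymin,xmax,ymax' bounds or a polygon vertex CSV."""
    text = str(spec)
    if "," in text and not Path(text).exists():
        parts = [float(v) for v in text.split(",")]
        if len(parts) != 4:
            raise ValueError("rectangle ROI must be 'xmin,ymin,xmax,ymax'")
        return box(*parts)
    df = pd.read_csv(text)
    if "x_nm" not in df.columns or "y_nm" not in df.columns:
        raise ValueError("ROI vertex file needs 'x_nm' and 'y_nm' columns")
    return Polygon(df[["x_nm", "y_nm"]].to_numpy())


# ---------------------------------------------------------------------------
# truth / JSON


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_json(obj, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_jsonify(obj), fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
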