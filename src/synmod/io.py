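"""File I/O: trajectory panels, protein matrices, images, truth, tables.

Plain-text formats throughout: CSV trajectory panels, TSV abundance and
metadata tables, 16-bit grayscale TIFF (or PNG) images, JSON ground truth.
Output tables carry a header row plus a provenance comment line (tool
version and config hash).
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from . import __version__

PANEL_COLUMNS = ["genotype", "tray", "replicate", "trial", "age_days", "speed"]


class SchemaError(ValueError):
    """Input table violates the expected schema."""


def read_panel(path) -> pd.DataFrame:
    """Read a trajectory panel CSV and validate its schema.

    Required columns: genotype, tray, replicate, age_days, speed (trial is
    optional — absent after technical aggregation). Offending rows are
    reported with their 1-based data row numbers.
    """
    panel = pd.read_csv(path)
    missing = [c for c in PANEL_COLUMNS if c not in panel.columns and c != "trial"]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    bad_speed = panel.index[pd.to_numeric(panel["speed"], errors="coerce").isna()
                            | (pd.to_numeric(panel["speed"], errors="coerce") < 0)]
    if len(bad_speed):
        raise SchemaError(
            f"{path}: non-numeric or negative speed at row(s) {[i + 1 for i in bad_speed[:5]]}"
        )
    bad_age = panel.index[pd.to_numeric(panel["age_days"], errors="coerce").isna()
                          | (pd.to_numeric(panel["age_days"], errors="coerce") <= 0)]
    if len(bad_age):
        raise SchemaError(
            f"{path}: non-positive age_days at row(s) {[i + 1 for i in bad_age[:5]]}"
        )
    return panel


def write_panel(panel: pd.DataFrame, path) -> None:
    panel.to_csv(path, index=False)


def write_table(df: pd.DataFrame, path, config_hash: str = "none") -> None:
    """Write a TSV result table with a provenance comment line."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# synmod {__version__} config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_protein_matrix(matrix: pd.DataFrame, meta: pd.DataFrame, prefix) -> None:
    """Write abundance (TSV, first column protein id) and metadata (TSV)."""
    prefix = Path(prefix)
    matrix.rename_axis("protein").to_csv(prefix.with_suffix(".abundance.tsv"), sep="\t")
    meta.to_csv(prefix.with_suffix(".meta.tsv"), sep="\t", index=False)


def write_image(pixels: np.ndarray, path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, pixels)
    else:
        iio.imwrite(path, pixels)


def read_image(path) -> np.ndarray:
    """Read an 8/16-bit grayscale TIFF or PNG as a 2-D array."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        px = tifffile.imread(path)
    else:
        px = iio.imread(path)
    px = np.asarray(px)
    if px.ndim == 3:  # collapse an accidental channel axis
        px = px[..., 0]
    return px


def write_truth(truth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=1)


def read_homolog_table(path) -> pd.DataFrame:
    """Read a human-to-fly homolog map CSV (human_gene, fly_gene / conserved)."""
    df = pd.read_csv(path)
    if "human_gene" not in df.columns:
        raise SchemaError(f"{path}: needs a 'human_gene' column")
    return df


def read_strain_table(path) -> pd.DataFrame:
    """Read a strain table CSV (strain, gene, type) mapping alleles to genes."""
    df = pd.read_csv(path)
    for col in ("strain", "gene"):
        if col not in df.columns:
            raise SchemaError(f"{path}: needs a {col!r} column")
    return df
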