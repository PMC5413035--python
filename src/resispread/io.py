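"""File formats: genotype CSV dialect, ESRI ASCII grid rasters, matrices.

Genotype CSV dialect (the supplementary-dataset layout): a header row with
columns ``id, x, y`` followed by two integer allele columns per locus named
``<locus>_1, <locus>_2``.  A missing allele is coded ``NA`` or ``0``; both
are accepted on read and normalised to missing (``NA`` is written).

Rasters use the ESRI ASCII grid format (plain text, lossless for values,
cell size, origin and nodata).
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import ConfigurationError, GenotypeTable, MISSING, PairwiseMatrix, RasterGrid

__all__ = [
    "read_genotype_csv",
    "write_genotype_csv",
    "read_ascii_grid",
    "write_ascii_grid",
    "write_pairwise_csv",
    "read_pairwise_csv",
    "load_config",
]


class FormatError(ValueError):
    """Malformed input file."""


def _parse_allele(value, path, row) -> int:
    if pd.isna(value):
        return MISSING
    s = str(value).strip()
    if s.upper() in ("NA", "NAN", ""):
        return MISSING
    try:
        allele = int(float(s))
    except ValueError:
        raise FormatError(f"{path}: row {row}: unparseable allele {value!r}") from None
    return MISSING if allele == 0 else allele


def read_genotype_csv(path) -> GenotypeTable:
    """Read a genotype table in the supplementary-dataset CSV dialect."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = list(df.columns)
    if len(cols) < 5 or cols[0].lower() != "id":
        raise FormatError(f"{path}: expected columns id, x, y, <locus>_1, <locus>_2, ...")
    allele_cols = cols[3:]
    if len(allele_cols) % 2 != 0:
        raise FormatError(f"{path}: odd number of allele columns ({len(allele_cols)})")
    loci: list[str] = []
    for a, b in zip(allele_cols[::2], allele_cols[1::2]):
        ma = re.fullmatch(r"(.+)_1", a)
        mb = re.fullmatch(r"(.+)_2", b)
        if not (ma and mb and ma.group(1) == mb.group(1)):
            raise FormatError(f"{path}: allele columns {a!r}, {b!r} do not pair up")
        loci.append(ma.group(1))

    ids = df[cols[0]].tolist()
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise FormatError(f"{path}: duplicate ids {dupes}")
    try:
        coords = df[cols[1:3]].astype(float).to_numpy()
    except ValueError as e:
        raise FormatError(f"{path}: unparseable coordinates: {e}") from None

    n, n_loci = len(ids), len(loci)
    genotypes = np.empty((n, n_loci, 2), dtype=np.int64)
    for l in range(n_loci):
        for slot in range(2):
            col = df[allele_cols[2 * l + slot]]
            for i in range(n):
                genotypes[i, l, slot] = _parse_allele(col.iloc[i], path, i + 2)
    return GenotypeTable(ids=ids, coordinates=coords, genotypes=genotypes, locus_names=loci)


def write_genotype_csv(table: GenotypeTable, path) -> None:
    data: dict = {"id": table.ids, "x": table.coordinates[:, 0], "y": table.coordinates[:, 1]}
    for l, name in enumerate(table.locus_names):
        for slot in (0, 1):
            col = table.genotypes[:, l, slot]
            data[f"{name}_{slot + 1}"] = ["NA" if a == MISSING else int(a) for a in col]
    pd.DataFrame(data).to_csv(path, index=False)


_ASCII_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


def read_ascii_grid(path) -> RasterGrid:
    """Read an ESRI ASCII grid (row 0 on disk = top row)."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in _ASCII_HEADER_KEYS:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise FormatError(f"{path}: missing header field {key}")
    nodata = header.get("nodata_value", -9999.0)
    try:
        values = np.loadtxt(lines[i:], ndmin=2)
    except ValueError as e:
        raise FormatError(f"{path}: unparseable grid body: {e}") from None
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise FormatError(
            f"{path}: body shape {values.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    return RasterGrid(
        values,
        cell_size=header["cellsize"],
        origin=(header["xllcorner"], header["yllcorner"]),
        nodata=nodata,
    )


def write_ascii_grid(grid: RasterGrid, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {float(grid.origin[0])!r}\n")
        fh.write(f"yllcorner {float(grid.origin[1])!r}\n")
        fh.write(f"cellsize {float(grid.cell_size)!r}\n")
        fh.write(f"NODATA_value {float(grid.nodata)!r}\n")
        for row in grid.values:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def write_pairwise_csv(matrix: PairwiseMatrix, path) -> None:
    """Square CSV with an id header row and column."""
    df = pd.DataFrame(matrix.values, index=matrix.ids, columns=matrix.ids)
    df.to_csv(path, index_label="id")


def read_pairwise_csv(path, metric_kind: str) -> PairwiseMatrix:
    df = pd.read_csv(path, index_col=0)
    return PairwiseMatrix(ids=list(df.columns), values=df.to_numpy(), metric_kind=metric_kind)


def load_config(path) -> dict:
    """Load and minimally validate a YAML run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    return cfg
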