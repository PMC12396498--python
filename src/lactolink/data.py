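"""Containers and I/O for annotated single-cell counts, HMO panels, and gene sets.

The annotated cell matrix is a validated :class:`anndata.AnnData` (cells x
genes, raw integer counts in ``.X``) whose ``.obs`` carries the per-cell
annotations every downstream stage needs: the biological sample, the donor,
the source study, the assigned cell type, and the time postpartum of the
sample. The HMO panel is a plain DataFrame keyed by sample with one
concentration column per oligosaccharide (nmol/mL) plus the type-I/type-II
aggregate columns. Gene-set libraries use the GMT convention.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite


class FormatError(ValueError):
    """A file's structure contradicts its declared format."""


class SchemaError(ValueError):
    """Required columns/identifiers are missing, duplicated, or inconsistent."""


#: obs columns every annotated cell matrix must carry
REQUIRED_CELL_META = (
    "sample_id",
    "donor_id",
    "study_id",
    "cell_type",
    "time_postpartum_days",
)

#: canonical milk-derived cell-type labels (not enforced as a closed set)
CANONICAL_CELL_TYPES = ("LC1", "LC2", "cycling-epithelial", "myeloid", "lymphoid", "other")

#: the 19 HMOs quantified by HPLC-FL, in nmol/mL
HMO_NAMES = (
    "2'FL", "3FL", "3'SL", "6'SL", "DFLac", "DFLNH", "DFLNT", "DSLNH",
    "DSLNT", "FDSLNH", "FLNH", "LNFPI", "LNFPII", "LNFPIII", "LNH", "LNT",
    "LNnT", "LSTb", "LSTc",
)

#: type-I HMOs carry galactose beta1-3-linked to GlcNAc (LNT core)
TYPE_I_HMOS = ("LNT", "LNFPI", "LNFPII", "LSTb", "DSLNT")
#: type-II HMOs carry galactose beta1-4-linked to GlcNAc (LNnT core)
TYPE_II_HMOS = ("LNnT", "LNFPIII", "LSTc")

HMO_PANEL_META = ("donor_id", "time_postpartum_days", "secretor")
HMO_AGGREGATES = ("typeI_total", "typeII_total")


# ---------------------------------------------------------------------------
# annotated cell matrix


def validate_cell_data(adata: ad.AnnData) -> ad.AnnData:
    """Validate an AnnData as an annotated cell matrix; returns it unchanged.

    Raises :class:`SchemaError` on metadata problems and :class:`ValueError`
    on count problems.
    """
    for col in REQUIRED_CELL_META:
        if col not in adata.obs.columns:
            raise SchemaError(f"missing required cell metadata column {col!r}")
    if adata.var_names.duplicated().any():
        dup = adata.var_names[adata.var_names.duplicated()][0]
        raise SchemaError(f"duplicate gene symbol {dup!r}")
    if adata.obs_names.duplicated().any():
        raise SchemaError("duplicate cell identifiers")

    X = adata.X
    data = X.data if sp.issparse(X) else np.asarray(X)
    if data.size and (np.min(data) < 0 or np.any(data != np.round(data))):
        raise ValueError("counts must be non-negative integers")

    for col in ("sample_id", "donor_id", "study_id", "cell_type"):
        if adata.obs[col].isna().any() or (adata.obs[col].astype(str) == "").any():
            raise SchemaError(f"cell metadata column {col!r} has missing values")
    # each sample belongs to exactly one donor and one study
    per_sample = adata.obs.groupby("sample_id", observed=True)[["donor_id", "study_id"]].nunique()
    bad = per_sample[(per_sample > 1).any(axis=1)]
    if len(bad):
        raise SchemaError(
            f"samples mapped to multiple donors/studies: {list(bad.index[:5])}"
        )
    t = pd.to_numeric(adata.obs["time_postpartum_days"], errors="coerce")
    if (t.dropna() < 0).any():
        raise ValueError("time_postpartum_days must be non-negative where present")
    return adata


def load_cell_data(matrix_path, genes_path, cells_meta_path) -> ad.AnnData:
    """Load a cells x genes Matrix Market file with TSV sidecars.

    ``genes_path`` needs a ``gene_id`` column; ``cells_meta_path`` needs
    ``cell_id`` plus the required annotation columns. Row/column counts in
    the MTX header must match the sidecar lengths exactly.
    """
    counts = mmread(str(matrix_path))
    genes = pd.read_csv(genes_path, sep="\t", dtype=str)
    cells = pd.read_csv(cells_meta_path, sep="\t")

    if "gene_id" not in genes.columns:
        raise SchemaError("gene sidecar must have a 'gene_id' column")
    if "cell_id" not in cells.columns:
        raise SchemaError("cell sidecar must have a 'cell_id' column")
    for col in REQUIRED_CELL_META:
        if col not in cells.columns:
            raise SchemaError(f"cell sidecar missing column {col!r}")

    n_cells, n_genes = counts.shape
    if n_cells != len(cells):
        raise FormatError(
            f"matrix declares {n_cells} cells but cell sidecar has {len(cells)} rows"
        )
    if n_genes != len(genes):
        raise FormatError(
            f"matrix declares {n_genes} genes but gene sidecar has {len(genes)} rows"
        )

    obs = cells.set_index("cell_id")
    obs.index = obs.index.astype(str)
    obs["time_postpartum_days"] = pd.to_numeric(
        obs["time_postpartum_days"], errors="coerce"
    )
    var = genes.set_index("gene_id")
    var.index = var.index.astype(str)
    X = sp.csr_matrix(counts)
    adata = ad.AnnData(X=X, obs=obs, var=var)
    return validate_cell_data(adata)


def write_cell_data(adata: ad.AnnData, out_dir) -> dict[str, Path]:
    """Write an annotated cell matrix as MTX + TSV sidecars; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "matrix.mtx",
        "genes": out / "genes.tsv",
        "cells": out / "cells.tsv",
    }
    X = adata.X if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    mmwrite(str(paths["matrix"]), sp.coo_matrix(X))
    pd.DataFrame({"gene_id": adata.var_names}).to_csv(paths["genes"], sep="\t", index=False)
    cells = adata.obs.reset_index(names="cell_id")
    cells.to_csv(paths["cells"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# HMO panel


def validate_hmo_panel(panel: pd.DataFrame, hmo_columns=None) -> pd.DataFrame:
    """Validate an HMO concentration table indexed by sample_id.

    Concentrations must be non-negative; each aggregate column present must
    equal the sum of its declared member HMOs to within 1e-9.
    """
    if panel.index.duplicated().any():
        raise SchemaError("duplicate sample_id in HMO panel")
    if "donor_id" not in panel.columns:
        raise SchemaError("HMO panel requires a donor_id column")
    if hmo_columns is None:
        skip = set(HMO_PANEL_META) | set(HMO_AGGREGATES)
        hmo_columns = [c for c in panel.columns if c not in skip]
    conc = panel[list(hmo_columns)].apply(pd.to_numeric)
    if (conc.to_numpy() < 0).any():
        raise ValueError("HMO concentrations must be non-negative")
    for agg, members in (("typeI_total", TYPE_I_HMOS), ("typeII_total", TYPE_II_HMOS)):
        if agg in panel.columns:
            present = [m for m in members if m in panel.columns]
            expected = panel[present].sum(axis=1)
            if not np.allclose(panel[agg], expected, rtol=0, atol=1e-9):
                raise ValueError(f"{agg} does not equal the sum of its member HMOs")
    return panel


def load_hmo_panel(csv_path) -> pd.DataFrame:
    """Load an HMO panel CSV with a sample_id column as the index."""
    panel = pd.read_csv(csv_path)
    if "sample_id" not in panel.columns:
        raise SchemaError("HMO panel CSV requires a sample_id column")
    panel = panel.set_index("sample_id")
    return validate_hmo_panel(panel)


def hmo_columns(panel: pd.DataFrame) -> list[str]:
    """Names of the individual HMO concentration columns in a panel."""
    skip = set(HMO_PANEL_META) | set(HMO_AGGREGATES)
    return [c for c in panel.columns if c not in skip]


# ---------------------------------------------------------------------------
# gene-set libraries


@dataclasses.dataclass
class GeneSetLibrary:
    """A named collection of gene sets (GMT convention).

    For transcription-factor libraries the set name begins with the TF
    symbol; multiple sets per TF are distinguished by a suffix after the
    first separator (space or underscore).
    """

    name: str
    sets: dict[str, list[str]]

    def __post_init__(self):
        for set_name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {set_name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {set_name!r} has duplicate genes")

    def __len__(self) -> int:
        return len(self.sets)


def load_gmt(path, name: str | None = None) -> GeneSetLibrary:
    """Read a GMT file: one set per line, tab-separated name/description/genes."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"GMT line with fewer than 3 fields: {fields[0]!r}")
            sets[fields[0]] = [g for g in fields[2:] if g]
    return GeneSetLibrary(name=name or Path(path).stem, sets=sets)


def write_gmt(library: GeneSetLibrary, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for set_name, genes in library.sets.items():
            fh.write("\t".join([set_name, library.name, *genes]) + "\n")
    return path
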