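"""Marker-expression quantification.

Three data sources, one question — which cells co-express spatial markers
(Stard5, Peg10) with the projection-neuron receptors Drd1a/Drd2:

* single-cell RNA-seq count matrices: filter genes/cells, call a cell
  marker-positive at a single transcript copy, report co-expression
  fractions;
* FISH cell tables: per-region, per-axis proportions of Drd1+/Drd2+ cells
  that carry a probe, averaged section -> animal -> group;
* in-situ optical density: background-subtracted mean intensity of fixed
  100x100 px squares, averaged over hemispheres.
"""

from __future__ import annotations

import difflib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "GeneCellMatrix",
    "PositivityCall",
    "ODMeasurement",
    "filter_matrix",
    "positive_cells",
    "coexpression_fraction",
    "fish_proportions",
    "optical_density",
    "normalize_log_cpm",
]

ROI_VOCAB = ("medNAcSh_dorsal", "medNAcSh_ventral", "core", "latNAcSh")
AXIS_VOCAB = ("rostral", "caudal")


@dataclass
class GeneCellMatrix:
    """Sparse genes x cells matrix of non-negative integer counts."""

    counts: sparse.spmatrix
    gene_names: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.counts = sparse.csr_matrix(self.counts)
        self.gene_names = np.asarray(self.gene_names, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.counts.shape != (self.gene_names.size, self.cell_ids.size):
            raise ValueError("GeneCellMatrix: counts shape must be (n_genes, n_cells)")
        if len(set(self.gene_names)) != self.gene_names.size:
            raise ValueError("GeneCellMatrix: duplicate gene names")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("GeneCellMatrix: counts must be non-negative")

    @property
    def shape(self) -> tuple:
        return self.counts.shape

    def gene_index(self, marker: str) -> int:
        idx = np.flatnonzero(self.gene_names == marker)
        if idx.size == 0:
            near = difflib.get_close_matches(marker, [str(g) for g in self.gene_names], n=3)
            raise KeyError(f"gene {marker!r} not in matrix; near matches: {near}")
        return int(idx[0])


@dataclass
class PositivityCall:
    """Cells carrying at least one transcript copy of a marker."""

    marker: str
    positive_cells: set = field(default_factory=set)


def filter_matrix(m: GeneCellMatrix, min_cells: int = 3, min_features: int = 1250) -> GeneCellMatrix:
    """Retain genes detected in >= min_cells cells and cells with
    >= min_features detected genes.

    Both criteria are evaluated on the input matrix in a single pass (no
    iteration), mirroring Seurat's CreateSeuratObject min.cells/min.features
    behavior.
    """
    binary = (m.counts > 0)
    gene_keep = np.asarray(binary.sum(axis=1)).ravel() >= min_cells
    cell_keep = np.asarray(binary.sum(axis=0)).ravel() >= min_features
    if not gene_keep.any() or not cell_keep.any():
        raise ValueError("filter_matrix: no genes or no cells survive the thresholds")
    return GeneCellMatrix(
        counts=m.counts[gene_keep][:, cell_keep],
        gene_names=m.gene_names[gene_keep],
        cell_ids=m.cell_ids[cell_keep],
    )


def positive_cells(m: GeneCellMatrix, marker: str) -> PositivityCall:
    """Cells with count >= 1 for the marker (single-copy positivity)."""
    row = m.counts[m.gene_index(marker)]
    pos = np.asarray((row > 0).todense()).ravel()
    return PositivityCall(marker=marker, positive_cells=set(m.cell_ids[pos]))


def coexpression_fraction(m: GeneCellMatrix, marker_a: str, marker_b: str,
                          denominator: str = "b") -> float:
    """Percentage of denominator-marker-positive cells positive for both.

    ``denominator='b'`` reports 100 * |A+ and B+| / |B+| (e.g. the fraction
    of Drd1a+ cells that are Stard5+ when a=Stard5, b=Drd1a); 'a' swaps the
    orientation.
    """
    a = positive_cells(m, marker_a).positive_cells
    b = positive_cells(m, marker_b).positive_cells
    denom = {"a": a, "b": b}.get(denominator)
    if denom is None:
        raise ValueError("coexpression_fraction: denominator must be 'a' or 'b'")
    if not denom:
        name = marker_a if denominator == "a" else marker_b
        raise ValueError(f"coexpression_fraction: empty denominator set (marker {name!r})")
    return 100.0 * len(a & b) / len(denom)


def normalize_log_cpm(m: GeneCellMatrix, scale: float = 1e6) -> sparse.csr_matrix:
    """Optional log-normalization, ln(1 + count/depth * scale).

    Positivity calls use raw counts (normalization preserves the zero
    pattern); this transform is provided only for downstream exploration.
    """
    depth = np.asarray(m.counts.sum(axis=0)).ravel().astype(float)
    if np.any(depth == 0):
        raise ValueError("normalize_log_cpm: cells with zero total counts")
    x = m.counts.tocsc(copy=True).astype(float)
    x.data = x.data * (scale / depth.repeat(np.diff(x.indptr)))
    x.data = np.log1p(x.data)
    return x.tocsr()


_REQ_FISH_COLS = {"animal_id", "section_id", "roi", "axis_position",
                  "drd1_pos", "drd2_pos", "probe_pos"}


def fish_proportions(table: pd.DataFrame, group_by=("roi", "axis_position")) -> pd.DataFrame:
    """Per-group % of Drd1+ (and Drd2+) cells that are probe+.

    Per section: 100 * |receptor+ and probe+| / |receptor+|. Section values
    are averaged within animal, then across animals. A section with zero
    receptor-positive cells contributes NaN (flagged undefined) and is
    ignored by the averaging.
    """
    missing = _REQ_FISH_COLS - set(table.columns)
    if missing:
        raise ValueError(f"fish_proportions: missing columns {sorted(missing)}")
    bad_roi = set(table["roi"].unique()) - set(ROI_VOCAB)
    if bad_roi:
        raise ValueError(f"fish_proportions: unknown ROI values {sorted(bad_roi)}")
    group_by = list(group_by)

    def _section_pct(sub: pd.DataFrame) -> pd.Series:
        out = {}
        for rec in ("drd1", "drd2"):
            pos = sub[sub[f"{rec}_pos"]]
            out[f"pct_{rec}_probe"] = (100.0 * pos["probe_pos"].mean()) if len(pos) else np.nan
        return pd.Series(out)

    per_section = (table.groupby(group_by + ["animal_id", "section_id"], observed=True)
                   .apply(_section_pct, include_groups=False))
    per_animal = per_section.groupby(group_by + ["animal_id"], observed=True).mean()
    per_group = per_animal.groupby(group_by, observed=True).mean()
    per_group["n_animals"] = per_animal.groupby(group_by, observed=True).size()
    return per_group


@dataclass
class ODMeasurement:
    """Background-corrected optical density of one ROI (both hemispheres)."""

    roi: str
    section_bregma_mm: float
    hemisphere_values: tuple
    od_background: float
    od_corrected: float
    single_hemisphere: bool = False


def optical_density(roi: str, hemisphere_means, background_mean: float,
                    section_bregma_mm: float = float("nan")) -> ODMeasurement:
    """OD = mean over hemispheres of (ROI square mean - background mean).

    The background square sits in the anterior commissure of the same
    section. Negative corrected values are preserved (no clipping). With a
    single hemisphere available the value is reported with a warning flag.
    """
    vals = [float(v) for v in np.atleast_1d(hemisphere_means) if np.isfinite(v)]
    if not vals or not np.isfinite(background_mean):
        raise ValueError("optical_density: need at least one finite hemisphere value "
                         "and a finite background")
    corrected = [v - background_mean for v in vals]
    single = len(vals) == 1
    if single:
        warnings.warn(f"optical_density: single hemisphere for ROI {roi!r}")
    return ODMeasurement(
        roi=roi,
        section_bregma_mm=section_bregma_mm,
        hemisphere_values=tuple(vals),
        od_background=float(background_mean),
        od_corrected=float(np.mean(corrected)),
        single_hemisphere=single,
    )
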