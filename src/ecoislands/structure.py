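"""Vegetation-structure ordination.

Twelve plot-level structure variables (laser-scan complexity indices,
canopy covers, stand densities, ground covers) are z-standardized and
reduced by PCA to two orthogonal axes: PC1 is read as a structural
complexity gradient (anchored so the stand structural complexity index,
SSCI, loads positively) and PC2 as tree dominance (anchored so tree cover
loads positively).  These axes serve as mediators in the path analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Canonical structure-variable names, in panel order.
STRUCTURE_VARIABLES: tuple[str, ...] = (
    "ssci",
    "mean_frac",
    "enl",
    "understory_complexity",
    "canopy_gap_fraction",
    "oil_palm_cover",
    "tree_cover",
    "oil_palm_density",
    "tree_density",
    "understorey_cover",
    "litter_cover",
    "litter_depth",
)

#: Loading anchors fixing the (otherwise arbitrary) PCA signs.
_PC1_ANCHOR = "ssci"
_PC2_ANCHOR = "tree_cover"


class DegenerateStructureError(ValueError):
    """Raised when a structure variable is constant across plots."""


@dataclass(frozen=True)
class StructureAxes:
    """First two principal components of the structure panel."""

    scores: pd.DataFrame  # plot × {pc1, pc2}
    loadings: pd.DataFrame  # variable × {pc1, pc2}, unit-norm columns
    variance_explained: tuple[float, float]
    imputed_plots: tuple[str, ...] = ()


def structure_pca(table: pd.DataFrame) -> StructureAxes:
    """PCA of the z-scored structure table.

    Plots with missing values are column-mean imputed (and flagged) so the
    full plot panel keeps one score per plot.  Raises
    :class:`DegenerateStructureError` for a constant column, naming it.
    """
    if table.shape[0] < 3:
        raise ValueError("need at least 3 plots for a structure ordination")
    x = table.astype(float).copy()
    imputed = tuple(x.index[x.isna().any(axis=1)].astype(str))
    x = x.fillna(x.mean(axis=0))
    sd = x.std(axis=0, ddof=1)
    constant = sd.index[(sd == 0) | ~np.isfinite(sd)]
    if len(constant):
        raise DegenerateStructureError(
            f"constant structure variable(s): {list(constant)}"
        )
    z = (x - x.mean(axis=0)) / sd

    corr = np.corrcoef(z.to_numpy(), rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    load = eigvec[:, :2].copy()
    cols = list(table.columns)
    for axis, anchor in enumerate((_PC1_ANCHOR, _PC2_ANCHOR)):
        if anchor in cols and load[cols.index(anchor), axis] < 0:
            load[:, axis] *= -1.0
    scores = z.to_numpy() @ load
    total = eigval.sum()
    return StructureAxes(
        scores=pd.DataFrame(scores, index=table.index, columns=["pc1", "pc2"]),
        loadings=pd.DataFrame(load, index=cols, columns=["pc1", "pc2"]),
        variance_explained=(float(eigval[0] / total), float(eigval[1] / total)),
        imputed_plots=imputed,
    )
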