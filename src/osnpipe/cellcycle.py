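"""PC1-sign cell-cycle stage classifier.

Expression of a cell-cycle gene list is calibrated against a labelled
reference (G1 vs S/G2-M): log10(x + 1)-transformed reference profiles
are centered on the reference gene means and the first principal axis is
computed; its sign is oriented so G1 reference samples project negative.
A test sample is then allocated to G1 iff its projection on that axis is
negative (a projection of exactly 0 falls on the S/G2-M side; this
boundary convention is configurable).  Neuronal samples, being
postmitotic, are expected to land in G1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .exceptions import ConfigurationError

G1_LABEL = "G1"
S_LABEL = "S/G2-M"


@dataclass
class CellCycleModel:
    """Trained PC1-sign classifier.

    Attributes
    ----------
    genes : list of model gene ids (reference order)
    center : per-gene reference means on the log10(x+1) scale
    loadings : unit-norm first principal axis, oriented so G1 is negative
    separation : |gap between label mean projections| / pooled SD
    """

    genes: list
    center: np.ndarray
    loadings: np.ndarray
    separation: float
    g1_label: str = G1_LABEL
    s_label: str = S_LABEL
    boundary_stage: str = S_LABEL  # stage assigned at projection exactly 0

    def project(self, matrix: pd.DataFrame, min_overlap: int = 10) -> pd.Series:
        """Project samples (columns) onto the cell-cycle axis.

        Model genes absent from the matrix are dropped (at least
        ``min_overlap`` must remain); extra genes are ignored.
        """
        present = [g for g in self.genes if g in matrix.index]
        if len(present) < min_overlap:
            raise ConfigurationError(
                f"only {len(present)} model genes overlap the matrix (need {min_overlap})"
            )
        idx = [self.genes.index(g) for g in present]
        logx = np.log10(matrix.loc[present].to_numpy(dtype=float) + 1.0)
        centered = logx - self.center[idx][:, None]
        proj = self.loadings[idx] @ centered
        return pd.Series(proj, index=matrix.columns, name="projection")

    def classify(self, matrix: pd.DataFrame, min_overlap: int = 10) -> pd.DataFrame:
        """Stage per sample: G1 iff projection < 0."""
        proj = self.project(matrix, min_overlap)
        stage = np.where(proj < 0, self.g1_label, self.s_label)
        if self.boundary_stage == self.g1_label:
            stage = np.where(proj <= 0, self.g1_label, self.s_label)
        return pd.DataFrame({"projection": proj, "stage": stage}, index=matrix.columns)


def train_cellcycle(
    reference: pd.DataFrame,
    labels: pd.Series,
    gene_list,
    g1_label: str = G1_LABEL,
    min_overlap: int = 10,
) -> CellCycleModel:
    """Calibrate the PC1-sign classifier on a labelled reference.

    ``reference`` is genes x samples (normalized counts), ``labels`` maps
    every reference sample to one of exactly two stage labels, one of
    which is ``g1_label``.
    """
    labels = labels.reindex(reference.columns)
    if labels.isna().any():
        raise ConfigurationError("labels missing for some reference samples")
    uniq = sorted(set(labels))
    if len(uniq) != 2 or g1_label not in uniq:
        raise ConfigurationError(
            f"need exactly two labels including {g1_label!r}; got {uniq}"
        )
    s_label = next(l for l in uniq if l != g1_label)
    if (labels == g1_label).sum() < 2 or (labels == s_label).sum() < 2:
        raise ConfigurationError("need at least 2 reference samples per label")
    genes = [g for g in gene_list if g in reference.index]
    if len(genes) < min_overlap:
        raise ConfigurationError(
            f"cell-cycle gene list shares only {len(genes)} genes with the reference"
        )
    logx = np.log10(reference.loc[genes].to_numpy(dtype=float) + 1.0)
    center = logx.mean(axis=1)
    centered = (logx - center[:, None]).T  # samples x genes
    if np.allclose(centered.std(axis=0).sum(), 0):
        raise ConfigurationError("reference has no variance over the cell-cycle genes")
    pca = PCA(n_components=1, svd_solver="full")
    scores = pca.fit_transform(centered).ravel()
    loadings = pca.components_[0]
    loadings = loadings / np.linalg.norm(loadings)
    g1 = labels.to_numpy() == g1_label
    if scores[g1].mean() > 0:
        loadings, scores = -loadings, -scores
    gap = scores[~g1].mean() - scores[g1].mean()
    pooled = np.sqrt(0.5 * (scores[g1].var(ddof=1) + scores[~g1].var(ddof=1)))
    separation = float(abs(gap) / max(pooled, 1e-12))
    if separation < 2.0:
        warnings.warn(
            f"cell-cycle reference separation {separation:.2f} < 2: "
            "stage calls will be low-confidence",
            stacklevel=2,
        )
    return CellCycleModel(
        genes=genes,
        center=center,
        loadings=loadings,
        separation=separation,
        g1_label=g1_label,
        s_label=s_label,
    )


def classify_cellcycle(
    model: CellCycleModel, matrix: pd.DataFrame, min_overlap: int = 10
) -> pd.DataFrame:
    """Functional wrapper over :meth:`CellCycleModel.classify`."""
    return model.classify(matrix, min_overlap)
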