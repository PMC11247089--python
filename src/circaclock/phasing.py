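"""PCA-based circular phase assignment for snapshot transcriptomes.

For an intact clock the expression of a phase-sorted circadian gene list
traces a closed cycle in gene-expression space; the first two principal
components of the (per-gene standardised) list expression recover that cycle
as a circle, and the quadrant-aware angle of each sample's (PC1, PC2) score
is its circadian phase up to an unknown rotation and reflection.  The
orientation step fixes both, either against recorded times (validation) or
against the canonical clock geometry (the PER3-role gene anchored to a fixed
peak hour, reflection chosen so the RORC-role gene peaks ~6 h after it).
Phases of paired snapshot samples can then be transferred from normal tissue
to tumor partners.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from circaclock.rhythmfit import HarmonicFit, fit_harmonic, wrap_phase_diff

logger = logging.getLogger(__name__)

#: explained-variance floor below which a PCA assignment is flagged weak
WEAK_CLOCK_EV_THRESHOLD = 0.5

_H_PER_RAD = 24.0 / (2.0 * np.pi)


def _wrap24(phi):
    # tiny negative inputs can round `x % 24.0` up to exactly 24.0
    w = phi % 24.0
    if isinstance(w, pd.Series):
        return w.mask(w >= 24.0, 0.0)
    return np.where(w >= 24.0, 0.0, w)


def _angle_to_hours(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    return _wrap24(np.arctan2(y, x) * _H_PER_RAD)


@dataclass
class PhaseAssignment:
    """Per-sample circadian phase in [0, 24) h with provenance.

    ``method`` records how the phase was obtained: ``pca`` (circular PCA
    reconstruction), ``proxy`` (quadrature gene-pair angle) or
    ``transferred`` (copied from a paired sample).  ``reflected`` and
    ``offset_h`` describe the orientation applied on top of the raw PCA
    angle; ``weak`` flags assignments whose first two components explain
    too little variance to trust the circle.
    """

    phi_h: pd.Series
    pc1: pd.Series | None = None
    pc2: pd.Series | None = None
    explained_variance_1: float | None = None
    explained_variance_2: float | None = None
    reflected: bool = False
    offset_h: float = 0.0
    method: str = "pca"
    gene_list_used: list[str] = field(default_factory=list)
    weak: bool = False

    @property
    def samples(self) -> list[str]:
        return list(self.phi_h.index)

    def with_orientation(self, reflected: bool, offset_h: float) -> "PhaseAssignment":
        phi = self.phi_h.copy()
        if reflected:
            phi = _wrap24(-phi)
        phi = _wrap24(phi + offset_h)
        return replace(self, phi_h=phi,
                       reflected=self.reflected ^ reflected,
                       offset_h=(self.offset_h + offset_h) % 24.0)

    def write(self, path) -> None:
        df = pd.DataFrame({"phi_h": self.phi_h})
        if self.pc1 is not None:
            df["pc1"] = self.pc1
            df["pc2"] = self.pc2
        df["method"] = self.method
        df["reflected"] = self.reflected
        df["offset_h"] = self.offset_h
        df.index.name = "sample"
        df.to_csv(path, sep="\t", float_format="%.12g")

    @classmethod
    def read(cls, path) -> "PhaseAssignment":
        df = pd.read_csv(path, sep="\t", index_col="sample")
        return cls(
            phi_h=df["phi_h"],
            pc1=df["pc1"] if "pc1" in df else None,
            pc2=df["pc2"] if "pc2" in df else None,
            method=str(df["method"].iloc[0]) if "method" in df else "pca",
            reflected=bool(df["reflected"].iloc[0]) if "reflected" in df else False,
            offset_h=float(df["offset_h"].iloc[0]) if "offset_h" in df else 0.0,
        )


class CircadianPhasePCA(TransformerMixin, BaseEstimator):
    """Circular phase reconstruction from snapshot expression, sklearn style.

    Fit on a samples-by-genes frame restricted (by ``gene_list``) to
    circadian genes.  Each gene is centred and scaled to unit variance
    across samples, then a two-component PCA is computed on samples;
    ``transform`` returns the (PC1, PC2) scores and ``predict`` the
    quadrant-aware angle mapped to hours in [0, 24).

    Parameters
    ----------
    gene_list : sequence of str, optional
        Genes to use; default = all columns of X.
    shuffle_seed : int
        Seed for shuffling the sample order before the decomposition.  PCA
        is order-free, so any seed yields identical phases; the option
        exists to make that invariance checkable.
    weak_threshold : float
        Explained-variance floor (PC1+PC2) below which the assignment is
        flagged weak.
    """

    def __init__(self, gene_list=None, shuffle_seed: int = 0,
                 weak_threshold: float = WEAK_CLOCK_EV_THRESHOLD):
        self.gene_list = gene_list
        self.shuffle_seed = shuffle_seed
        self.weak_threshold = weak_threshold

    def _usable_genes(self, X: pd.DataFrame) -> list[str]:
        genes = list(self.gene_list) if self.gene_list is not None else list(X.columns)
        present = [g for g in genes if g in X.columns]
        usable = []
        for g in present:
            if X[g].std(ddof=0) == 0.0:
                logger.warning("dropping zero-variance list gene %s", g)
            else:
                usable.append(g)
        if len(usable) < 3:
            raise ValueError(f"need >= 3 usable list genes, got {usable}")
        return usable

    def fit(self, X: pd.DataFrame, y=None):
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a samples-by-genes DataFrame")
        if X.shape[0] < 4:
            raise ValueError("need >= 4 samples")
        self.genes_ = self._usable_genes(X)
        sub = X.loc[:, self.genes_].astype(float)
        self.mean_ = sub.mean(axis=0)
        self.scale_ = sub.std(axis=0, ddof=0)
        z = (sub - self.mean_) / self.scale_

        # sample order is irrelevant to PCA; shuffling documents that fact
        order = np.random.default_rng(self.shuffle_seed).permutation(len(z))
        pca = PCA(n_components=2, svd_solver="full")
        pca.fit(z.to_numpy()[order])
        self.pca_ = pca
        ev = pca.explained_variance_ratio_
        self.explained_variance_ratio_ = ev
        self.weak_ = bool(ev[:2].sum() < self.weak_threshold)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        z = (X.loc[:, self.genes_].astype(float) - self.mean_) / self.scale_
        return self.pca_.transform(z.to_numpy())

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        scores = self.transform(X)
        return _angle_to_hours(scores[:, 1], scores[:, 0])


def pca_phase(matrix, gene_list, shuffle_seed: int = 0) -> PhaseAssignment:
    """Assign raw (unoriented) circadian phases to all samples of a matrix.

    The phase is the quadrant-aware angle of each sample's (PC1, PC2) score
    mapped from [-pi, pi] to [0, 24) h; orientation (rotation/reflection to
    real clock time) is a separate step, see :func:`orient_phase`.
    """
    if hasattr(gene_list, "genes") and not isinstance(gene_list, (list, tuple)):
        genes = list(gene_list.genes)
    elif isinstance(gene_list, (set, frozenset)):
        genes = sorted(gene_list)
    else:
        genes = list(gene_list)
    X = matrix.values.T  # samples x genes
    est = CircadianPhasePCA(gene_list=genes, shuffle_seed=shuffle_seed).fit(X)
    scores = est.transform(X)
    if est.weak_:
        logger.warning(
            "weak circadian signal: PC1+PC2 explain %.2f of variance (< %.2f)",
            est.explained_variance_ratio_[:2].sum(), est.weak_threshold,
        )
    return PhaseAssignment(
        phi_h=pd.Series(_angle_to_hours(scores[:, 1], scores[:, 0]), index=X.index),
        pc1=pd.Series(scores[:, 0], index=X.index),
        pc2=pd.Series(scores[:, 1], index=X.index),
        explained_variance_1=float(est.explained_variance_ratio_[0]),
        explained_variance_2=float(est.explained_variance_ratio_[1]),
        method="pca",
        gene_list_used=est.genes_,
        weak=est.weak_,
    )


def _median_abs_circular_error(phi: np.ndarray, target: np.ndarray) -> float:
    diff = (phi - target + 12.0) % 24.0 - 12.0
    return float(np.median(np.abs(diff)))


def orient_phase(assignment: PhaseAssignment, matrix=None, mode: str = "anchored",
                 recorded_times: pd.Series | None = None,
                 ref_gene: str = "PER3", quad_gene: str = "RORC",
                 anchor_peak_h: float = 12.0) -> PhaseAssignment:
    """Fix the reflection and rotation of a raw PCA phase assignment.

    ``supervised`` mode (validation only) picks reflection and offset to
    minimise the median absolute circular error against recorded collection
    times.  ``anchored`` mode needs no times: the offset places the
    harmonic-fit peak of the PER3-role gene at ``anchor_peak_h``, and the
    reflection is chosen so the RORC-role gene peaks after (not before) the
    PER3-role gene, matching the conserved +6 h quadrature geometry.
    """
    if mode == "supervised":
        if recorded_times is None:
            raise ValueError("supervised orientation needs recorded times")
        times = recorded_times.reindex(assignment.samples).to_numpy(dtype=float) % 24.0
        best = None
        grid = np.arange(0.0, 24.0, 0.05)
        for reflected in (False, True):
            phi = (-assignment.phi_h.to_numpy() if reflected else assignment.phi_h.to_numpy()) % 24.0
            for offset in grid:
                err = _median_abs_circular_error((phi + offset) % 24.0, times)
                if best is None or err < best[0]:
                    best = (err, reflected, float(offset))
        _, reflected, offset = best
        return assignment.with_orientation(reflected, offset)

    if mode == "anchored":
        if matrix is None:
            raise ValueError("anchored orientation needs the expression matrix")
        for g in (ref_gene, quad_gene):
            if g not in matrix.values.index:
                raise KeyError(f"anchor gene {g!r} not in matrix")
        candidates = []
        for reflected in (False, True):
            cand = assignment.with_orientation(reflected, 0.0)
            phi = cand.phi_h.reindex(matrix.samples).to_numpy(dtype=float)
            ref_fit = fit_harmonic(matrix.values.loc[ref_gene].to_numpy(), phi)
            offset = (anchor_peak_h - ref_fit.peak_h) % 24.0
            oriented = cand.with_orientation(False, offset)
            phi_o = oriented.phi_h.reindex(matrix.samples).to_numpy(dtype=float)
            quad_fit = fit_harmonic(matrix.values.loc[quad_gene].to_numpy(), phi_o)
            ref_fit_o = fit_harmonic(matrix.values.loc[ref_gene].to_numpy(), phi_o)
            dphi = wrap_phase_diff(quad_fit.peak_h - ref_fit_o.peak_h)
            candidates.append((dphi, oriented))
        # keep the orientation where the quadrature gene peaks after the reference
        for dphi, oriented in candidates:
            if 0.0 < dphi <= 12.0:
                return oriented
        logger.warning("no orientation places %s after %s; keeping first candidate",
                       quad_gene, ref_gene)
        return candidates[0][1]

    raise ValueError(f"unknown orientation mode {mode!r}")


def proxy_time(matrix, gene_num: str = "RORC", gene_den: str = "PER3") -> PhaseAssignment:
    """Circadian phase proxy from a quadrature gene pair.

    Both genes are centred and scaled across samples (raw log2 levels are
    strictly positive, which would confine the angle to one quadrant); the
    phase is the quadrant-aware angle of (denominator, numerator) mapped to
    [0, 24) h.  Convention: a sample at (z_den, z_num) = (1, 0) has phase 0.
    """
    for g in (gene_num, gene_den):
        if g not in matrix.values.index:
            raise KeyError(f"proxy gene {g!r} not in matrix")
    num = matrix.values.loc[gene_num].to_numpy(dtype=float)
    den = matrix.values.loc[gene_den].to_numpy(dtype=float)
    if num.std() == 0.0 or den.std() == 0.0:
        raise ValueError("proxy genes must have nonzero variance")
    z_num = (num - num.mean()) / num.std()
    z_den = (den - den.mean()) / den.std()
    return PhaseAssignment(
        phi_h=pd.Series(_angle_to_hours(z_num, z_den), index=matrix.samples),
        method="proxy",
        gene_list_used=[gene_den, gene_num],
    )


def reconstruct_gene(matrix, assignment: PhaseAssignment, gene: str) -> HarmonicFit:
    """Harmonic fit of one gene's levels against assigned phases.

    The resulting R^2 is the rhythm-strength readout used to compare normal
    and tumor tissue.
    """
    if gene not in matrix.values.index:
        raise KeyError(f"gene {gene!r} not in matrix")
    phi = assignment.phi_h.reindex(matrix.samples)
    if phi.isna().any():
        missing = phi.index[phi.isna()].tolist()
        raise ValueError(f"assignment lacks phases for samples: {missing}")
    return fit_harmonic(matrix.values.loc[gene].to_numpy(dtype=float),
                        phi.to_numpy(dtype=float))


def transfer_phases(assignment_normal: PhaseAssignment,
                    pairing: dict[str, str]) -> PhaseAssignment:
    """Copy each tumor sample's phase from its paired normal sample.

    Multiple tumor samples may share one normal partner; every tumor sample
    must be paired.
    """
    if not pairing:
        raise ValueError("empty pairing")
    unpaired = [t for t, n in pairing.items() if n not in assignment_normal.phi_h.index]
    if unpaired:
        raise KeyError(f"tumor samples paired to unknown normals: {unpaired}")
    phi = pd.Series(
        {t: float(assignment_normal.phi_h[n]) for t, n in pairing.items()}
    )
    return PhaseAssignment(phi_h=phi, method="transferred",
                           gene_list_used=list(assignment_normal.gene_list_used))


def circular_metrics(phi_a: pd.Series, phi_b: pd.Series) -> dict[str, float]:
    """Agreement between two phase assignments on the same samples.

    Returns the Fisher–Lee circular correlation, the raw median absolute
    circular error (hours, errors wrapped to [-12, 12]) and the error after
    removing the best common circular offset — a pure rotation gives
    correlation 1 with zero offset-removed error.
    """
    a = phi_a.sort_index()
    b = phi_b.reindex(a.index)
    if len(a) < 3 or b.isna().any() or len(a) != len(phi_b):
        raise ValueError("need the same >= 3 samples in both assignments")
    ra = a.to_numpy(dtype=float) / _H_PER_RAD
    rb = b.to_numpy(dtype=float) / _H_PER_RAD

    def _circ_mean(x):
        return np.arctan2(np.sin(x).mean(), np.cos(x).mean())

    # Fisher–Lee T-linear association over sample pairs; unlike mean-centred
    # variants it stays well defined when phases cover the cycle uniformly
    # (the circular mean is then degenerate)
    da = np.sin(ra[:, None] - ra[None, :])
    db = np.sin(rb[:, None] - rb[None, :])
    denom = np.sqrt((da**2).sum() * (db**2).sum())
    corr = float((da * db).sum() / denom) if denom > 0 else float("nan")

    raw_err = _median_abs_circular_error(a.to_numpy(dtype=float), b.to_numpy(dtype=float))
    # offset-removed: rotate a by the circular mean of the (b - a) differences
    delta = _circ_mean(rb - ra) * _H_PER_RAD
    adj_err = _median_abs_circular_error((a.to_numpy(dtype=float) + delta) % 24.0,
                                         b.to_numpy(dtype=float))
    return {
        "circular_correlation": corr,
        "median_abs_error_h": raw_err,
        "median_abs_error_offset_removed_h": adj_err,
        "offset_h": float(delta % 24.0),
    }
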