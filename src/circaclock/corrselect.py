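"""Rank-correlation machinery for phase-sorted circadian gene selection.

For two genes whose log2 levels oscillate as 24 h sinusoids, the Spearman
rank correlation r_S of their levels is a decreasing function of the absolute
peak-time difference |Δφ|: ~+1 at 0 h, ~0 at ±6 h, ~-1 at 12 h.  That
relationship lets a reference gene (the PER3 role) pull out in-phase and
anti-phase gene groups from a ranked correlation list, and — combined with a
second reference in anti-phase (the ARNTL role) and a rhythmicity filter — a
quadrature (±6 h) group.  Circadian correlation matrices (CCMs) over such a
list summarise all pairwise phase relationships and remain computable for
snapshot data without any time labels; flattened CCMs are compared across
datasets by cosine similarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from circaclock.genelists import (
    ANTI_PHASE,
    IN_PHASE,
    QUADRATURE,
    CircadianGeneList,
    GeneEntry,
)
from circaclock.rhythmfit import fit_all, wrap_phase_diff

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionThresholds:
    """Gene-group selection thresholds.

    k_top / k_bottom: sizes of the in-phase and anti-phase groups (ranked by
    r_S to the reference).  quad_rs_band: open interval of r_S to *both*
    references inside which a gene is a quadrature candidate.  quad_r2_min:
    harmonic-fit R^2 floor that keeps non-rhythmic genes out of the
    quadrature group.
    """

    k_top: int = 100
    k_bottom: int = 100
    quad_rs_band: tuple[float, float] = (-0.4, 0.4)
    quad_r2_min: float = 0.8

    def __post_init__(self) -> None:
        if self.k_top < 1 or self.k_bottom < 1:
            raise ValueError("k_top and k_bottom must be >= 1")
        if not self.quad_rs_band[0] < self.quad_rs_band[1]:
            raise ValueError("quad_rs_band must be an ordered pair")
        if not 0.0 <= self.quad_r2_min <= 1.0:
            raise ValueError("quad_r2_min must lie in [0, 1]")


@dataclass
class CorrelationMatrix:
    """Symmetric gene-by-gene Spearman matrix over a circadian gene list.

    Genes absent from the source dataset appear as all-NaN rows/columns so
    cross-dataset comparisons can mask them explicitly.
    """

    values: pd.DataFrame
    dataset_label: str = ""

    @property
    def gene_list(self) -> list[str]:
        return list(self.values.index)

    def write(self, path) -> None:
        df = self.values.copy()
        df.index.name = "gene"
        df.to_csv(path, sep="\t", float_format="%.12g")

    @classmethod
    def read(cls, path, dataset_label: str = "") -> "CorrelationMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(values=df, dataset_label=dataset_label)


def spearman(x, y) -> float:
    """Spearman rank correlation of two equal-length sample vectors.

    Average ranks for ties; r_S is the Pearson correlation of the rank
    vectors.  Zero rank variance in either vector makes the statistic
    undefined and yields NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    if x.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return float("nan")
    r, _ = stats.spearmanr(x, y)
    return float(r)


def correlate_to_reference(matrix, ref_gene: str) -> pd.Series:
    """r_S between a reference gene and every other gene of the matrix.

    The reference itself is excluded from the output; zero-variance genes
    come back as NaN.
    """
    if ref_gene not in matrix.values.index:
        near = [g for g in matrix.genes if g.upper() == ref_gene.upper() or ref_gene.upper() in g.upper()]
        raise KeyError(f"reference gene {ref_gene!r} not in matrix; near matches: {near[:5]}")
    ref = matrix.values.loc[ref_gene].to_numpy(dtype=float)
    others = matrix.values.drop(index=ref_gene)
    if np.unique(ref).size < 2:
        raise ValueError(f"reference gene {ref_gene!r} has zero variance")
    ref_rank = stats.rankdata(ref)
    ranks = np.apply_along_axis(stats.rankdata, 1, others.to_numpy(dtype=float))
    ref_c = ref_rank - ref_rank.mean()
    rk_c = ranks - ranks.mean(axis=1, keepdims=True)
    denom = np.sqrt((rk_c**2).sum(axis=1) * (ref_c**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        rs = (rk_c @ ref_c) / denom
    rs[denom == 0.0] = np.nan
    return pd.Series(rs, index=others.index, name=f"rs_{ref_gene}")


class PhaseGroupSelector(BaseEstimator):
    """Select phase-sorted circadian gene groups, sklearn style.

    Fit on a samples-by-genes frame ``X`` with per-sample collection times
    ``y`` (hours).  The selector ranks genes by r_S to ``ref_gene``, takes
    the ``k_top`` largest as the in-phase group and the ``k_bottom`` smallest
    as the anti-phase group, and forms the quadrature group from genes whose
    r_S to both ``ref_gene`` and ``second_ref`` falls inside ``quad_rs_band``
    and whose harmonic-fit R^2 exceeds ``quad_r2_min``.

    Attributes
    ----------
    gene_list_ : CircadianGeneList
        The selected phase-sorted list with per-gene r_S and Δφ.
    support_ : ndarray of bool
        Mask over input genes (reference included) marking selected genes.
    """

    def __init__(self, ref_gene: str = "PER3", second_ref: str = "ARNTL",
                 k_top: int = 100, k_bottom: int = 100,
                 quad_rs_band: tuple[float, float] = (-0.4, 0.4),
                 quad_r2_min: float = 0.8):
        self.ref_gene = ref_gene
        self.second_ref = second_ref
        self.k_top = k_top
        self.k_bottom = k_bottom
        self.quad_rs_band = quad_rs_band
        self.quad_r2_min = quad_r2_min

    def _thresholds(self) -> SelectionThresholds:
        return SelectionThresholds(self.k_top, self.k_bottom,
                                   tuple(self.quad_rs_band), self.quad_r2_min)

    def fit(self, X: pd.DataFrame, y):
        from circaclock.exprio import ExpressionMatrix

        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a samples-by-genes DataFrame with gene names")
        times = pd.Series(np.asarray(y, dtype=float), index=X.index)
        em = ExpressionMatrix(values=X.T.copy(), sample_times_h=times)
        self.gene_list_ = _select(em, self.ref_gene, self.second_ref,
                                  fit_all(em), self._thresholds())
        selected = set(self.gene_list_.genes)
        self.support_ = np.array([g in selected for g in X.columns])
        self.feature_names_in_ = np.asarray(X.columns)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        keep = [g for g in self.gene_list_.genes if g in X.columns]
        return X.loc[:, keep]

    def get_support(self) -> np.ndarray:
        return self.support_


def _select(matrix, ref_gene, second_ref, fits: pd.DataFrame,
            thresholds: SelectionThresholds) -> CircadianGeneList:
    rs_ref = correlate_to_reference(matrix, ref_gene)
    rs_second = correlate_to_reference(matrix, second_ref)

    degenerate = rs_ref.index[rs_ref.isna()].tolist()
    if degenerate:
        logger.warning("excluding %d degenerate (zero-variance) genes from ranking",
                       len(degenerate))
    usable = rs_ref.dropna()
    if len(usable) < thresholds.k_top + thresholds.k_bottom + 1:
        raise ValueError(
            f"too few non-degenerate genes ({len(usable)}) for "
            f"k_top={thresholds.k_top} + k_bottom={thresholds.k_bottom}"
        )

    ref_peak = fits.loc[ref_gene, "peak_h"] if ref_gene in fits.index else np.nan

    def dphi(gene: str) -> float | None:
        if gene not in fits.index or fits.loc[gene, "degenerate"] or np.isnan(ref_peak):
            return None
        return wrap_phase_diff(float(fits.loc[gene, "peak_h"]) - float(ref_peak))

    # deterministic ranking: r_S descending, symbol ascending breaks ties
    tiebreak = pd.DataFrame({"rs": usable.to_numpy(), "gene": usable.index.to_numpy()})
    tiebreak = tiebreak.sort_values(["rs", "gene"], ascending=[False, True], kind="stable")
    ranked = tiebreak["gene"].tolist()

    top = ranked[: thresholds.k_top]
    bottom = ranked[-thresholds.k_bottom:][::-1]  # most negative first

    lst = CircadianGeneList(reference=ref_gene, thresholds={
        "k_top": thresholds.k_top, "k_bottom": thresholds.k_bottom,
        "quad_rs_band": list(thresholds.quad_rs_band),
        "quad_r2_min": thresholds.quad_r2_min,
    })
    taken: set[str] = set()
    for gene in top:
        lst.add(GeneEntry(gene, IN_PHASE, rs=float(usable[gene]), dphi_h=dphi(gene)))
        taken.add(gene)
    for gene in bottom:
        lst.add(GeneEntry(gene, ANTI_PHASE, rs=float(usable[gene]), dphi_h=dphi(gene)))
        taken.add(gene)

    lo, hi = thresholds.quad_rs_band
    for gene in usable.index:
        if gene in taken or gene == second_ref:
            continue
        r1, r2 = usable[gene], rs_second.get(gene, np.nan)
        if not (lo < r1 < hi and lo < r2 < hi):
            continue
        if gene not in fits.index or fits.loc[gene, "degenerate"]:
            continue
        if float(fits.loc[gene, "r2"]) > thresholds.quad_r2_min:
            lst.add(GeneEntry(gene, QUADRATURE, rs=float(r1), dphi_h=dphi(gene)))
    return lst


def select_phase_groups(matrix, ref_gene: str, second_ref: str,
                        fits: pd.DataFrame | None = None,
                        thresholds: SelectionThresholds | None = None) -> CircadianGeneList:
    """Build the phase-sorted circadian gene list for one dataset.

    See :class:`PhaseGroupSelector` for the selection rules.  ``fits`` is
    the per-gene harmonic-fit table (computed from the matrix's own time
    annotation when omitted).
    """
    thresholds = thresholds or SelectionThresholds()
    if fits is None:
        fits = fit_all(matrix)
    return _select(matrix, ref_gene, second_ref, fits, thresholds)


def ccm(matrix, gene_list) -> CorrelationMatrix:
    """Circadian correlation matrix: pairwise r_S over a gene list.

    Needs no time labels, so it applies to snapshot data unchanged.  List
    genes absent from the matrix are recorded as NaN rows/columns.
    """
    genes = gene_list.genes if isinstance(gene_list, CircadianGeneList) else list(gene_list)
    present = [g for g in genes if g in matrix.values.index]
    if len(present) < 2:
        raise ValueError(f"fewer than 2 list genes present in matrix: {present}")
    sub = matrix.values.loc[present].T  # samples x genes
    corr = sub.corr(method="spearman")
    full = corr.reindex(index=genes, columns=genes)
    return CorrelationMatrix(values=full, dataset_label=matrix.species or "")


def cosine_similarity(ccm_a: CorrelationMatrix, ccm_b: CorrelationMatrix,
                      include_diagonal: bool = False) -> float:
    """Cosine similarity of two flattened circadian correlation matrices.

    The matrices are restricted to genes present (non-missing) in both, then
    flattened over the upper triangle.  The unit diagonal is excluded by
    default: it would add a constant positive term inflating every
    similarity.  Genes missing from either dataset are ignored.
    """
    shared = [g for g in ccm_a.gene_list if g in set(ccm_b.gene_list)]
    a = ccm_a.values.loc[shared, shared]
    b = ccm_b.values.loc[shared, shared]
    ok = (~a.isna().all(axis=1)) & (~b.isna().all(axis=1))
    shared = [g for g, keep in zip(shared, ok) if keep]
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared non-missing genes, got {shared}")
    a = ccm_a.values.loc[shared, shared].to_numpy(dtype=float)
    b = ccm_b.values.loc[shared, shared].to_numpy(dtype=float)
    iu = np.triu_indices(len(shared), k=0 if include_diagonal else 1)
    x, y = a[iu], b[iu]
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    denom = np.sqrt((x**2).sum()) * np.sqrt((y**2).sum())
    if denom == 0.0:
        raise ValueError("zero-norm flattened correlation matrix")
    return float((x * y).sum() / denom)


def dphi_rs_curve(n_samples: int = 24, n_cycles: int = 1,
                  dphi_grid=None) -> pd.DataFrame:
    """Spearman r_S between two noiseless unit sinusoids versus their Δφ.

    Samples are evenly spaced over ``n_cycles`` 24 h cycles.  The curve is
    even in Δφ and decreases from +1 at 0 h through ~0 at ±6 h to -1 at 12 h.
    """
    if n_samples < 3:
        raise ValueError("n_samples must be >= 3")
    if dphi_grid is None:
        dphi_grid = np.arange(-12.0, 12.01, 0.5)
    t = np.arange(n_samples) * (n_cycles * 24.0 / n_samples)
    # round the noiseless sinusoids so mathematically tied samples (symmetric
    # around the peak) tie exactly despite floating-point cosine asymmetry;
    # with exact ties the anti-phase rank reversal gives r_S = -1 exactly
    x = np.round(np.cos(2 * np.pi * t / 24.0), 12)
    rows = []
    for dphi in np.asarray(dphi_grid, dtype=float):
        y = np.round(np.cos(2 * np.pi * (t - dphi) / 24.0), 12)
        rows.append((float(dphi), spearman(x, y)))
    return pd.DataFrame(rows, columns=["dphi_h", "rs"])


def rs_consistency(snapshot_rs: pd.Series, reference_points: pd.DataFrame,
                   tolerance: float = 0.25) -> pd.DataFrame:
    """Compare snapshot r_S values against time-series reference datasets.

    ``reference_points`` has one row per (gene, dataset) with columns
    ``gene`` and ``rs`` (a ``dphi_h`` column, when present, is averaged and
    carried through).  For every overlapping gene the report gives the
    absolute difference between the snapshot r_S and the mean reference r_S,
    and a conserved/altered flag at ``tolerance``.
    """
    if reference_points.empty or snapshot_rs.empty:
        return pd.DataFrame(columns=["gene", "snapshot_rs", "reference_rs_mean",
                                     "abs_diff", "conserved"]).set_index("gene")
    grouped = reference_points.groupby("gene")
    ref_mean = grouped["rs"].mean()
    shared = [g for g in snapshot_rs.index if g in ref_mean.index]
    rows = {}
    for gene in shared:
        diff = abs(float(snapshot_rs[gene]) - float(ref_mean[gene]))
        rows[gene] = {
            "snapshot_rs": float(snapshot_rs[gene]),
            "reference_rs_mean": float(ref_mean[gene]),
            "abs_diff": diff,
            "conserved": diff <= tolerance,
        }
        if "dphi_h" in reference_points.columns:
            rows[gene]["reference_dphi_mean"] = float(grouped["dphi_h"].mean()[gene])
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "gene"
    return out
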