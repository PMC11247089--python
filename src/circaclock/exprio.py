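"""Expression-matrix container and IO.

Matrices are log2 gene-by-sample tables with gene symbols as row identifiers.
The loader enforces a single normalisation policy: values are log2-transformed
(with a pseudocount) when they look like raw counts, and passed through
unchanged when they are already on the log2 scale.  Gene symbols can be
harmonized to upper case so homologs from different species (mouse ``Per3``,
human ``PER3``) match by name.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: raw-count heuristic: already-log2 expression rarely exceeds this
_LOG2_MAX = 50.0


@dataclass
class ExpressionMatrix:
    """Log2 gene-by-sample expression with optional time/condition metadata.

    Attributes
    ----------
    values : pandas.DataFrame
        Genes as rows (index = symbols), samples as columns, log2 units.
    species : str or None
        Free-text species tag used for provenance only.
    sample_times_h : pandas.Series or None
        Per-sample collection times in hours.  Stored unwrapped: multi-day
        series keep values above 24 so a 48 h design stays distinguishable
        from a single cycle.  Absent for snapshot cohorts.
    condition : pandas.Series or None
        Per-sample label, e.g. ``normal`` / ``tumor``.
    pairing : dict or None
        tumor-sample -> normal-sample map for paired cohorts.
    """

    values: pd.DataFrame
    species: str | None = None
    sample_times_h: pd.Series | None = None
    condition: pd.Series | None = None
    pairing: dict[str, str] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbols: {dupes}")
        if self.values.columns.has_duplicates:
            dupes = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dupes}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        present = [g for g in genes if g in self.values.index]
        return replace(self, values=self.values.loc[present])

    def subset_samples(self, samples: list[str]) -> "ExpressionMatrix":
        out = replace(self, values=self.values.loc[:, samples])
        if self.sample_times_h is not None:
            out.sample_times_h = self.sample_times_h.reindex(samples)
        if self.condition is not None:
            out.condition = self.condition.reindex(samples)
        return out

    def write(self, path: str | Path, sep: str = "\t") -> None:
        df = self.values.copy()
        df.index.name = "gene"
        # %.17g round-trips IEEE doubles exactly
        df.to_csv(path, sep=sep, float_format="%.17g")

    def write_metadata(self, path: str | Path) -> None:
        meta = pd.DataFrame(index=pd.Index(self.samples, name="sample"))
        if self.sample_times_h is not None:
            meta["time_h"] = self.sample_times_h.reindex(self.samples)
        if self.condition is not None:
            meta["condition"] = self.condition.reindex(self.samples)
        if self.pairing:
            normal_of = pd.Series(self.pairing)
            meta["pair_id"] = normal_of.reindex(self.samples)
        meta.to_csv(path, sep="\t")


def read_matrix(
    path: str | Path,
    *,
    sep: str | None = None,
    log2: str = "auto",
    pseudocount: float = 1.0,
    dedup: str = "drop",
    species: str | None = None,
) -> ExpressionMatrix:
    """Load a delimited genes-by-samples expression table.

    Parameters
    ----------
    path : str or Path
        Delimited text file; genes as rows, first column = gene symbol,
        header row = sample identifiers.
    sep : str, optional
        Field delimiter; inferred from the extension when omitted
        (``.csv`` -> comma, otherwise tab).
    log2 : {"auto", "always", "never"}
        ``auto`` applies ``log2(x + pseudocount)`` only when the value
        distribution indicates raw counts (maximum above 50); already-log2
        data passes through unchanged, so the loader is idempotent.
    pseudocount : float
        Offset added before the log2 of counts; 1.0 keeps zeros at zero.
    dedup : {"drop", "error"}
        Policy for duplicated gene rows; ``drop`` keeps the first occurrence.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    # check the raw header: pandas silently renames duplicated columns
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    dupes = sorted({name for name in header if header.count(name) > 1})
    if dupes:
        raise ValueError(f"duplicate sample IDs in {path.name}: {dupes}")

    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "gene"
    df.columns = df.columns.astype(str)

    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise ValueError(
                f"non-numeric cell in {path.name}: row {row!r}, column {col!r}"
            )

    if df.index.has_duplicates:
        if dedup == "error":
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene rows: {dupes}")
        n_before = len(df)
        df = df[~df.index.duplicated(keep="first")]
        logger.warning("dropped %d duplicated gene rows (kept first)", n_before - len(df))

    n_with_na = int(df.isna().any(axis=1).sum())
    if n_with_na:
        logger.warning("dropping %d gene rows with missing values", n_with_na)
        df = df.dropna(axis=0)

    if log2 == "always" or (log2 == "auto" and df.to_numpy().max(initial=0.0) > _LOG2_MAX):
        logger.info("applying log2(x + %g) transform (raw-count scale detected)", pseudocount)
        df = np.log2(df + pseudocount)
    elif log2 not in ("auto", "never", "always"):
        raise ValueError(f"log2 must be 'auto', 'always' or 'never', got {log2!r}")

    return ExpressionMatrix(values=df.astype(float), species=species)


def attach_times(matrix: ExpressionMatrix, metadata_path: str | Path) -> ExpressionMatrix:
    """Attach per-sample collection times (and condition/pairing) from a TSV.

    The metadata file needs ``sample`` and ``time_h`` columns; ``condition``
    and ``pair_id`` (normal partner of a tumor sample) are optional.  Samples
    absent from the metadata keep an undefined time; metadata rows naming
    unknown samples are warned about and skipped.
    """
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"sample": str})
    if meta.empty:
        return matrix
    if "sample" not in meta.columns or "time_h" not in meta.columns:
        raise ValueError("metadata must have 'sample' and 'time_h' columns")
    meta = meta.set_index("sample")

    unknown = [s for s in meta.index if s not in matrix.values.columns]
    if unknown:
        logger.warning("metadata samples not in matrix (ignored): %s", unknown)
        meta = meta.drop(index=unknown)

    times = pd.to_numeric(meta["time_h"], errors="coerce")
    if times.isna().any() and meta["time_h"].notna().any():
        bad = meta.index[times.isna() & meta["time_h"].notna()].tolist()
        if bad:
            raise ValueError(f"malformed time_h for samples: {bad}")

    out = replace(matrix)
    full_times = pd.Series(np.nan, index=matrix.values.columns, dtype=float)
    if matrix.sample_times_h is not None:
        full_times.update(matrix.sample_times_h)
    full_times.update(times)
    out.sample_times_h = full_times

    if "condition" in meta.columns:
        cond = pd.Series(index=matrix.values.columns, dtype=object)
        if matrix.condition is not None:
            cond.update(matrix.condition)
        cond.update(meta["condition"])
        out.condition = cond
    if "pair_id" in meta.columns:
        pairing = dict(matrix.pairing or {})
        for tumor, normal in meta["pair_id"].dropna().items():
            pairing[tumor] = str(normal)
        normals = list(pairing.values())
        if len(set(normals)) != len(normals):
            logger.info("pairing is not bijective: some normals pair multiple tumors")
        out.pairing = pairing
    return out


def harmonize_symbols(matrix: ExpressionMatrix, mode: str = "uppercase") -> ExpressionMatrix:
    """Map gene symbols case-insensitively to upper case.

    Homology across the species analysed here is by shared symbol, so mouse
    ``Per3`` and human ``PER3`` collapse to one name.  When two rows collide
    after upper-casing, the row with the higher variance is kept (the flatter
    duplicate is usually a lowly expressed paralog or probe artefact).
    """
    if mode != "uppercase":
        raise ValueError(f"unknown harmonization mode: {mode!r}")
    if matrix.n_genes == 0:
        return matrix
    upper = matrix.values.index.str.upper()
    df = matrix.values.copy()
    df.index = upper
    if df.index.has_duplicates:
        variances = df.var(axis=1)
        order = np.argsort(-variances.to_numpy(), kind="stable")
        df = df.iloc[order]
        dupes = df.index[df.index.duplicated()].unique().tolist()
        logger.warning("symbol collisions resolved by variance: %s", dupes)
        df = df[~df.index.duplicated(keep="first")]
        # restore original relative order of the survivors
        keep_order = [g for g in upper if g in set(df.index)]
        seen: set[str] = set()
        keep_order = [g for g in keep_order if not (g in seen or seen.add(g))]
        df = df.loc[keep_order]
    return replace(matrix, values=df)
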