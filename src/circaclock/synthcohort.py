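"""Synthetic circadian snapshot cohorts with known ground truth.

Genes oscillate in log2 units as 24 h cosines with gene-specific peak phase,
amplitude and mesor plus additive Gaussian noise; non-rhythmic background
genes carry mesor plus noise only.  Rhythmic genes fall into four phase
groups offset 0 h, 12 h, +6 h and -6 h from a reference gene.  A paired
"tumor" condition damps amplitudes, phase-shifts chosen genes, and jitters
each sample's effective circadian time — the failure modes reported for
clock gene expression in lung adenocarcinoma.

Clock-role aliases: the first genes of the relevant groups are named PER3
and TEF (0 h), ARNTL (12 h) and RORC (+6 h), and are planted without
within-group phase jitter, so reference-gene-dependent operations run on
synthetic cohorts unmodified with exactly the canonical geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from circaclock.exprio import ExpressionMatrix

GROUP_OFFSETS_H = {"0h": 0.0, "12h": 12.0, "+6h": 6.0, "-6h": -6.0}
BACKGROUND = "background"

#: clock-role aliases assigned to the first gene(s) of each group
_ALIASES = {"0h": ["PER3", "TEF"], "12h": ["ARNTL"], "+6h": ["RORC"]}


@dataclass(frozen=True)
class EvenSampling:
    """Evenly spaced times over ``n_cycles`` full days (period derived from
    n_samples), or every ``period_h`` hours when given explicitly."""
    n_cycles: int = 1
    period_h: float | None = None

    def times(self, n_samples: int, rng: np.random.Generator) -> np.ndarray:
        if self.period_h is not None:
            return np.arange(n_samples) * float(self.period_h)
        return np.arange(n_samples) * (self.n_cycles * 24.0 / n_samples)


@dataclass(frozen=True)
class UniformRandomSampling:
    """Collection times uniform over the full circadian day."""

    def times(self, n_samples: int, rng: np.random.Generator) -> np.ndarray:
        return rng.uniform(0.0, 24.0, size=n_samples)


@dataclass(frozen=True)
class ClinicalSampling:
    """Collection times uniform inside a daytime window (surgical hours)."""
    window_start_h: float = 8.0
    window_end_h: float = 18.0

    def times(self, n_samples: int, rng: np.random.Generator) -> np.ndarray:
        if self.window_start_h == self.window_end_h:
            raise ValueError("clinical sampling window must have nonzero width")
        lo, hi = self.window_start_h, self.window_end_h
        if hi < lo:  # window crossing midnight
            hi += 24.0
        return rng.uniform(lo, hi, size=n_samples) % 24.0


@dataclass
class CohortConfig:
    """Parameters of one synthetic cohort; defaults emulate a 24-sample,
    2-hourly mouse-lung style series with moderate noise."""

    n_genes_per_group: int | dict[str, int] = 25
    n_background: int = 100
    n_samples: int = 24
    sampling: EvenSampling | UniformRandomSampling | ClinicalSampling = field(
        default_factory=EvenSampling
    )
    amplitude_range: tuple[float, float] = (0.5, 1.5)
    mesor_range: tuple[float, float] = (4.0, 10.0)
    noise_sd: float = 0.25
    phase_jitter_sd_h: float = 0.5
    reference_peak_h: float = 12.0  # matches the anchored-orientation convention
    clock_aliases: bool = True
    seed: int = 0

    def group_counts(self) -> dict[str, int]:
        if isinstance(self.n_genes_per_group, dict):
            counts = {g: 0 for g in GROUP_OFFSETS_H}
            counts.update(self.n_genes_per_group)
            unknown = set(counts) - set(GROUP_OFFSETS_H)
            if unknown:
                raise ValueError(f"unknown phase groups: {sorted(unknown)}")
            return counts
        return {g: int(self.n_genes_per_group) for g in GROUP_OFFSETS_H}

    def validate(self) -> None:
        counts = self.group_counts()
        if any(c < 0 for c in counts.values()) or self.n_background < 0:
            raise ValueError("gene counts must be >= 0")
        if self.n_samples < 3:
            raise ValueError("n_samples must be >= 3 for any downstream fit")
        if self.noise_sd < 0 or self.phase_jitter_sd_h < 0:
            raise ValueError("noise_sd and phase_jitter_sd_h must be >= 0")
        for name, (lo, hi) in (("amplitude_range", self.amplitude_range),
                               ("mesor_range", self.mesor_range)):
            if lo > hi:
                raise ValueError(f"{name} must be an ordered (low, high) pair")


@dataclass
class TumorConfig:
    """Tumor transformation: global amplitude damping, per-gene phase shifts
    (hours, modulo 24), and per-sample circadian phase jitter."""

    amplitude_factor: float = 0.2
    shifted_genes: dict[str, float] = field(default_factory=dict)
    damped_genes: list[str] | None = None  # None = damp every rhythmic gene
    sample_phase_jitter_sd_h: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.amplitude_factor <= 1.0:
            raise ValueError("amplitude_factor must lie in [0, 1]")
        if self.sample_phase_jitter_sd_h < 0:
            raise ValueError("sample_phase_jitter_sd_h must be >= 0")


@dataclass
class GroundTruth:
    """Planted parameters: per-gene (group, peak phase, amplitude, mesor),
    per-sample true times, and the normal/tumor pairing."""

    genes: pd.DataFrame     # index gene: group, peak_h, amplitude, mesor
    samples: pd.DataFrame   # index sample: time_h, condition, pair_id
    noise_sd: float = 0.0

    def write(self, gene_path: str | Path, sample_path: str | Path) -> None:
        g = self.genes.copy()
        g.index.name = "gene"
        g.to_csv(gene_path, sep="\t", float_format="%.12g")
        s = self.samples.copy()
        s.index.name = "sample"
        s.to_csv(sample_path, sep="\t", float_format="%.12g")


def _signal(t: np.ndarray, peak_h: float, amplitude: float, mesor: float) -> np.ndarray:
    return mesor + amplitude * np.cos(2.0 * np.pi * (t - peak_h) / 24.0)


def generate_cohort(config: CohortConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Generate one synthetic cohort; identical seeds give identical output."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    counts = config.group_counts()

    times = np.asarray(config.sampling.times(config.n_samples, rng), dtype=float)
    sample_ids = [f"S{i:03d}" for i in range(config.n_samples)]

    gene_rows = []
    for group in GROUP_OFFSETS_H:
        aliases = list(_ALIASES.get(group, [])) if config.clock_aliases else []
        tag = group.replace("+", "P").replace("-", "M").upper()
        for i in range(counts[group]):
            if i < len(aliases):
                name, jitter = aliases[i], 0.0
            else:
                name = f"G{tag}_{i:03d}"
                jitter = rng.normal(0.0, config.phase_jitter_sd_h) if config.phase_jitter_sd_h else 0.0
            peak = (config.reference_peak_h + GROUP_OFFSETS_H[group] + jitter) % 24.0
            amp = rng.uniform(*config.amplitude_range)
            mesor = rng.uniform(*config.mesor_range)
            gene_rows.append((name, group, peak, amp, mesor))
    for i in range(config.n_background):
        mesor = rng.uniform(*config.mesor_range)
        gene_rows.append((f"BG_{i:03d}", BACKGROUND, np.nan, 0.0, mesor))

    genes = pd.DataFrame(gene_rows, columns=["gene", "group", "peak_h", "amplitude", "mesor"])
    genes = genes.set_index("gene")
    if genes.index.has_duplicates:
        raise ValueError("duplicate synthetic gene names; reduce group sizes or disable aliases")

    values = np.empty((len(genes), config.n_samples))
    for i, (_, row) in enumerate(genes.iterrows()):
        if row["group"] == BACKGROUND:
            values[i] = row["mesor"]
        else:
            values[i] = _signal(times, row["peak_h"], row["amplitude"], row["mesor"])
    if config.noise_sd > 0:
        values = values + rng.normal(0.0, config.noise_sd, size=values.shape)

    samples = pd.DataFrame(
        {"time_h": times, "condition": "normal", "pair_id": pd.NA},
        index=pd.Index(sample_ids, name="sample"),
    )
    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=genes.index.copy(), columns=sample_ids),
        species="synthetic",
        sample_times_h=pd.Series(times, index=sample_ids),
        condition=pd.Series("normal", index=sample_ids),
    )
    return matrix, GroundTruth(genes=genes, samples=samples, noise_sd=config.noise_sd)


def apply_tumor(matrix: ExpressionMatrix, truth: GroundTruth,
                tcfg: TumorConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Derive a paired tumor cohort from a normal cohort.

    Each normal sample gets one tumor partner that inherits its true
    circadian time (perturbed by per-sample jitter); rhythmic amplitudes are
    multiplied by ``amplitude_factor`` and listed genes are phase-shifted.
    Fresh noise is drawn from ``tcfg.seed`` at the normal cohort's noise
    level.
    """
    tcfg.validate()
    missing = [g for g in tcfg.shifted_genes if g not in truth.genes.index]
    if missing:
        raise KeyError(f"shifted genes absent from matrix: {missing}")
    if tcfg.damped_genes is not None:
        missing = [g for g in tcfg.damped_genes if g not in truth.genes.index]
        if missing:
            raise KeyError(f"damped genes absent from matrix: {missing}")
    rng = np.random.default_rng(tcfg.seed)

    normal_samples = list(matrix.samples)
    tumor_ids = [f"T_{s}" for s in normal_samples]
    base_times = truth.samples.loc[normal_samples, "time_h"].to_numpy(dtype=float)
    jitter = (rng.normal(0.0, tcfg.sample_phase_jitter_sd_h, size=len(normal_samples))
              if tcfg.sample_phase_jitter_sd_h > 0 else np.zeros(len(normal_samples)))
    eff_times = base_times + jitter

    tumor_genes = truth.genes.copy()
    damp = tumor_genes["group"] != BACKGROUND
    if tcfg.damped_genes is not None:
        damp &= tumor_genes.index.isin(tcfg.damped_genes)
    tumor_genes.loc[damp, "amplitude"] *= tcfg.amplitude_factor
    for gene, shift in tcfg.shifted_genes.items():
        tumor_genes.loc[gene, "peak_h"] = (tumor_genes.loc[gene, "peak_h"] + shift) % 24.0

    values = np.empty((len(tumor_genes), len(tumor_ids)))
    for i, (_, row) in enumerate(tumor_genes.iterrows()):
        if row["group"] == BACKGROUND:
            values[i] = row["mesor"]
        else:
            values[i] = _signal(eff_times, row["peak_h"], row["amplitude"], row["mesor"])
    if truth.noise_sd > 0:
        values = values + rng.normal(0.0, truth.noise_sd, size=values.shape)

    pairing = dict(zip(tumor_ids, normal_samples))
    samples = pd.DataFrame(
        {"time_h": base_times, "effective_time_h": eff_times,
         "condition": "tumor", "pair_id": normal_samples},
        index=pd.Index(tumor_ids, name="sample"),
    )
    tumor_matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=tumor_genes.index.copy(), columns=tumor_ids),
        species=matrix.species,
        sample_times_h=None,  # snapshot semantics: tumor times are hidden
        condition=pd.Series("tumor", index=tumor_ids),
        pairing=pairing,
    )
    tumor_truth = GroundTruth(genes=tumor_genes, samples=samples, noise_sd=truth.noise_sd)
    return tumor_matrix, tumor_truth
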