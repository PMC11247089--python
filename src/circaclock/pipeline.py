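"""End-to-end study replica: simulate or load cohorts, select phase-sorted
gene lists per dataset, intersect them, compare circadian correlation
matrices across datasets, reconstruct snapshot phases, and contrast paired
normal vs tumor rhythm strength.  Emits a machine-readable JSON report plus
TSV tables."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from circaclock._version import __version__ as _version
from circaclock.corrselect import SelectionThresholds, ccm, cosine_similarity, select_phase_groups
from circaclock.exprio import ExpressionMatrix, attach_times, read_matrix
from circaclock.genelists import intersect_lists
from circaclock.phasing import (
    orient_phase,
    pca_phase,
    reconstruct_gene,
    transfer_phases,
)
from circaclock.synthcohort import (
    ClinicalSampling,
    CohortConfig,
    EvenSampling,
    TumorConfig,
    UniformRandomSampling,
    apply_tumor,
    generate_cohort,
)

logger = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed (< 2^31)."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """One study-replica run.

    ``datasets`` maps a label to either ``{"matrix": path, "metadata": path}``
    (load from disk) or ``{"synthetic": {...CohortConfig fields...}}``; an
    optional ``tumor`` block on one dataset adds a paired tumor cohort.
    """

    datasets: dict[str, dict]
    ref_gene: str = "PER3"
    second_ref: str = "ARNTL"
    thresholds: SelectionThresholds = field(default_factory=SelectionThresholds)
    orientation: str = "anchored"
    out_dir: str | Path = "circaclock_run"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        thr = payload.pop("thresholds", None)
        cfg = cls(**payload)
        if thr:
            if "quad_rs_band" in thr:
                thr["quad_rs_band"] = tuple(thr["quad_rs_band"])
            cfg.thresholds = SelectionThresholds(**thr)
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(
            {"datasets": self.datasets, "ref": self.ref_gene, "second": self.second_ref,
             "thresholds": vars(self.thresholds) if hasattr(self.thresholds, "__dict__")
             else self.thresholds.__repr__(), "orientation": self.orientation,
             "seed": self.seed},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _build_sampling(block: dict):
    kind = block.get("kind", "even")
    if kind == "even":
        return EvenSampling(n_cycles=block.get("n_cycles", 1),
                            period_h=block.get("period_h"))
    if kind == "uniform_random":
        return UniformRandomSampling()
    if kind == "clinical":
        return ClinicalSampling(window_start_h=block.get("window_start_h", 8.0),
                                window_end_h=block.get("window_end_h", 18.0))
    raise ValueError(f"unknown sampling kind {kind!r}")


def _load_dataset(label: str, block: dict, global_seed: int):
    """Returns (matrix, truth-or-None, tumor_matrix-or-None)."""
    if "synthetic" in block:
        syn = dict(block["synthetic"])
        if "sampling" in syn:
            syn["sampling"] = _build_sampling(syn["sampling"])
        syn.setdefault("seed", stage_seed(global_seed, f"simulate:{label}"))
        cfg = CohortConfig(**syn)
        matrix, truth = generate_cohort(cfg)
        tumor_matrix = None
        if "tumor" in block:
            tum = dict(block["tumor"])
            tum.setdefault("seed", stage_seed(global_seed, f"tumor:{label}"))
            tumor_matrix, _ = apply_tumor(matrix, truth, TumorConfig(**tum))
        return matrix, truth, tumor_matrix
    if "matrix" in block:
        if not Path(block["matrix"]).exists():
            raise FileNotFoundError(
                f"dataset block {label!r}: matrix file not found: {block['matrix']}"
            )
        matrix = read_matrix(block["matrix"])
        if block.get("metadata"):
            matrix = attach_times(matrix, block["metadata"])
        return matrix, None, None
    raise ValueError(f"dataset block {label!r} needs a 'matrix' path or a 'synthetic' config")


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the report dict (also written to
    ``out_dir/report.json``).  Identical config and seed reproduce the report
    bit for bit (timestamps excluded by construction: none are embedded)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": _version,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "datasets": {},
    }

    matrices: dict[str, ExpressionMatrix] = {}
    tumors: dict[str, ExpressionMatrix] = {}
    lists = {}
    for label, block in config.datasets.items():
        logger.info("stage load/simulate: %s", label)
        matrix, truth, tumor_matrix = _load_dataset(label, block, config.seed)
        matrices[label] = matrix
        if tumor_matrix is not None:
            tumors[label] = tumor_matrix
        has_times = matrix.sample_times_h is not None and matrix.sample_times_h.notna().any()
        entry: dict = {"n_genes": matrix.n_genes, "n_samples": matrix.n_samples,
                       "time_annotated": bool(has_times)}
        if has_times:
            gl = select_phase_groups(matrix, config.ref_gene, config.second_ref,
                                     thresholds=config.thresholds)
            gl.provenance = [label]
            lists[label] = gl
            gl.write(out / f"genelist_{label}.json")
            entry["gene_list"] = {
                "in_phase": len(gl.group("IN_PHASE")),
                "anti_phase": len(gl.group("ANTI_PHASE")),
                "quadrature": len(gl.group("QUADRATURE")),
            }
        report["datasets"][label] = entry

    if len(lists) >= 2:
        shared = intersect_lists(list(lists.values()))
        shared.write(out / "genelist_shared.json")
        report["intersection"] = {"n_genes": len(shared)}
    elif lists:
        shared = next(iter(lists.values()))
        report["intersection"] = {"n_genes": len(shared), "note": "single time-annotated dataset"}
    else:
        raise RuntimeError("stage select-genes: no time-annotated dataset to build lists from")

    logger.info("stage ccm/similarity")
    all_matrices = dict(matrices)
    all_matrices.update({f"{k}_tumor": v for k, v in tumors.items()})
    ccms = {}
    for label, matrix in all_matrices.items():
        cm = ccm(matrix, shared)
        cm.dataset_label = label
        cm.write(out / f"ccm_{label}.tsv")
        ccms[label] = cm
    labels = list(ccms)
    sim = pd.DataFrame(np.eye(len(labels)), index=labels, columns=labels)
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if j > i:
                s = cosine_similarity(ccms[a], ccms[b])
                sim.iloc[i, j] = sim.iloc[j, i] = s
    sim.to_csv(out / "ccm_similarity.tsv", sep="\t", float_format="%.6g")
    report["ccm_cosine_similarity"] = {
        a: {b: float(sim.loc[a, b]) for b in labels} for a in labels
    }

    recon: dict = {}
    for label, tumor_matrix in tumors.items():
        logger.info("stage reconstruct: %s", label)
        normal = matrices[label]
        assignment = pca_phase(normal, shared,
                               shuffle_seed=stage_seed(config.seed, f"pca:{label}"))
        if config.orientation == "supervised" and normal.sample_times_h is not None:
            oriented = orient_phase(assignment, mode="supervised",
                                    recorded_times=normal.sample_times_h)
        else:
            oriented = orient_phase(assignment, matrix=normal, mode="anchored",
                                    ref_gene=config.ref_gene)
        oriented.write(out / f"phases_{label}.tsv")
        transferred = transfer_phases(oriented, tumor_matrix.pairing)
        transferred.write(out / f"phases_{label}_tumor.tsv")

        per_gene = {}
        for gene in shared.genes:
            if gene not in normal.values.index or gene not in tumor_matrix.values.index:
                continue
            fit_n = reconstruct_gene(normal, oriented, gene)
            fit_t = reconstruct_gene(tumor_matrix, transferred, gene)
            per_gene[gene] = {"r2_normal": fit_n.r2, "r2_tumor": fit_t.r2}
        df = pd.DataFrame.from_dict(per_gene, orient="index")
        df.index.name = "gene"
        df.to_csv(out / f"reconstruction_r2_{label}.tsv", sep="\t", float_format="%.6g")
        recon[label] = {
            "mean_r2_normal": float(df["r2_normal"].mean()),
            "mean_r2_tumor": float(df["r2_tumor"].mean()),
            "fraction_weaker_in_tumor": float((df["r2_tumor"] < df["r2_normal"]).mean()),
        }
    if recon:
        report["reconstruction"] = recon

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
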