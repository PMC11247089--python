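"""Phase-sorted circadian gene lists and their algebra.

A :class:`CircadianGeneList` groups genes by the phase difference of their
expression peak to a reference gene (the PER3 role): IN_PHASE (~0 h),
ANTI_PHASE (~12 h) and QUADRATURE (~±6 h).  Lists from different datasets are
combined by group-consistent intersection; cross-species combination matches
homologs by upper-cased symbol.  Curated lists for murine and mammalian lung
tissue, and five previously published core-clock sets, ship as packaged JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

IN_PHASE = "IN_PHASE"
ANTI_PHASE = "ANTI_PHASE"
QUADRATURE = "QUADRATURE"
GROUPS = (IN_PHASE, ANTI_PHASE, QUADRATURE)

_GROUP_JSON = {IN_PHASE: "in_phase", ANTI_PHASE: "anti_phase", QUADRATURE: "quadrature"}
_GROUP_FROM_JSON = {v: k for k, v in _GROUP_JSON.items()}

#: fixtures shipping full phase-group structure
_GROUPED_FIXTURES = ("murine_shared", "mammalian_shared")
#: previously published core-clock lists, shipped as flat symbol sets
_FLAT_FIXTURES = ("hughey", "wittenbrink", "talamanca", "shilts", "wu")


@dataclass
class GeneEntry:
    gene: str
    group: str
    rs: float | None = None
    dphi_h: float | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.dphi_h is not None and not (-12.0 < self.dphi_h <= 12.0):
            raise ValueError(f"dphi_h must lie in (-12, 12], got {self.dphi_h}")


@dataclass
class CircadianGeneList:
    """Phase-sorted gene set relative to a reference gene.

    The reference itself is not listed among the entries (its correlation to
    itself is trivially 1); fixture group counts include it in the in-phase
    column where the curated tables print it there.
    """

    reference: str
    entries: dict[str, GeneEntry] = field(default_factory=dict)
    provenance: list[str] = field(default_factory=list)
    thresholds: dict | None = None

    def __post_init__(self) -> None:
        if self.reference in self.entries:
            raise ValueError("reference gene must not appear in its own entries")

    def add(self, entry: GeneEntry) -> None:
        if entry.gene == self.reference:
            raise ValueError("reference gene must not appear in its own entries")
        self.entries[entry.gene] = entry

    def group(self, group: str) -> list[str]:
        """Genes assigned to one phase group; IN_PHASE includes the reference."""
        genes = sorted(g for g, e in self.entries.items() if e.group == group)
        if group == IN_PHASE:
            genes = sorted({self.reference, *genes})
        return genes

    @property
    def genes(self) -> list[str]:
        """All list genes, reference included, in group order."""
        out: list[str] = []
        for grp in GROUPS:
            out.extend(self.group(grp))
        return out

    def __len__(self) -> int:
        return len(self.entries) + 1  # + reference

    def __contains__(self, gene: str) -> bool:
        return gene == self.reference or gene in self.entries

    # ------------------------------------------------------------------ io
    def to_dict(self) -> dict:
        groups = {json_name: [] for json_name in _GROUP_JSON.values()}
        for gene in sorted(self.entries):
            e = self.entries[gene]
            groups[_GROUP_JSON[e.group]].append(
                {"gene": e.gene, "rs": e.rs, "dphi_h": e.dphi_h}
            )
        return {
            "reference": self.reference,
            "groups": groups,
            "thresholds": self.thresholds,
            "dataset_label": list(self.provenance),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "CircadianGeneList":
        lst = cls(
            reference=payload["reference"],
            provenance=list(payload.get("dataset_label") or []),
            thresholds=payload.get("thresholds"),
        )
        for json_name, entries in payload.get("groups", {}).items():
            group = _GROUP_FROM_JSON[json_name]
            for item in entries:
                lst.add(GeneEntry(gene=item["gene"], group=group,
                                  rs=item.get("rs"), dphi_h=item.get("dphi_h")))
        return lst

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "CircadianGeneList":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _mean_or_none(values: list[float | None]) -> float | None:
    vals = [v for v in values if v is not None]
    return float(np.mean(vals)) if vals else None


def intersect_lists(lists: list[CircadianGeneList]) -> CircadianGeneList:
    """Group-consistent intersection of two or more circadian gene lists.

    A gene survives only if it is present in every input and assigned to the
    same phase group in every input; group conflicts are logged and the gene
    dropped.  The surviving entry carries the mean r_S across inputs and the
    per-dataset phase-difference range is reduced to its mean.
    """
    if len(lists) < 2:
        raise ValueError("need at least two lists to intersect")
    refs = {lst.reference for lst in lists}
    if len(refs) > 1:
        raise ValueError(f"conflicting reference genes: {sorted(refs)}")

    out = CircadianGeneList(
        reference=lists[0].reference,
        provenance=sorted({p for lst in lists for p in lst.provenance}),
    )
    shared = set(lists[0].entries)
    for lst in lists[1:]:
        shared &= set(lst.entries)
    for gene in sorted(shared):
        groups = {lst.entries[gene].group for lst in lists}
        if len(groups) > 1:
            logger.info("gene %s dropped: group conflict %s", gene, sorted(groups))
            continue
        out.add(GeneEntry(
            gene=gene,
            group=groups.pop(),
            rs=_mean_or_none([lst.entries[gene].rs for lst in lists]),
            dphi_h=_mean_or_none([lst.entries[gene].dphi_h for lst in lists]),
        ))
    return out


def homolog_intersect(list_a: CircadianGeneList, list_b: CircadianGeneList) -> CircadianGeneList:
    """Cross-species intersection by upper-cased symbol with group agreement.

    Homologs are matched by name (mouse ``Per3`` vs human ``PER3``); no
    orthology database is consulted.  An empty result is legal and warned
    about.
    """
    up_a = _uppercased(list_a)
    up_b = _uppercased(list_b)
    result = intersect_lists([up_a, up_b])
    if not result.entries:
        logger.warning("homolog intersection is empty beyond the reference gene")
    return result


def _uppercased(lst: CircadianGeneList) -> CircadianGeneList:
    out = CircadianGeneList(reference=lst.reference.upper(),
                            provenance=list(lst.provenance), thresholds=lst.thresholds)
    for e in lst.entries.values():
        out.add(GeneEntry(gene=e.gene.upper(), group=e.group, rs=e.rs, dphi_h=e.dphi_h))
    return out


def load_fixture(name: str):
    """Load a packaged circadian gene list.

    ``murine_shared`` and ``mammalian_shared`` return a
    :class:`CircadianGeneList` with the full three-group structure of the
    curated lung lists (107 and 13 genes respectively, reference PER3
    counted in the 0 h group).  The five previously published core-clock
    lists (``hughey``, ``wittenbrink``, ``talamanca``, ``shilts``, ``wu``)
    return plain frozensets of symbols, intended for correlation-matrix
    comparisons only.
    """
    if name in _GROUPED_FIXTURES:
        payload = json.loads(
            resources.files("circaclock.data").joinpath(f"{name}.json").read_text()
        )
        return CircadianGeneList.from_dict(payload)
    if name in _FLAT_FIXTURES:
        payload = json.loads(
            resources.files("circaclock.data").joinpath("published_lists.json").read_text()
        )
        return frozenset(payload[name])
    available = ", ".join([*_GROUPED_FIXTURES, *_FLAT_FIXTURES])
    raise KeyError(f"unknown fixture {name!r}; available: {available}")
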