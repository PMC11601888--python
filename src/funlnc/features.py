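"""The 57-column, three-category feature matrix computed from the network.

Category C1 (8 features) summarizes promoter-proximal regulators (SNPs, TFs,
methylation, activating histone marks). Category C2 (46) summarizes distal
elements — super-enhancers (12), typical enhancers (23) and accessibility
regions (10), each under the distance-based and the 3D-interaction
assignment manner, plus the total promoter contact frequency (1). Category
C3 (3) counts downstream partners (mRNA, miRNA, protein).

Distinct-count semantics: the identity of a distal element is its genomic
region (chrom, start, end); a region observed in several samples counts once
in ``count`` but every per-sample instance contributes to
``constituent_count``. The normalized rank of an element with
descending-signal rank ``r`` in a pool of ``M`` elements is
``(M - r + 1) / M`` (ties take the best rank), so stronger elements score
nearer 1 and ranks are invariant to positive rescaling of all signals.
"""

from __future__ import annotations

import dataclasses
import json
from bisect import bisect_right
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .network import Edge, MultiOmicNetwork

__all__ = [
    "FeatureDescriptor",
    "FeatureSchema",
    "FeatureMatrix",
    "default_schema",
    "CORE_TFS",
    "ACTIVATING_MARKS",
    "tf_count",
    "histone_type_count",
    "site_features",
    "element_features",
    "interaction_frequency",
    "downstream_counts",
    "build_feature_matrix",
]

CORE_TFS = frozenset({"SOX2", "MYC", "NANOG", "OCT4"})
ACTIVATING_MARKS = frozenset({"H3K27ac", "H3K4me3", "H3K4me1", "H3K9ac"})

STATISTICS = {
    "count", "distinct_count", "signal_sum", "signal_max", "signal_mean",
    "signal_mean_norm", "rank_mean", "rank_best", "type_count", "frequency",
    "constituent_count", "promoter_overlap_count", "nearest_distance_norm",
    "frequency_weighted_count", "sample_count",
}
_COUNT_STATS = {
    "count", "distinct_count", "type_count", "constituent_count",
    "promoter_overlap_count", "sample_count",
}
_NORMALIZED_STATS = {"signal_mean_norm", "nearest_distance_norm", "rank_mean", "rank_best"}


@dataclasses.dataclass(frozen=True)
class FeatureDescriptor:
    name: str
    category: str  # C1 | C2 | C3
    subcategory: str
    kind: str  # partner_kind the feature reads, or a pseudo-kind
    manner: str  # "any" when manner-agnostic
    statistic: str

    def __post_init__(self) -> None:
        if self.category not in {"C1", "C2", "C3"}:
            raise ValueError(f"bad category {self.category!r}")
        if self.statistic not in STATISTICS:
            raise ValueError(f"bad statistic {self.statistic!r}")

    @property
    def is_count(self) -> bool:
        return self.statistic in _COUNT_STATS

    @property
    def is_normalized(self) -> bool:
        return self.statistic in _NORMALIZED_STATS


@dataclasses.dataclass(frozen=True)
class FeatureSchema:
    descriptors: tuple[FeatureDescriptor, ...]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        names = [d.name for d in self.descriptors]
        if len(names) != len(set(names)):
            raise ValueError("duplicate feature names in schema")
        if len(self.descriptors) != 57:
            raise ValueError(f"schema must have 57 features, got {len(self.descriptors)}")
        by_cat = self.category_counts()
        if (by_cat.get("C1"), by_cat.get("C2"), by_cat.get("C3")) != (8, 46, 3):
            raise ValueError(f"category counts must be 8/46/3, got {by_cat}")
        sub = self.subcategory_counts()
        expected = {
            "super_enhancer": 12, "enhancer": 23, "accessibility": 10,
            "interaction_3d": 1,
        }
        for k, v in expected.items():
            if sub.get(k) != v:
                raise ValueError(f"subcategory {k} must have {v} features, got {sub.get(k)}")

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.descriptors]

    def category_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for d in self.descriptors:
            out[d.category] = out.get(d.category, 0) + 1
        return out

    def subcategory_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for d in self.descriptors:
            out[d.subcategory] = out.get(d.subcategory, 0) + 1
        return out

    def names_in_subcategory(self, subcategory: str) -> list[str]:
        return [d.name for d in self.descriptors if d.subcategory == subcategory]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump([dataclasses.asdict(d) for d in self.descriptors], fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureSchema":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(tuple(FeatureDescriptor(**d) for d in raw))


def _d(name, category, subcategory, kind, manner, statistic) -> FeatureDescriptor:
    return FeatureDescriptor(name, category, subcategory, kind, manner, statistic)


def default_schema() -> FeatureSchema:
    """The built-in 57-feature schema (8 C1 / 46 C2 / 3 C3)."""
    desc: list[FeatureDescriptor] = [
        # --- C1: promoter-proximal regulators (8) ---
        _d("RiskSNP_num", "C1", "snp", "snp_risk", "proximal", "count"),
        _d("CommonSNP_num", "C1", "snp", "snp_common", "proximal", "count"),
        _d("TF_ChIPnum", "C1", "transcription_factor", "tf_chip", "proximal", "distinct_count"),
        _d("Core_TF_ChIPnum", "C1", "transcription_factor", "tf_chip_core", "proximal", "distinct_count"),
        _d("TF_motifnum", "C1", "transcription_factor", "tf_motif", "proximal", "distinct_count"),
        _d("Meth_site_num", "C1", "methylation", "methylation", "proximal", "count"),
        _d("Meth_signal_norm", "C1", "methylation", "methylation", "proximal", "signal_mean_norm"),
        _d("Histone_act_typenum", "C1", "histone", "histone", "proximal", "type_count"),
    ]
    # --- C2: super-enhancers, 2 manners x 6 statistics (12) ---
    for manner, tag in (("distance_assigned", "rose"), ("chromatin_interaction", "3d")):
        for stat in ("count", "signal_sum", "signal_max", "rank_mean", "rank_best",
                     "constituent_count"):
            desc.append(_d(f"SE_{tag}_{stat}", "C2", "super_enhancer",
                           "enhancer_se", manner, stat))
    # --- C2: typical enhancers, 2 manners x 11 statistics + 1 combined (23) ---
    for manner, tag in (("distance_assigned", "rose"), ("chromatin_interaction", "3d")):
        for stat in ("count", "signal_sum", "signal_max", "signal_mean", "rank_mean",
                     "rank_best", "constituent_count", "promoter_overlap_count",
                     "nearest_distance_norm", "frequency_weighted_count",
                     "sample_count"):
            desc.append(_d(f"TE_{tag}_{stat}", "C2", "enhancer",
                           "enhancer_te", manner, stat))
    desc.append(_d("TE_SE_combined_num", "C2", "enhancer", "te_se_combined",
                   "any", "count"))
    # --- C2: chromatin accessibility, 2 manners x 5 statistics (10) ---
    for manner, tag in (("distance_assigned", "rose"), ("chromatin_interaction", "3d")):
        for stat in ("count", "signal_sum", "signal_max", "rank_mean", "rank_best"):
            desc.append(_d(f"ATAC_{tag}_{stat}", "C2", "accessibility",
                           "atac", manner, stat))
    # --- C2: 3D contact frequency (1) ---
    desc.append(_d("Interaction_freq", "C2", "interaction_3d", "interaction",
                   "chromatin_interaction", "frequency"))
    # --- C3: downstream partners (3) ---
    desc.append(_d("mRNA_num", "C3", "mrna_mirna", "mRNA", "any", "distinct_count"))
    desc.append(_d("miRNA_num", "C3", "mrna_mirna", "miRNA", "any", "distinct_count"))
    desc.append(_d("Protein_num", "C3", "protein", "protein", "any", "distinct_count"))
    return FeatureSchema(tuple(desc))


@dataclasses.dataclass
class FeatureMatrix:
    """lncRNA x feature matrix with its schema; ``data`` rows follow input order."""

    data: pd.DataFrame
    schema: FeatureSchema

    def __post_init__(self) -> None:
        if list(self.data.columns) != self.schema.names:
            raise ValueError("matrix columns do not match schema order")

    def category_of(self, column: str) -> str:
        for d in self.schema.descriptors:
            if d.name == column:
                return d.category
        raise KeyError(column)

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="lncrna_id")

    @classmethod
    def from_tsv(cls, path: str | Path, schema: FeatureSchema | None = None) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col="lncrna_id")
        return cls(df, schema or default_schema())


# ---------------------------------------------------------------------------
# per-lncRNA statistics


def _edges(network: MultiOmicNetwork, lncrna_id: str, kind: str,
           manner: str | None = None) -> list[Edge]:
    return [
        e for e in network.edges_for(lncrna_id)
        if e.partner_kind == kind and (manner is None or e.manner == manner)
    ]


def tf_count(network: MultiOmicNetwork, lncrna_id: str, source: str = "chip_all",
             core_tfs: frozenset[str] = CORE_TFS) -> int:
    """Number of distinct TF identities with at least one promoter edge."""
    if source in ("chip_all", "chip_core"):
        names = {e.partner_id for e in _edges(network, lncrna_id, "tf_chip")}
        if source == "chip_core":
            names &= core_tfs
    elif source == "motif":
        names = {e.partner_id for e in _edges(network, lncrna_id, "tf_motif")}
    else:
        raise ValueError(f"unknown TF source {source!r}")
    return len(names)


def histone_type_count(network: MultiOmicNetwork, lncrna_id: str,
                       activating_marks: frozenset[str] = ACTIVATING_MARKS) -> int:
    """Number of distinct activating histone-mark types at the promoter."""
    marks = {e.partner_id for e in _edges(network, lncrna_id, "histone")}
    return len(marks & activating_marks)


def _region_groups(edges: Sequence[Edge]) -> dict[tuple[str, int, int], list[Edge]]:
    groups: dict[tuple[str, int, int], list[Edge]] = {}
    for e in edges:
        groups.setdefault((e.chrom, e.start, e.end), []).append(e)
    return groups


def site_features(network: MultiOmicNetwork, lncrna_id: str, kind: str) -> tuple[int, float]:
    """(site count, cohort-normalized signal sum) for methylation/SNP kinds.

    The signal sum is divided by the maximum sum over all lncRNAs in the
    network (0 when that maximum is 0). SNP kinds carry no meaningful
    signal; callers use only the count.
    """
    if kind not in {"methylation", "snp_risk", "snp_common"}:
        raise ValueError(f"unsupported site kind {kind!r}")
    regions = _region_groups(_edges(network, lncrna_id, kind))
    count = len(regions)
    total = sum(max(e.signal for e in grp) for grp in regions.values())
    global_max = 0.0
    for other in network.lncrna_ids:
        grp = _region_groups(_edges(network, other, kind))
        s = sum(max(e.signal for e in g) for g in grp.values())
        global_max = max(global_max, s)
    norm = total / global_max if global_max > 0 else 0.0
    return count, norm


class _RankPool:
    """Normalized ranks against a fixed pool of descending-sorted signals."""

    def __init__(self, signals: Sequence[float]):
        self._sorted = sorted(signals)
        self._m = len(self._sorted)

    def normalized_rank(self, signal: float) -> float:
        if self._m == 0:
            return 0.0
        greater = self._m - bisect_right(self._sorted, signal)
        r = 1 + greater  # best rank among ties
        return (self._m - r + 1) / self._m


def _pool_for(network: MultiOmicNetwork, kind: str) -> _RankPool:
    pool = network.element_pools.get(kind)
    if pool is not None:
        return _RankPool([iv.signal for iv in pool])
    # fall back to the union of element regions seen in the edges
    seen: dict[tuple[str, int, int], float] = {}
    for e in network.edges:
        if e.partner_kind == kind:
            key = (e.chrom, e.start, e.end)
            seen[key] = max(seen.get(key, 0.0), e.signal)
    return _RankPool(list(seen.values()))


def element_features(
    network: MultiOmicNetwork,
    lncrna_id: str,
    kind: str,
    manner: str,
    pool: _RankPool | None = None,
) -> dict[str, float]:
    """All distal-element statistics for one (kind, manner) pair.

    Returns every statistic the schema may reference; lncRNAs with no linked
    element get 0 for everything and ``nearest_distance`` = nan (normalized
    cohort-wide later).
    """
    edges = _edges(network, lncrna_id, kind, manner)
    regions = _region_groups(edges)
    if pool is None:
        pool = _pool_for(network, kind)
    if not regions:
        return {
            "count": 0, "signal_sum": 0.0, "signal_max": 0.0, "signal_mean": 0.0,
            "rank_mean": 0.0, "rank_best": 0.0, "constituent_count": 0,
            "promoter_overlap_count": 0, "nearest_distance": float("nan"),
            "frequency_weighted_count": 0.0, "sample_count": 0,
        }
    signals = [max(e.signal for e in grp) for grp in regions.values()]
    ranks = [pool.normalized_rank(s) for s in signals]
    return {
        "count": len(regions),
        "signal_sum": float(sum(signals)),
        "signal_max": float(max(signals)),
        "signal_mean": float(sum(signals) / len(signals)),
        "rank_mean": float(sum(ranks) / len(ranks)),
        "rank_best": float(max(ranks)),
        "constituent_count": len(edges),
        "promoter_overlap_count": sum(
            1 for grp in regions.values() if any(e.overlaps_promoter for e in grp)
        ),
        "nearest_distance": float(min(e.distance for e in edges)),
        "frequency_weighted_count": float(sum(e.frequency for e in edges)),
        "sample_count": len({e.sample_id for e in edges}),
    }


def interaction_frequency(network: MultiOmicNetwork, lncrna_id: str) -> float:
    """Summed 3D-contact frequency of anchor pairs touching the promoter."""
    return float(sum(e.frequency for e in _edges(network, lncrna_id, "interaction")))


def downstream_counts(network: MultiOmicNetwork, lncrna_id: str) -> tuple[int, int, int]:
    """Distinct (mRNA, miRNA, protein) partner counts."""
    return (
        len({e.partner_id for e in _edges(network, lncrna_id, "mRNA")}),
        len({e.partner_id for e in _edges(network, lncrna_id, "miRNA")}),
        len({e.partner_id for e in _edges(network, lncrna_id, "protein")}),
    )


def build_feature_matrix(
    network: MultiOmicNetwork,
    lncrnas: Sequence[str] | None = None,
    schema: FeatureSchema | None = None,
    core_tfs: frozenset[str] = CORE_TFS,
    activating_marks: frozenset[str] = ACTIVATING_MARKS,
) -> FeatureMatrix:
    """Compute the full feature matrix; deterministic given the network.

    Missing regulators yield 0 (never NaN). Cohort-relative normalizations
    (methylation signal, nearest enhancer distance) are min-max over the
    lncRNAs being featurized.
    """
    if schema is None:
        schema = default_schema()
    schema.validate()
    ids = list(lncrnas) if lncrnas is not None else list(network.lncrna_ids)

    pools = {k: _pool_for(network, k) for k in ("enhancer_se", "enhancer_te", "atac")}
    element_kinds = [
        ("enhancer_se", "distance_assigned"), ("enhancer_se", "chromatin_interaction"),
        ("enhancer_te", "distance_assigned"), ("enhancer_te", "chromatin_interaction"),
        ("atac", "distance_assigned"), ("atac", "chromatin_interaction"),
    ]
    stats: dict[tuple[str, str], list[dict[str, float]]] = {
        km: [] for km in element_kinds
    }
    # methylation count + signal sum per lncRNA, normalized by the cohort max
    meth_counts: list[int] = []
    meth_raw: list[float] = []
    for lid in ids:
        grp = _region_groups(_edges(network, lid, "methylation"))
        meth_counts.append(len(grp))
        meth_raw.append(sum(max(e.signal for e in g) for g in grp.values()))
    meth_max = max(meth_raw, default=0.0)
    meth_sums = [s / meth_max if meth_max > 0 else 0.0 for s in meth_raw]

    rows_basic: list[dict[str, float]] = []
    for lid in ids:
        for km in element_kinds:
            stats[km].append(element_features(network, lid, km[0], km[1], pools[km[0]]))
        n_mrna, n_mirna, n_protein = downstream_counts(network, lid)
        te_se_regions = {
            (e.chrom, e.start, e.end)
            for e in network.edges_for(lid)
            if e.partner_kind in ("enhancer_te", "enhancer_se")
        }
        rows_basic.append({
            "RiskSNP_num": len(_region_groups(_edges(network, lid, "snp_risk"))),
            "CommonSNP_num": len(_region_groups(_edges(network, lid, "snp_common"))),
            "TF_ChIPnum": tf_count(network, lid, "chip_all", core_tfs),
            "Core_TF_ChIPnum": tf_count(network, lid, "chip_core", core_tfs),
            "TF_motifnum": tf_count(network, lid, "motif"),
            "Histone_act_typenum": histone_type_count(network, lid, activating_marks),
            "Interaction_freq": interaction_frequency(network, lid),
            "mRNA_num": n_mrna,
            "miRNA_num": n_mirna,
            "Protein_num": n_protein,
            "TE_SE_combined_num": len(te_se_regions),
        })

    # cohort normalization of nearest distances per (kind, manner)
    dist_norm: dict[tuple[str, str], list[float]] = {}
    for km in element_kinds:
        dists = [s["nearest_distance"] for s in stats[km]]
        finite = [d for d in dists if d == d]  # not NaN
        dmax = max(finite) if finite else 0.0
        vals = []
        for d in dists:
            if d != d:
                vals.append(0.0)
            elif dmax == 0:
                vals.append(1.0)
            else:
                vals.append(1.0 - d / dmax)
        dist_norm[km] = vals

    tag_for = {"distance_assigned": "rose", "chromatin_interaction": "3d"}
    prefix_for = {"enhancer_se": "SE", "enhancer_te": "TE", "atac": "ATAC"}
    records: list[dict[str, float]] = []
    for i, lid in enumerate(ids):
        row = dict(rows_basic[i])
        row["Meth_site_num"] = meth_counts[i]
        row["Meth_signal_norm"] = meth_sums[i]
        for kind, manner in element_kinds:
            tag = tag_for[manner]
            pre = prefix_for[kind]
            s = stats[(kind, manner)][i]
            for stat, val in s.items():
                if stat == "nearest_distance":
                    row[f"{pre}_{tag}_nearest_distance_norm"] = dist_norm[(kind, manner)][i]
                else:
                    row[f"{pre}_{tag}_{stat}"] = val
        records.append(row)

    df = pd.DataFrame.from_records(records, index=pd.Index(ids, name="lncrna_id"))
    df = df[schema.names]
    for d in schema.descriptors:
        if d.is_count:
            df[d.name] = df[d.name].astype(np.int64)
        else:
            df[d.name] = df[d.name].astype(float)
    if df.isna().any().any():
        raise AssertionError("feature matrix contains missing values")
    return FeatureMatrix(df, schema)
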