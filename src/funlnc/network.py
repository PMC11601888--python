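"""Assembly of the heterogeneous lncRNA regulatory network.

Upstream edges connect lncRNA promoters to interval-level regulators either
by direct overlap (``proximal``), by distance to externally produced
enhancer calls (``distance_assigned``), or through 3D-contact anchor pairs
(``chromatin_interaction``). Downstream edges come from curated pair tables
(``targeted``/``annotated``). Partner identity is the element's BED name, so
multi-sample peaks of the same regulator collapse in distinct counts while
remaining separate edges.
"""

from __future__ import annotations

import dataclasses
import json
from collections import Counter
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .genomic_io import AnchorPair, GenomicInterval, LncRNAGene, PairRow, overlaps

__all__ = [
    "Edge",
    "MultiOmicNetwork",
    "UPSTREAM_KINDS",
    "DOWNSTREAM_KINDS",
    "assign_proximal",
    "assign_by_interaction",
    "assign_distance",
    "promoter_interactions",
    "build_downstream",
    "integrate",
    "write_edges",
    "read_edges",
]

UPSTREAM_KINDS = {
    "tf_chip",
    "tf_motif",
    "histone",
    "methylation",
    "snp_risk",
    "snp_common",
    "enhancer_te",
    "enhancer_se",
    "atac",
    "interaction",
}
DOWNSTREAM_KINDS = {"mRNA", "miRNA", "protein"}

ALLOWED_MANNERS: dict[str, frozenset[str]] = {
    **{
        k: frozenset({"proximal", "distance_assigned", "chromatin_interaction"})
        for k in UPSTREAM_KINDS
    },
    "mRNA": frozenset({"targeted"}),
    "miRNA": frozenset({"targeted"}),
    "protein": frozenset({"annotated"}),
}


@dataclasses.dataclass(frozen=True)
class Edge:
    """One typed, provenance-carrying regulatory edge.

    ``frequency`` is the summed 3D-contact frequency for interaction-assigned
    edges and 1.0 otherwise; ``distance`` is |element midpoint - TSS| (-1 for
    downstream edges); ``overlaps_promoter`` records direct promoter overlap.
    """

    lncrna_id: str
    partner_id: str
    partner_kind: str
    manner: str
    sample_id: str = "."
    signal: float = 1.0
    frequency: float = 1.0
    distance: float = -1.0
    overlaps_promoter: bool = False
    chrom: str = "."
    start: int = -1
    end: int = -1

    def __post_init__(self) -> None:
        if self.partner_kind not in ALLOWED_MANNERS:
            raise ValueError(f"unknown partner_kind {self.partner_kind!r}")
        if self.manner not in ALLOWED_MANNERS[self.partner_kind]:
            raise ValueError(
                f"manner {self.manner!r} not allowed for kind {self.partner_kind!r}"
            )

    @property
    def key(self) -> tuple:
        """Identity used for global deduplication."""
        return (
            self.lncrna_id,
            self.partner_id,
            self.partner_kind,
            self.manner,
            self.sample_id,
            self.chrom,
            self.start,
            self.end,
        )


def _element_edge(
    gene: LncRNAGene,
    element: GenomicInterval,
    kind: str,
    manner: str,
    sample_id: str,
    frequency: float = 1.0,
) -> Edge:
    tss_pos = gene.tss.start
    return Edge(
        lncrna_id=gene.id,
        partner_id=element.name,
        partner_kind=kind,
        manner=manner,
        sample_id=sample_id,
        signal=element.signal,
        frequency=frequency,
        distance=abs(element.midpoint - (tss_pos + 0.5)),
        overlaps_promoter=overlaps(gene.promoter, element),
        chrom=element.chrom,
        start=element.start,
        end=element.end,
    )


def _require_promoters(promoters: Sequence[LncRNAGene]) -> None:
    missing = [g.id for g in promoters if g.promoter is None]
    if missing:
        raise ValueError(f"genes without derived promoters: {missing[:5]}")


def assign_proximal(
    promoters: Sequence[LncRNAGene],
    elements: Sequence[GenomicInterval],
    kind: str,
    sample_id: str = ".",
) -> list[Edge]:
    """One ``proximal`` edge per (lncRNA, element) with overlapping intervals."""
    if kind not in UPSTREAM_KINDS:
        raise ValueError(f"unknown upstream kind {kind!r}")
    _require_promoters(promoters)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for el in elements:
        by_chrom.setdefault(el.chrom, []).append(el)
    edges: list[Edge] = []
    for gene in promoters:
        promoter = gene.promoter
        for el in by_chrom.get(promoter.chrom, ()):
            if el.start < promoter.end and promoter.start < el.end:
                edges.append(_element_edge(gene, el, kind, "proximal", sample_id))
    return edges


def assign_by_interaction(
    promoters: Sequence[LncRNAGene],
    elements: Sequence[GenomicInterval],
    anchor_pairs: Sequence[AnchorPair],
    kind: str,
    sample_id: str = ".",
) -> list[Edge]:
    """Link elements to promoters through opposite anchors of contact pairs.

    A (lncRNA, element) pair connected by several distinct anchor pairs
    collapses to a single edge whose ``frequency`` is the sum of the pair
    frequencies (each pair counted once even if both orientations match).
    """
    if kind not in UPSTREAM_KINDS:
        raise ValueError(f"unknown upstream kind {kind!r}")
    _require_promoters(promoters)
    # (gene index, element index) -> set of supporting pair indices
    support: dict[tuple[int, int], set[int]] = {}
    for pi, pair in enumerate(anchor_pairs):
        for first, second in ((pair.anchor_a, pair.anchor_b), (pair.anchor_b, pair.anchor_a)):
            hit_elements = [ei for ei, el in enumerate(elements) if overlaps(el, first)]
            if not hit_elements:
                continue
            for gi, gene in enumerate(promoters):
                if overlaps(gene.promoter, second):
                    for ei in hit_elements:
                        support.setdefault((gi, ei), set()).add(pi)
    edges: list[Edge] = []
    for (gi, ei), pair_ids in sorted(support.items()):
        freq = sum(anchor_pairs[pi].frequency for pi in pair_ids)
        edges.append(
            _element_edge(
                promoters[gi], elements[ei], kind, "chromatin_interaction",
                sample_id, frequency=freq,
            )
        )
    return edges


def assign_distance(
    promoters: Sequence[LncRNAGene],
    enhancer_calls: Sequence[GenomicInterval],
    kind: str,
    sample_id: str = ".",
    max_dist: int = 50_000,
) -> list[Edge]:
    """Assign enhancer/accessibility calls within ``max_dist`` of the TSS.

    An element is linked when its midpoint lies within ``max_dist`` of the
    TSS or when it overlaps the promoter outright.
    """
    if max_dist <= 0:
        raise ValueError(f"max_dist must be > 0, got {max_dist}")
    if kind not in UPSTREAM_KINDS:
        raise ValueError(f"unknown upstream kind {kind!r}")
    _require_promoters(promoters)
    edges: list[Edge] = []
    for gene in promoters:
        tss_mid = gene.tss.start + 0.5
        for el in enhancer_calls:
            if el.chrom != gene.tss.chrom:
                continue
            if abs(el.midpoint - tss_mid) <= max_dist or overlaps(gene.promoter, el):
                edges.append(
                    _element_edge(gene, el, kind, "distance_assigned", sample_id)
                )
    return edges


def promoter_interactions(
    promoters: Sequence[LncRNAGene],
    anchor_pairs: Sequence[AnchorPair],
    sample_id: str = ".",
) -> list[Edge]:
    """One ``interaction`` edge per (lncRNA, anchor pair) touching the promoter."""
    _require_promoters(promoters)
    edges: list[Edge] = []
    for pi, pair in enumerate(anchor_pairs):
        name = pair.name if pair.name != "." else f"pair_{pi}"
        for gene in promoters:
            if overlaps(gene.promoter, pair.anchor_a) or overlaps(
                gene.promoter, pair.anchor_b
            ):
                edges.append(
                    Edge(
                        lncrna_id=gene.id,
                        partner_id=name,
                        partner_kind="interaction",
                        manner="chromatin_interaction",
                        sample_id=sample_id,
                        signal=pair.frequency,
                        frequency=pair.frequency,
                    )
                )
    return edges


def build_downstream(pair_rows: Iterable[PairRow]) -> list[Edge]:
    """Turn deduplicated pair-table rows into downstream edges."""
    manner_for = {"mRNA": "targeted", "miRNA": "targeted", "protein": "annotated"}
    seen: set[tuple[str, str, str]] = set()
    edges: list[Edge] = []
    for row in pair_rows:
        key = (row.lncrna_id, row.partner_id, row.partner_kind)
        if key in seen:
            continue
        seen.add(key)
        edges.append(
            Edge(
                lncrna_id=row.lncrna_id,
                partner_id=row.partner_id,
                partner_kind=row.partner_kind,
                manner=manner_for[row.partner_kind],
            )
        )
    return edges


@dataclasses.dataclass
class MultiOmicNetwork:
    """The integrated network plus the global element pools used for ranking."""

    lncrna_ids: list[str]
    edges: list[Edge]
    element_pools: dict[str, list[GenomicInterval]] = dataclasses.field(
        default_factory=dict
    )

    @property
    def partner_ids(self) -> set[str]:
        return {e.partner_id for e in self.edges}

    @property
    def kind_counts(self) -> dict[str, int]:
        return dict(Counter(e.partner_kind for e in self.edges))

    @property
    def manner_counts(self) -> dict[str, int]:
        return dict(Counter(e.manner for e in self.edges))

    def edges_for(self, lncrna_id: str) -> list[Edge]:
        if lncrna_id not in self._edge_index:
            if lncrna_id not in set(self.lncrna_ids):
                raise KeyError(f"unknown lncRNA id {lncrna_id!r}")
            return []
        return self._edge_index[lncrna_id]

    def __post_init__(self) -> None:
        self._edge_index: dict[str, list[Edge]] = {}
        for e in self.edges:
            self._edge_index.setdefault(e.lncrna_id, []).append(e)

    def summary(self) -> dict:
        return {
            "n_lncrnas": len(self.lncrna_ids),
            "n_partners": len(self.partner_ids),
            "n_edges": len(self.edges),
            "edges_per_kind": self.kind_counts,
            "edges_per_manner": self.manner_counts,
        }


def integrate(
    edge_lists: Iterable[Sequence[Edge]],
    lncrna_ids: Sequence[str] | None = None,
    element_pools: Mapping[str, Sequence[GenomicInterval]] | None = None,
) -> MultiOmicNetwork:
    """Union of edge lists with global dedup by edge identity.

    Idempotent and order-independent: the resulting edge list is sorted by
    edge key. ``lncrna_ids`` fixes the node set (lncRNAs with no edges stay
    in the network and featurize to all-zero rows); when omitted it is taken
    from the edges.
    """
    dedup: dict[tuple, Edge] = {}
    for edges in edge_lists:
        for e in edges:
            dedup.setdefault(e.key, e)
    merged = [dedup[k] for k in sorted(dedup)]
    if lncrna_ids is None:
        ids = sorted({e.lncrna_id for e in merged})
    else:
        ids = list(lncrna_ids)
    pools = {k: list(v) for k, v in (element_pools or {}).items()}
    return MultiOmicNetwork(lncrna_ids=ids, edges=merged, element_pools=pools)


_EDGE_COLUMNS = [
    "lncrna_id", "partner_id", "partner_kind", "manner", "sample_id",
    "signal", "frequency", "distance", "overlaps_promoter",
    "chrom", "start", "end",
]


def write_edges(network: MultiOmicNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_EDGE_COLUMNS) + "\n")
        for e in network.edges:
            fh.write(
                f"{e.lncrna_id}\t{e.partner_id}\t{e.partner_kind}\t{e.manner}\t"
                f"{e.sample_id}\t{e.signal:g}\t{e.frequency:g}\t{e.distance:g}\t"
                f"{int(e.overlaps_promoter)}\t{e.chrom}\t{e.start}\t{e.end}\n"
            )


def read_edges(
    path: str | Path, lncrna_ids: Sequence[str] | None = None
) -> MultiOmicNetwork:
    edges: list[Edge] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _EDGE_COLUMNS:
            raise ValueError(f"{path}: unexpected edge-list header")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            edges.append(
                Edge(
                    lncrna_id=f[0], partner_id=f[1], partner_kind=f[2], manner=f[3],
                    sample_id=f[4], signal=float(f[5]), frequency=float(f[6]),
                    distance=float(f[7]), overlaps_promoter=bool(int(f[8])),
                    chrom=f[9], start=int(f[10]), end=int(f[11]),
                )
            )
    return integrate([edges], lncrna_ids=lncrna_ids)


def write_summary(network: MultiOmicNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(network.summary(), fh, indent=2, sort_keys=True)
        fh.write("\n")
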