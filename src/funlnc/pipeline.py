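"""End-to-end orchestration: inputs -> network -> features -> model -> scores."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Mapping, Sequence

from . import __version__
from .classifier import (
    LabeledSet,
    cluster_by_similarity,
    evaluate,
    fit_model,
    predict_and_label,
    split_grouped,
    split_random,
)
from .features import build_feature_matrix, default_schema
from .genomic_io import (
    AnchorPair,
    GenomicInterval,
    LncRNAGene,
    PairRow,
    derive_promoters,
    read_bed,
    read_bedpe,
    read_fasta,
    read_genes_bed,
    read_pair_table,
)
from .network import (
    MultiOmicNetwork,
    assign_by_interaction,
    assign_distance,
    assign_proximal,
    build_downstream,
    integrate,
    promoter_interactions,
    write_edges,
    write_summary,
)
from .permscore import call_hc, random_probabilities, records_to_frame, score_records
from .synthetic import DISTAL_KINDS, PROXIMAL_KINDS, SimBundle

__all__ = ["RunConfig", "build_network", "network_from_bundle", "run_pipeline", "read_labels"]


def build_network(
    genes: Sequence[LncRNAGene],
    elements: Mapping[str, Sequence[GenomicInterval]],
    anchors: Sequence[AnchorPair] = (),
    pair_rows: Sequence[PairRow] = (),
    sample_ids: Mapping[str, str] | None = None,
    max_dist: int = 50_000,
) -> MultiOmicNetwork:
    """Assemble the full network from validated inputs.

    Proximal kinds are assigned by promoter overlap; distal kinds
    (enhancer_te / enhancer_se / atac) by distance AND through contact
    anchors, in parallel. ``genes`` must carry derived promoters.
    """
    sample_ids = dict(sample_ids or {})
    edge_lists = []
    for kind in PROXIMAL_KINDS:
        els = elements.get(kind, ())
        if els:
            edge_lists.append(
                assign_proximal(genes, els, kind, sample_ids.get(kind, "s1"))
            )
    for kind in DISTAL_KINDS:
        els = elements.get(kind, ())
        if not els:
            continue
        sid = sample_ids.get(kind, "s1")
        edge_lists.append(assign_distance(genes, els, kind, sid, max_dist))
        if anchors:
            edge_lists.append(assign_by_interaction(genes, els, anchors, kind, sid))
    if anchors:
        edge_lists.append(promoter_interactions(genes, anchors))
    if pair_rows:
        edge_lists.append(build_downstream(pair_rows))
    pools = {k: list(elements.get(k, ())) for k in DISTAL_KINDS}
    return integrate(edge_lists, lncrna_ids=[g.id for g in genes], element_pools=pools)


def network_from_bundle(
    bundle: SimBundle, window: int = 2000, max_dist: int = 50_000
) -> MultiOmicNetwork:
    genes = derive_promoters(bundle.genes, window)
    return build_network(
        genes, bundle.elements, bundle.anchors, bundle.pair_rows, max_dist=max_dist
    )


def read_labels(path: str | Path) -> LabeledSet:
    """Read a two-column TSV ``lncrna_id  label`` (1 = positive)."""
    pos, neg = [], []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["lncrna_id", "label"]:
            raise ValueError(f"{path}: expected header 'lncrna_id\\tlabel'")
        for line in fh:
            if not line.strip():
                continue
            lid, lab = line.rstrip("\n").split("\t")[:2]
            (pos if int(lab) == 1 else neg).append(lid)
    return LabeledSet(tuple(pos), tuple(neg))


def read_supplementary_sets(path: str | Path) -> LabeledSet:
    """Read a curated training-set table into a LabeledSet.

    Expects a TSV with header columns ``lncrna_id`` and ``set`` where set is
    ``positive`` or ``negative`` (case-insensitive); duplicate ids within a
    set are collapsed.
    """
    pos: list[str] = []
    neg: list[str] = []
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        header = [c.strip().lower() for c in fh.readline().rstrip("\n").split("\t")]
        try:
            id_col = header.index("lncrna_id")
            set_col = header.index("set")
        except ValueError as exc:
            raise ValueError(
                f"{path}: expected columns 'lncrna_id' and 'set'"
            ) from exc
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            lid = fields[id_col].strip()
            side = fields[set_col].strip().lower()
            if side not in ("positive", "negative"):
                raise ValueError(f"{path}:{lineno}: unknown set {side!r}")
            if not lid or (lid, side) in seen:
                continue
            seen.add((lid, side))
            (pos if side == "positive" else neg).append(lid)
    return LabeledSet(tuple(pos), tuple(neg))


@dataclasses.dataclass
class RunConfig:
    lncrnas: str
    elements: dict[str, str]  # kind -> BED path
    interactions: str | None = None
    pairs: str | None = None
    sequences: str | None = None
    labels: str | None = None
    promoter_window: int = 2000
    max_dist: int = 50_000
    split_mode: str = "random"  # random | grouped
    train_frac: float = 0.8
    cv_folds: int = 10
    n_trees: int = 500
    threshold: float = 0.5
    B: int = 1000
    score_mode: str = "safe"
    score_threshold: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        paths = [self.lncrnas, *self.elements.values()]
        for p in (self.interactions, self.pairs, self.sequences, self.labels):
            if p is not None:
                paths.append(p)
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input paths: {missing}")
        if self.split_mode not in ("random", "grouped"):
            raise ValueError(f"unknown split_mode {self.split_mode!r}")
        if self.split_mode == "grouped" and self.sequences is None:
            raise ValueError("grouped split requires sequences")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_pipeline(config: RunConfig, outdir: str | Path, log=print) -> Path:
    """Run all stages and emit the artifact set plus a manifest.

    Artifacts: network edge list + summary, feature matrix, trained model
    directory, evaluation report, prediction + score table, manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.validate()
    t0 = time.time()

    def stage(name):
        log(f"[{time.time() - t0:7.1f}s] {name}")

    stage("build-network")
    genes = derive_promoters(read_genes_bed(config.lncrnas), config.promoter_window)
    elements = {k: read_bed(p, kind=k) for k, p in config.elements.items()}
    anchors = read_bedpe(config.interactions) if config.interactions else []
    pair_rows = read_pair_table(config.pairs) if config.pairs else []
    network = build_network(
        genes, elements, anchors, pair_rows, max_dist=config.max_dist
    )
    write_edges(network, outdir / "network_edges.tsv")
    write_summary(network, outdir / "network_summary.json")

    stage("featurize")
    matrix = build_feature_matrix(network, schema=default_schema())
    matrix.to_tsv(outdir / "feature_matrix.tsv")

    if config.labels is None:
        raise ValueError("run_pipeline requires labels; use predict for unlabeled data")
    labeled = read_labels(config.labels)
    labeled.require_in(matrix)

    stage("train")
    if config.split_mode == "grouped":
        seqs = read_fasta(config.sequences)
        clusters = cluster_by_similarity({i: seqs[i] for i in labeled.ids})
        train, test = split_grouped(labeled, clusters, config.train_frac, config.seed)
    else:
        train, test = split_random(labeled, config.train_frac, config.seed)
    model = fit_model(
        matrix, train, cv_folds=config.cv_folds, seed=config.seed,
        n_trees=config.n_trees,
    )
    model.save(outdir / "model")

    records = predict_and_label(model, matrix, config.threshold)
    truth = dict(labeled.labels())
    test_records = [r for r in records if r.lncrna_id in set(test.ids)]
    report = evaluate(test_records, truth, config.threshold) if test.ids else None
    with open(outdir / "evaluation.json", "w") as fh:
        json.dump(report.to_dict() if report else None, fh, indent=2)

    stage("permscore")
    r = random_probabilities(model, matrix, B=config.B, seed=config.seed)
    scored = call_hc(
        score_records(records, r, config.score_mode), config.score_threshold
    )
    records_to_frame(scored).to_csv(outdir / "predictions.tsv", sep="\t")

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "artifacts": [
            "network_edges.tsv", "network_summary.json", "feature_matrix.tsv",
            "model", "evaluation.json", "predictions.tsv",
        ],
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    stage("done")
    return outdir
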