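"""Self-contained synthetic data with the class structure the pipeline assumes.

Functional lncRNAs receive more regulator elements (Poisson rates per kind)
with stronger signals (log-normal) than nonfunctional ones; a configurable
fraction of distal elements is wired to the promoter through contact anchor
pairs; downstream partner degrees are Poisson per class. Everything is
plain-text (BED/BEDPE/TSV/FASTA) and byte-identical under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .genomic_io import (
    AnchorPair,
    GenomicInterval,
    LncRNAGene,
    PairRow,
    derive_promoters,
    write_bed,
    write_bedpe,
    write_fasta,
    write_pair_table,
)

__all__ = ["SimConfig", "SimBundle", "simulate_dataset", "worked_micro_example"]

PROXIMAL_KINDS = ("tf_chip", "tf_motif", "histone", "methylation", "snp_risk", "snp_common")
DISTAL_KINDS = ("enhancer_te", "enhancer_se", "atac")
DOWNSTREAM_KINDS = ("mRNA", "miRNA", "protein")

_TF_POOL = ["SOX2", "MYC", "NANOG", "OCT4"] + [f"TF{i:02d}" for i in range(5, 31)]
_ACT_MARKS = ["H3K27ac", "H3K4me3", "H3K4me1", "H3K9ac"]
_REP_MARKS = ["H3K27me3", "H3K9me3"]


def _default_rates() -> dict[str, tuple[float, float]]:
    # kind -> (lambda_positive, lambda_negative)
    return {
        "tf_chip": (8.0, 2.0),
        "tf_motif": (4.0, 2.0),
        "histone": (8.0, 2.0),
        "methylation": (3.0, 3.0),
        "snp_risk": (1.0, 1.0),
        "snp_common": (2.0, 2.0),
        "enhancer_te": (8.0, 2.0),
        "enhancer_se": (2.0, 0.5),
        "atac": (4.0, 2.0),
        "mRNA": (5.0, 1.0),
        "miRNA": (2.0, 0.5),
        "protein": (2.0, 0.5),
    }


@dataclasses.dataclass
class SimConfig:
    n_lncrnas: int = 200
    positive_fraction: float = 0.5
    genome_size: int = 50_000_000
    promoter_window: int = 2000
    rates: dict[str, tuple[float, float]] = dataclasses.field(default_factory=_default_rates)
    signal_mu: tuple[float, float] = (1.0, 0.0)  # log-normal mean (pos, neg)
    signal_sigma: float = 0.5
    interaction_fraction: float = 0.5
    interaction_freq_lambda: float = 2.0
    seq_length: int = 400
    kmer: int = 8
    n_dup_clusters: int = 5
    dup_cluster_size: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.n_lncrnas < 2:
            raise ValueError("n_lncrnas must be >= 2")
        if not 0 < self.positive_fraction < 1:
            raise ValueError("positive_fraction must be in (0, 1)")
        for kind, (lp, ln) in self.rates.items():
            if lp < 0 or ln < 0:
                raise ValueError(f"negative rate for kind {kind!r}")
        spacing = self.genome_size // (self.n_lncrnas + 1)
        if spacing < 2 * self.promoter_window + 100_000:
            raise ValueError(
                "genome_size too small for n_lncrnas: promoters and distal "
                "elements would collide"
            )
        if not 0 <= self.interaction_fraction <= 1:
            raise ValueError("interaction_fraction must be in [0, 1]")
        if self.n_dup_clusters * self.dup_cluster_size > self.n_lncrnas:
            raise ValueError("duplicate clusters exceed the number of lncRNAs")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = json.load(fh)
        raw["rates"] = {k: tuple(v) for k, v in raw["rates"].items()}
        raw["signal_mu"] = tuple(raw["signal_mu"])
        return cls(**raw)


@dataclasses.dataclass
class SimBundle:
    """In-memory counterpart of the on-disk fixture bundle."""

    config: SimConfig
    genes: list[LncRNAGene]
    labels: dict[str, int]
    elements: dict[str, list[GenomicInterval]]
    anchors: list[AnchorPair]
    pair_rows: list[PairRow]
    sequences: dict[str, str]

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        gene_ivs = [
            GenomicInterval(
                g.tss.chrom, g.tss.start, g.tss.start + 1000, g.strand, g.id, 1.0
            )
            if g.strand in ("+", ".")
            else GenomicInterval(
                g.tss.chrom, max(0, g.tss.end - 1000), g.tss.end, g.strand, g.id, 1.0
            )
            for g in self.genes
        ]
        write_bed(gene_ivs, outdir / "lncrnas.bed")
        for kind, ivs in self.elements.items():
            write_bed(ivs, outdir / f"{kind}.bed")
        write_bedpe(self.anchors, outdir / "interactions.bedpe")
        write_pair_table(self.pair_rows, outdir / "pairs.tsv")
        write_fasta(self.sequences, outdir / "sequences.fasta")
        with open(outdir / "labels.tsv", "w") as fh:
            fh.write("lncrna_id\tlabel\n")
            for g in self.genes:
                fh.write(f"{g.id}\t{self.labels[g.id]}\n")
        self.config.to_json(outdir / "config.json")
        return outdir


def _signal(rng: np.random.Generator, mu: float, sigma: float) -> float:
    return float(np.round(rng.lognormal(mu, sigma), 4))


def simulate_dataset(config: SimConfig, outdir: str | Path | None = None) -> SimBundle:
    """Generate the fixture bundle; writes it to ``outdir`` when given."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_lncrnas
    n_pos = round(config.positive_fraction * n)
    spacing = config.genome_size // (n + 1)
    window = config.promoter_window

    genes: list[LncRNAGene] = []
    labels: dict[str, int] = {}
    class_of: list[int] = [1] * n_pos + [0] * (n - n_pos)
    rng.shuffle(class_of)
    for i in range(n):
        gid = f"lnc{i:04d}"
        tss_pos = (i + 1) * spacing + int(rng.integers(-spacing // 8, spacing // 8))
        strand = "+" if rng.random() < 0.5 else "-"
        tss = GenomicInterval("chr1", tss_pos, tss_pos + 1, strand, f"{gid}_tss")
        genes.append(LncRNAGene(id=gid, tss=tss, strand=strand))
        labels[gid] = class_of[i]
    genes_p = derive_promoters(genes, window)

    elements: dict[str, list[GenomicInterval]] = {k: [] for k in PROXIMAL_KINDS + DISTAL_KINDS}
    anchors: list[AnchorPair] = []
    pair_rows: list[PairRow] = []
    counters = {k: 0 for k in elements}

    for g in genes_p:
        z = labels[g.id]
        mu = config.signal_mu[0] if z else config.signal_mu[1]
        tss = g.tss.start
        for kind in PROXIMAL_KINDS:
            lam = config.rates[kind][0] if z else config.rates[kind][1]
            count = int(rng.poisson(lam))
            for _ in range(count):
                counters[kind] += 1
                if kind in ("methylation", "snp_risk", "snp_common"):
                    width = 1
                else:
                    width = int(rng.integers(150, 400))
                lo = max(0, tss - window)
                hi = max(lo + 1, tss + window - width)
                start = int(rng.integers(lo, hi))
                if kind == "tf_chip":
                    pool = _TF_POOL[:10] if z else _TF_POOL[8:]
                    name = pool[int(rng.integers(len(pool)))]
                elif kind == "tf_motif":
                    name = _TF_POOL[int(rng.integers(len(_TF_POOL)))]
                elif kind == "histone":
                    if rng.random() < (0.9 if z else 0.2):
                        name = _ACT_MARKS[int(rng.integers(len(_ACT_MARKS)))]
                    else:
                        name = _REP_MARKS[int(rng.integers(len(_REP_MARKS)))]
                else:
                    name = f"{kind}_{counters[kind]:05d}"
                elements[kind].append(
                    GenomicInterval(
                        "chr1", start, start + width, ".", name,
                        _signal(rng, mu, config.signal_sigma),
                    )
                )
        for kind in DISTAL_KINDS:
            lam = config.rates[kind][0] if z else config.rates[kind][1]
            count = int(rng.poisson(lam))
            for _ in range(count):
                counters[kind] += 1
                width = int(rng.integers(5000, 20000)) if kind == "enhancer_se" else int(
                    rng.integers(500, 2000)
                )
                dist = int(rng.integers(5000, 40000))
                side = 1 if rng.random() < 0.5 else -1
                start = max(0, tss + side * dist - width // 2)
                el = GenomicInterval(
                    "chr1", start, start + width, ".",
                    f"{kind}_{counters[kind]:05d}",
                    _signal(rng, mu, config.signal_sigma),
                )
                elements[kind].append(el)
                if rng.random() < config.interaction_fraction:
                    freq = 1.0 + float(rng.poisson(config.interaction_freq_lambda))
                    mid = (el.start + el.end) // 2
                    anchors.append(
                        AnchorPair(
                            GenomicInterval("chr1", max(0, mid - 500), mid + 500),
                            GenomicInterval(
                                "chr1", max(0, tss - window // 2), tss + window // 2
                            ),
                            freq,
                            f"pair_{len(anchors):05d}",
                        )
                    )
        for kind in DOWNSTREAM_KINDS:
            lam = config.rates[kind][0] if z else config.rates[kind][1]
            degree = int(rng.poisson(lam))
            partners = rng.choice(2000, size=min(degree, 2000), replace=False)
            prefix = {"mRNA": "gene", "miRNA": "mir", "protein": "prot"}[kind]
            for p in partners:
                pair_rows.append(PairRow(g.id, f"{prefix}{int(p):05d}", kind))

    # sequences: random, with identical-sequence clusters for split tests
    alphabet = np.array(list("ACGT"))
    sequences: dict[str, str] = {}
    for g in genes:
        seq = "".join(alphabet[rng.integers(0, 4, size=config.seq_length)])
        sequences[g.id] = seq
    idx = 0
    for _ in range(config.n_dup_clusters):
        ref = genes[idx].id
        for j in range(1, config.dup_cluster_size):
            sequences[genes[idx + j].id] = sequences[ref]
        idx += config.dup_cluster_size

    bundle = SimBundle(
        config=config,
        genes=genes,
        labels=labels,
        elements=elements,
        anchors=anchors,
        pair_rows=pair_rows,
        sequences=sequences,
    )
    if outdir is not None:
        bundle.write(outdir)
    return bundle


def worked_micro_example() -> SimBundle:
    """Three hand-specified lncRNAs covering every input kind.

    lncA carries regulators of every kind (2 core TF ChIP peaks, 1 motif,
    2 activating marks, 2 methylation sites, 1 risk SNP, 2 TEs, 1 SE,
    1 accessible region, 1 contact pair of frequency 3, and 2/1/1
    downstream partners); lncB has a sparse non-core complement; lncC has
    nothing and featurizes to an all-zero row.
    """
    gi = GenomicInterval
    genes = [
        LncRNAGene("lncA", gi("chr1", 100_000, 100_001, "+", "lncA_tss"), "+"),
        LncRNAGene("lncB", gi("chr1", 500_000, 500_001, "-", "lncB_tss"), "-"),
        LncRNAGene("lncC", gi("chr1", 900_000, 900_001, "+", "lncC_tss"), "+"),
    ]
    elements = {
        "tf_chip": [
            gi("chr1", 99_000, 99_200, ".", "SOX2", 5.0),
            gi("chr1", 99_500, 99_700, ".", "NANOG", 3.0),
            gi("chr1", 499_100, 499_300, ".", "TP53", 2.0),  # lncB, non-core
        ],
        "tf_motif": [gi("chr1", 99_000, 99_010, ".", "MYC", 1.0)],
        "histone": [
            gi("chr1", 98_100, 98_300, ".", "H3K4me3", 4.0),
            gi("chr1", 98_400, 98_600, ".", "H3K27ac", 2.0),
            gi("chr1", 499_500, 499_700, ".", "H3K27me3", 3.0),  # non-activating
        ],
        "methylation": [
            gi("chr1", 99_900, 99_901, ".", "meth_1", 1.0),
            gi("chr1", 100_100, 100_101, ".", "meth_2", 2.0),
        ],
        "snp_risk": [gi("chr1", 100_500, 100_501, ".", "rs0001", 1.0)],
        "snp_common": [gi("chr1", 499_000, 499_001, ".", "rs0002", 1.0)],
        "enhancer_te": [
            gi("chr1", 120_000, 121_000, ".", "te_1", 10.0),
            gi("chr1", 95_000, 95_500, ".", "te_2", 4.0),
        ],
        "enhancer_se": [gi("chr1", 130_000, 140_000, ".", "se_1", 50.0)],
        "atac": [
            gi("chr1", 99_800, 100_500, ".", "atac_1", 6.0),
            gi("chr1", 520_000, 520_800, ".", "atac_2", 2.0),
        ],
    }
    anchors = [
        AnchorPair(
            gi("chr1", 120_200, 120_700), gi("chr1", 99_000, 99_500), 3.0, "pairA"
        )
    ]
    pair_rows = [
        PairRow("lncA", "gene001", "mRNA"),
        PairRow("lncA", "gene002", "mRNA"),
        PairRow("lncA", "mir001", "miRNA"),
        PairRow("lncA", "prot001", "protein"),
        PairRow("lncB", "gene003", "mRNA"),
    ]
    sequences = {
        "lncA": "ACGT" * 100,
        "lncB": "ACGT" * 100,  # identical to lncA: same split cluster
        "lncC": "TTGCA" * 80,
    }
    config = SimConfig(n_lncrnas=3, genome_size=3_000_000)
    return SimBundle(
        config=config,
        genes=genes,
        labels={"lncA": 1, "lncB": 0, "lncC": 0},
        elements=elements,
        anchors=anchors,
        pair_rows=pair_rows,
        sequences=sequences,
    )
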