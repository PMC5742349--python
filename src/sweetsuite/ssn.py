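"""Protein sequence similarity networks (SSNs).

Nodes are proteins; an edge joins two proteins whose pairwise local-alignment
e-value passes a cutoff (default 1e-55). Scores come from exact
Smith-Waterman alignment (BLOSUM62, affine gaps) with Karlin-Altschul
statistics: bitscore = (lambda * S - ln K) / ln 2 and evalue = m * n *
2**(-bitscore), where m is the query length and n the total residue count of
the search space. Connected components of the thresholded graph are the
clusters; those with at least ``min_cluster_size`` members are labelled
1, 2, ... by decreasing size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices

from .records import ProteinRecord

#: Gapped Karlin-Altschul constants for BLOSUM62 with gap open 11 / extend 1.
DEFAULT_LAMBDA = 0.267
DEFAULT_K = 0.041


@dataclass(frozen=True)
class SimilarityParams:
    """Scoring parameters for pairwise similarity.

    Gap convention: a gap of length g costs ``gap_open + (g - 1) *
    gap_extend``. ``database_size`` (total subject residues) overrides the
    subject length in the e-value search space when set.
    """

    substitution_matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    karlin_lambda: float = DEFAULT_LAMBDA
    karlin_k: float = DEFAULT_K
    database_size: Optional[int] = None

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.karlin_lambda <= 0 or self.karlin_k <= 0:
            raise ValueError("Karlin-Altschul constants must be positive")

    def aligner(self, mode: str = "local") -> PairwiseAligner:
        aligner = PairwiseAligner()
        aligner.mode = mode
        aligner.substitution_matrix = substitution_matrices.load(
            self.substitution_matrix
        )
        aligner.open_gap_score = -float(self.gap_open)
        aligner.extend_gap_score = -float(self.gap_extend)
        return aligner


@dataclass(frozen=True)
class SimilarityEdge:
    """Unordered similarity edge, stored with id_a < id_b."""

    id_a: str
    id_b: str
    raw_score: float
    bitscore: float
    evalue: float
    percent_identity: float
    alignment_length: int


def _bitscore(raw: float, params: SimilarityParams) -> float:
    return (params.karlin_lambda * raw - math.log(params.karlin_k)) / math.log(2)


def pairwise_similarity(
    a: ProteinRecord, b: ProteinRecord, params: SimilarityParams | None = None
) -> SimilarityEdge:
    """Exact Smith-Waterman similarity between two records.

    Identity is counted over the columns of one optimal local alignment
    (including internal gap columns). An all-negative pairing yields the
    empty alignment: raw score 0, identity 0, e-value m*n*2**(-bitscore(0)).
    """
    params = params or SimilarityParams()
    id_a, id_b = sorted((a.accession, b.accession))
    if id_a == a.accession:
        qa, qb = a, b
    else:
        qa, qb = b, a
    aligner = params.aligner("local")
    raw = float(aligner.score(qa.sequence, qb.sequence))
    if raw > 0:
        aln = aligner.align(qa.sequence, qb.sequence)[0]
        counts = aln.counts()
        identities = counts.identities
        length = counts.identities + counts.mismatches + counts.internal_gaps
        pct = 100.0 * identities / length if length else 0.0
    else:
        raw = 0.0
        pct = 0.0
        length = 0
    bits = _bitscore(raw, params)
    m = len(qa.sequence)
    n = params.database_size if params.database_size is not None else len(qb.sequence)
    evalue = m * n * math.pow(2.0, -bits)
    return SimilarityEdge(
        id_a=id_a,
        id_b=id_b,
        raw_score=raw,
        bitscore=bits,
        evalue=evalue,
        percent_identity=pct,
        alignment_length=length,
    )


@dataclass
class SSNGraph:
    """Similarity network: records, kept edges, components, labels."""

    records: dict[str, ProteinRecord]
    edges: list[SimilarityEdge]
    clusters: list[frozenset[str]] = field(default_factory=list)
    labels: dict[int, int] = field(default_factory=dict)  # cluster idx -> label
    composition: dict[int, dict[str, float]] = field(default_factory=dict)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for acc, rec in self.records.items():
            g.add_node(acc, taxon_group=rec.taxon_group)
        for e in self.edges:
            g.add_edge(
                e.id_a,
                e.id_b,
                bitscore=e.bitscore,
                evalue=e.evalue,
                pct_identity=e.percent_identity,
            )
        return g

    def edge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (e.id_a, e.id_b, e.bitscore, e.evalue, e.percent_identity)
                for e in self.edges
            ],
            columns=["id_a", "id_b", "bitscore", "evalue", "pct_identity"],
        )

    def membership_table(self) -> pd.DataFrame:
        rows = []
        for i, cluster in enumerate(self.clusters):
            label = self.labels.get(i)
            for acc in sorted(cluster):
                rows.append((acc, i, label if label is not None else pd.NA))
        return pd.DataFrame(rows, columns=["accession", "component", "label"]).astype(
            {"label": "Int64"}
        )

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph(), str(path))


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def build_network(
    records: Sequence[ProteinRecord],
    params: SimilarityParams | None = None,
    evalue_cutoff: float = 1e-55,
    kmer_prefilter: int | None = None,
) -> SSNGraph:
    """All-vs-all similarity graph thresholded at ``evalue_cutoff``.

    The search space for every pair is query length x total residue count of
    the input set (BLAST-like convention). With ``kmer_prefilter=k``, pairs
    sharing no k-mer are skipped (their exact e-value cannot realistically
    pass any stringent cutoff); the default is the exact all-pairs scan.
    """
    if len(records) < 2:
        raise ValueError("build_network requires at least 2 records")
    if evalue_cutoff <= 0:
        raise ValueError("evalue_cutoff must be positive")
    params = params or SimilarityParams()
    total_residues = sum(len(r) for r in records)
    params = SimilarityParams(
        substitution_matrix=params.substitution_matrix,
        gap_open=params.gap_open,
        gap_extend=params.gap_extend,
        karlin_lambda=params.karlin_lambda,
        karlin_k=params.karlin_k,
        database_size=total_residues,
    )
    kmers = (
        {r.accession: _kmer_set(r.sequence, kmer_prefilter) for r in records}
        if kmer_prefilter
        else None
    )
    edges = []
    ordered = sorted(records, key=lambda r: r.accession)
    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            if kmers is not None and not (kmers[a.accession] & kmers[b.accession]):
                continue
            edge = pairwise_similarity(a, b, params)
            if edge.evalue <= evalue_cutoff:
                edges.append(edge)
    graph = SSNGraph(records={r.accession: r for r in records}, edges=edges)
    g = graph.graph()
    components = [frozenset(c) for c in nx.connected_components(g)]
    graph.clusters = sorted(components, key=lambda c: (-len(c), min(c)))
    return graph


def label_clusters(graph: SSNGraph, min_cluster_size: int = 10) -> SSNGraph:
    """Label clusters of size >= ``min_cluster_size`` sequentially by
    decreasing size (ties by smallest member accession) and tabulate their
    taxonomic composition as fractions summing to 1."""
    if min_cluster_size < 1:
        raise ValueError("min_cluster_size must be >= 1")
    graph.labels = {}
    graph.composition = {}
    label = 1
    for i, cluster in enumerate(graph.clusters):
        if len(cluster) < min_cluster_size:
            continue
        graph.labels[i] = label
        counts: dict[str, int] = {}
        for acc in cluster:
            tg = graph.records[acc].taxon_group
            counts[tg] = counts.get(tg, 0) + 1
        graph.composition[i] = {
            tg: c / len(cluster) for tg, c in sorted(counts.items())
        }
        label += 1
    return graph
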