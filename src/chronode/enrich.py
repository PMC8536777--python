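"""GO over-representation, redundancy reduction, semantic term clustering.

Fisher (hypergeometric tail) enrichment per module with an optional module
membership (kME) filter; a three-criterion redundancy filter; a hybrid
semantic distance mixing ancestor-set Jaccard (ontology) with
module-restricted gene-set Jaccard; DBSCAN clustering over the precomputed
distances; and representative selection by the x-value statistic,
x = -log10(p) * sum of the per-gene differential-expression (BIC) scores of
the term's member genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import DBSCAN


@dataclass
class AnnotationSet:
    """term -> gene set mapping plus optional ontology parent graph."""
    term_genes: dict
    universe: set
    ontology: "nx.MultiDiGraph | nx.DiGraph | None" = None
    term_names: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.universe = set(self.universe)
        self.term_genes = {t: set(g) & self.universe for t, g in self.term_genes.items()}
        if self.ontology is not None and not nx.is_directed_acyclic_graph(self.ontology):
            raise ValueError("ontology graph must be acyclic")

    def ancestors(self, term: str) -> set:
        """Self-inclusive ancestor set; empty if the term is not in the ontology."""
        if self.ontology is None or term not in self.ontology:
            return set()
        return {term} | nx.descendants(self.ontology, term)  # edges point child -> parent


def read_gmt(path) -> dict:
    """Parse a GMT file: term <tab> description <tab> gene ...  -> two dicts."""
    term_genes, term_names = {}, {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        term_genes[parts[0]] = set(parts[2:])
        term_names[parts[0]] = parts[1]
    return term_genes, term_names


def load_annotation(gmt_path, universe, obo_path=None) -> AnnotationSet:
    term_genes, term_names = read_gmt(gmt_path)
    graph = None
    if obo_path is not None:
        import obonet
        graph = obonet.read_obo(obo_path)
    return AnnotationSet(term_genes=term_genes, universe=universe,
                         ontology=graph, term_names=term_names)


def x_value(p: float, sigma_bic: float) -> float:
    """Representative-selection statistic: -log10(p) times the summed BIC."""
    return -np.log10(p) * sigma_bic


@dataclass
class EnrichedTerm:
    term: str
    overlap: int
    module_size: int
    annotated: int
    universe: int
    p_value: float
    member_genes: tuple
    sigma_bic: float = 0.0

    @property
    def xvalue(self) -> float:
        return x_value(self.p_value, self.sigma_bic)


def fisher_enrichment(module_genes, annotation: AnnotationSet, p_cutoff: float = 0.01,
                      kme: pd.Series | None = None, kme_min: float = 0.6,
                      gene_scores: pd.Series | None = None) -> list[EnrichedTerm]:
    """One-sided over-representation test per annotated term.

    The p-value is the hypergeometric upper tail of the 2x2 table
    (module & annotated, module only, annotated only, rest).  ``kme``
    restricts the module to genes with membership >= ``kme_min``;
    ``gene_scores`` supplies the per-gene BIC scores summed into sigma_bic.
    """
    genes = set(module_genes)
    if kme is not None:
        genes = {g for g in genes if g in kme.index and kme[g] >= kme_min}
    genes &= annotation.universe
    if not genes:
        return []
    M = len(annotation.universe)
    n_mod = len(genes)
    out = []
    for term, ann in annotation.term_genes.items():
        k_ann = len(ann)
        if k_ann == 0:
            continue
        members = genes & ann
        k = len(members)
        if k == 0:
            continue  # p = 1 by the one-sided tail; never significant
        p = float(stats.hypergeom.sf(k - 1, M, k_ann, n_mod))
        p = min(max(p, np.nextafter(0, 1)), 1.0)
        if p > p_cutoff:
            continue
        sigma = float(gene_scores.reindex(sorted(members)).fillna(0.0).sum()) \
            if gene_scores is not None else 0.0
        out.append(EnrichedTerm(term=term, overlap=k, module_size=n_mod,
                                annotated=k_ann, universe=M, p_value=p,
                                member_genes=tuple(sorted(members)), sigma_bic=sigma))
    out.sort(key=lambda e: (e.p_value, e.term))
    return out


def reduce_redundancy(terms: list[EnrichedTerm], min_overlap: int = 5,
                      module_frac: float = 0.15,
                      background_frac: float = 0.15) -> list[EnrichedTerm]:
    """Keep a term iff it meets at least one of three coverage criteria:
    (1) >= min_overlap module genes annotated, (2) the overlap covers
    >= module_frac of the module, or (3) the overlap covers
    >= background_frac of the term's background-annotated genes."""
    kept = []
    for e in terms:
        c1 = e.overlap >= min_overlap
        c2 = e.overlap >= module_frac * e.module_size
        c3 = e.overlap >= background_frac * e.annotated
        if c1 or c2 or c3:
            kept.append(e)
    return kept


def term_distance(term_i: EnrichedTerm, term_j: EnrichedTerm,
                  annotation: AnnotationSet, w: float = 0.5) -> float:
    """Hybrid semantic distance in [0, 1].

    1 - [w * Jaccard(ancestor sets) + (1-w) * Jaccard(module gene sets)];
    a term absent from the ontology contributes an ancestor Jaccard of 0.
    """
    def jaccard(a: set, b: set) -> float:
        if not a and not b:
            return 0.0
        u = len(a | b)
        return len(a & b) / u if u else 0.0

    anc_i = annotation.ancestors(term_i.term)
    anc_j = annotation.ancestors(term_j.term)
    j_anc = jaccard(anc_i, anc_j)
    j_gene = jaccard(set(term_i.member_genes), set(term_j.member_genes))
    return float(np.clip(1.0 - (w * j_anc + (1.0 - w) * j_gene), 0.0, 1.0))


def distance_matrix(terms: list[EnrichedTerm], annotation: AnnotationSet,
                    w: float = 0.5) -> np.ndarray:
    n = len(terms)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = term_distance(terms[i], terms[j], annotation, w)
    return D


@dataclass
class TermCluster:
    cluster_id: int
    members: tuple            # EnrichedTerm
    representative: EnrichedTerm


def cluster_terms(terms: list[EnrichedTerm], distances: np.ndarray,
                  eps: float = 0.7, min_pts: int = 2) -> list[TermCluster]:
    """DBSCAN over the precomputed distances; noise terms become singleton
    clusters.  The representative is the member with the highest x-value
    (ties: smaller p, then lexicographic term id)."""
    if not terms:
        return []
    if len(terms) == 1:
        return [TermCluster(0, (terms[0],), terms[0])]
    labels = DBSCAN(eps=eps, min_samples=min_pts,
                    metric="precomputed").fit_predict(distances)
    clusters: dict = {}
    next_singleton = labels.max() + 1 if (labels >= 0).any() else 0
    for term, lab in zip(terms, labels):
        if lab == -1:
            clusters[next_singleton] = [term]
            next_singleton += 1
        else:
            clusters.setdefault(int(lab), []).append(term)
    out = []
    for cid in sorted(clusters):
        members = clusters[cid]
        rep = min(members, key=lambda e: (-e.xvalue, e.p_value, e.term))
        out.append(TermCluster(cluster_id=cid, members=tuple(members), representative=rep))
    return out


def enrichment_table(clusters: list[TermCluster], term_names: dict | None = None) -> pd.DataFrame:
    rows = []
    for cl in clusters:
        for e in cl.members:
            rows.append({
                "cluster": cl.cluster_id, "term": e.term,
                "name": (term_names or {}).get(e.term, ""),
                "overlap": e.overlap, "annotated": e.annotated,
                "module_size": e.module_size, "p_value": e.p_value,
                "sigma_bic": e.sigma_bic, "x_value": e.xvalue,
                "representative": int(e.term == cl.representative.term),
            })
    return pd.DataFrame(rows)
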