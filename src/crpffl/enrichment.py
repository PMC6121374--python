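"""Hypergeometric GO-term over-representation for gene groups.

For a group of n genes drawn from a universe of N genes, K of which carry
a term, the chance of seeing at least k carriers in the group is the
upper tail of the hypergeometric distribution,

    P(X >= k) = sum_{i=k..min(n,K)} C(K,i) C(N-K, n-i) / C(N, n).

Terms with P <= 0.01 (no multiple-testing correction, configurable) are
called over-represented.  Annotations arrive as a slim GAF-like TSV
(gene, term, namespace); when a term-parent table is supplied,
annotations are propagated up the ontology so that a gene annotated to a
leaf also counts toward every ancestor term (true-path rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
from scipy.stats import hypergeom

__all__ = [
    "AnnotationSet",
    "EnrichmentResult",
    "read_annotations",
    "read_term_parents",
    "propagate_annotations",
    "hypergeometric_p",
    "enrich_group",
    "write_enrichment",
]


@dataclass
class AnnotationSet:
    """gene -> GO term ids, with optional term names and is_a parent links."""

    gene2terms: dict[str, set[str]]
    term_names: dict[str, str] = field(default_factory=dict)
    parents: dict[str, set[str]] | None = None

    def carriers(self, term: str, universe: set[str] | None = None) -> set[str]:
        hit = {g for g, ts in self.gene2terms.items() if term in ts}
        return hit if universe is None else hit & universe

    def terms(self) -> set[str]:
        out: set[str] = set()
        for ts in self.gene2terms.values():
            out |= ts
        return out


@dataclass(frozen=True)
class EnrichmentResult:
    """One term's over-representation outcome for one gene group."""

    term: str
    name: str
    k: int  # carriers in the study group
    n: int  # study group size
    K: int  # carriers in the universe
    N: int  # universe size
    p_value: float
    significant: bool
    study_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.n, self.K) and self.n <= self.N and self.K <= self.N):
            raise ValueError(f"inconsistent margins k={self.k} n={self.n} K={self.K} N={self.N}")


def read_annotations(
    path: str | Path, *, namespace: str | None = "biological_process"
) -> AnnotationSet:
    """Read a slim annotation TSV: gene, term[, namespace[, term name]].

    Rows whose namespace column disagrees with ``namespace`` are skipped
    (pass ``None`` to keep everything); ``#`` lines are comments.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"annotation file not found: {path}")
    gene2terms: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    with path.open() as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = [f.strip() for f in line.rstrip("\n").split("\t")]
            if len(fields) < 2:
                raise ValueError(f"annotation row needs >=2 fields: {line!r}")
            gene, term = fields[0], fields[1]
            if namespace is not None and len(fields) > 2 and fields[2] and fields[2] != namespace:
                continue
            gene2terms.setdefault(gene, set()).add(term)
            if len(fields) > 3 and fields[3]:
                names[term] = fields[3]
    return AnnotationSet(gene2terms, names)


def read_term_parents(path: str | Path) -> dict[str, set[str]]:
    """Read a child-parent term table (TSV: child, parent)."""
    parents: dict[str, set[str]] = {}
    with Path(path).open() as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            child, parent = line.rstrip("\n").split("\t")[:2]
            parents.setdefault(child.strip(), set()).add(parent.strip())
    return parents


def propagate_annotations(ann: AnnotationSet) -> AnnotationSet:
    """Close every gene's term set under the ancestor relation (idempotent)."""
    if ann.parents is None:
        return ann
    dag = nx.DiGraph()
    for child, ps in ann.parents.items():
        for p in ps:
            dag.add_edge(child, p)
    try:
        cycle = nx.find_cycle(dag)
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle:
        raise ValueError(f"term parent relation contains a cycle through {cycle[0][0]!r}")
    ancestors = {t: nx.descendants(dag, t) for t in dag}  # parents point upward
    closed = {
        g: set().union(ts, *(ancestors.get(t, set()) for t in ts))
        for g, ts in ann.gene2terms.items()
    }
    return replace(ann, gene2terms=closed)


def hypergeometric_p(k: int, n: int, K: int, N: int) -> float:
    """Exact upper-tail probability P(X >= k) for the 2x2 margins (k, n, K, N)."""
    if not (0 <= k <= min(n, K) and 0 <= n <= N and 0 <= K <= N):
        raise ValueError(f"inconsistent margins k={k} n={n} K={K} N={N}")
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich_group(
    genes: set[str],
    universe: set[str],
    ann: AnnotationSet,
    max_p: float = 0.01,
) -> list[EnrichmentResult]:
    """Test every term hit by the group; sort by ascending p then term id.

    Genes without annotations still count toward the group size n and the
    universe size N.  Carriers are counted within the universe only.
    """
    offenders = sorted(genes - universe)
    if offenders:
        raise ValueError(f"study genes outside the universe: {offenders}")
    results: list[EnrichmentResult] = []
    n, N = len(genes), len(universe)
    terms = {t for g in genes for t in ann.gene2terms.get(g, set())}
    for term in sorted(terms):
        carriers = ann.carriers(term, universe)
        hits = sorted(carriers & genes)
        k, K = len(hits), len(carriers)
        if k == 0:
            continue
        p = hypergeometric_p(k, n, K, N)
        results.append(
            EnrichmentResult(
                term=term,
                name=ann.term_names.get(term, ""),
                k=k, n=n, K=K, N=N,
                p_value=p,
                significant=p <= max_p,
                study_genes=tuple(hits),
            )
        )
    results.sort(key=lambda r: (r.p_value, r.term))
    return results


def write_enrichment(results: list[EnrichmentResult], path: str | Path) -> None:
    """Results TSV: term, name, p-value, gene counts and member genes."""
    with Path(path).open("w") as fh:
        fh.write("term\tname\tp_value\tk\tn\tK\tN\tsignificant\tgenes\n")
        for r in results:
            fh.write(
                f"{r.term}\t{r.name}\t{r.p_value:.6g}\t{r.k}\t{r.n}\t{r.K}\t{r.N}"
                f"\t{int(r.significant)}\t{','.join(r.study_genes)}\n"
            )
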