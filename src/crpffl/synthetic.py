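"""Seeded generators for every input the pipeline consumes.

No public microarray accession exists for the cAMP dose-response data the
analysis was designed around, so the package ships generators that
emulate each input with known ground truth:

* a signed regulatory network with a master TF and a *planted* FFL-type
  composition (the planted instances are returned as a ledger and are,
  by construction, exactly the FFLs the network contains);
* a log2 expression matrix over the cAMP dose grid whose genes follow
  the five canonical dose-response shapes plus i.i.d. Gaussian noise;
* annotation sets in which one term per gene group is planted at a
  multiple of the background annotation rate.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clustering import SHAPES
from .doseresponse import DOSE_GRID, ExpressionMatrix
from .enrichment import AnnotationSet
from .motif import FFL_TYPES, SIGNS_TO_TYPE, FFLInstance, classify_signs
from .regnet import SignedRegulatoryNetwork, canonical

__all__ = [
    "SyntheticNetworkSpec",
    "SyntheticExpressionSpec",
    "GenerationError",
    "generate_network",
    "generate_expression",
    "generate_annotations",
]

_TYPE_SIGNS = {t: s for s, t in SIGNS_TO_TYPE.items()}


class GenerationError(RuntimeError):
    """A generator spec that cannot be satisfied."""


@dataclass(frozen=True)
class SyntheticNetworkSpec:
    """Planted composition of a master-TF regulatory network."""

    master: str = "crp"
    type_counts: dict[str, int] = field(default_factory=dict)
    decoy_edges: int = 0
    multi_y_fraction: float = 0.0
    seed: int = 0
    avoid_triangles: bool = True

    def __post_init__(self) -> None:
        unknown = set(self.type_counts) - set(FFL_TYPES)
        if unknown:
            raise ValueError(f"unknown FFL types: {sorted(unknown)}")
        if any(c < 0 for c in self.type_counts.values()):
            raise ValueError("planted counts must be >= 0")
        if not 0.0 <= self.multi_y_fraction <= 1.0:
            raise ValueError("multi_y_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticExpressionSpec:
    """Planted dose-response composition of an expression matrix."""

    dose_grid: tuple[float, ...] = DOSE_GRID
    shape_counts: dict[str, int] = field(default_factory=dict)
    amplitude: float = 2.0
    noise_sd: float = 0.1
    replicates: int = 2
    baseline: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.shape_counts) - set(SHAPES)
        if unknown:
            raise ValueError(f"unknown shapes: {sorted(unknown)}")
        if self.dose_grid[0] != 0.0 or any(
            b <= a for a, b in zip(self.dose_grid, self.dose_grid[1:])
        ):
            raise ValueError("dose grid must start at 0 and be strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")

    @property
    def n_genes(self) -> int:
        return sum(self.shape_counts.values())


def _would_form_triangle(
    edges: dict[tuple[str, str], int], m: str, u: str, v: str
) -> bool:
    """Would adding edge u->v create a (master, y, z) triangle?"""
    if u == m:
        # v as new z: any y with m->y and y->v
        if any(a != m and (m, a) in edges for (a, b) in edges if b == v):
            return True
        # v as new y: any z with v->z and m->z
        if any((m, b) in edges for (a, b) in edges if a == v and b != m):
            return True
        return False
    if (m, u) in edges:  # u is a master-regulated TF; u->v closes if m->v exists
        return (m, v) in edges
    return False


def generate_network(
    spec: SyntheticNetworkSpec,
) -> tuple[SignedRegulatoryNetwork, list[FFLInstance]]:
    """Build a signed network containing exactly the planted FFL instances.

    Each planted instance gets a fresh intermediate TF and target gene, so
    planted triangles never interfere.  With probability
    ``multi_y_fraction`` a planted target receives a second, fresh
    intermediate TF (making its loops multi-Y); the extra triangle's type
    is recorded in the ledger.  Decoy edges are sampled so that they never
    complete an unplanned triangle (unless ``avoid_triangles`` is off).
    """
    rng = np.random.default_rng(spec.seed)
    m = canonical(spec.master)
    net = SignedRegulatoryNetwork()
    net.display[m] = spec.master.strip()
    net.tfs.add(m)
    ledger: list[FFLInstance] = []
    serial = 0

    def fresh(prefix: str) -> str:
        nonlocal serial
        serial += 1
        name = f"{prefix}{serial:04d}"
        net.display[name] = name
        return name

    def add_edge(u: str, v: str, sign: int) -> None:
        net.edges[(u, v)] = sign
        net.tfs.add(u)

    for t in FFL_TYPES:
        s_xy, s_yz, s_xz = _TYPE_SIGNS[t]
        for _ in range(spec.type_counts.get(t, 0)):
            y, z = fresh("tf"), fresh("g")
            add_edge(m, y, s_xy)
            add_edge(y, z, s_yz)
            add_edge(m, z, s_xz)
            ledger.append(FFLInstance(spec.master, y, z, s_xy, s_yz, s_xz, t))
            if rng.random() < spec.multi_y_fraction:
                y2 = fresh("tf")
                s2_xy = int(rng.choice([-1, 1]))
                s2_yz = int(rng.choice([-1, 1]))
                add_edge(m, y2, s2_xy)
                add_edge(y2, z, s2_yz)
                ledger.append(
                    FFLInstance(spec.master, y2, z, s2_xy, s2_yz, s_xz,
                                classify_signs(s2_xy, s2_yz, s_xz))
                )

    for _ in range(spec.decoy_edges):
        for _attempt in range(200):
            kind = rng.integers(0, 3)
            sign = int(rng.choice([-1, 1]))
            tf_pool = sorted(net.tfs)
            gene_pool = sorted(net.nodes - {m})
            if kind == 0:  # master -> fresh orphan gene
                u, v = m, fresh("dg")
            elif kind == 1 and gene_pool:  # random TF -> random existing node
                u = tf_pool[int(rng.integers(0, len(tf_pool)))]
                v = gene_pool[int(rng.integers(0, len(gene_pool)))]
            else:  # fresh TF -> fresh gene (never a CRP triangle)
                u, v = fresh("dtf"), fresh("dg")
                net.tfs.add(u)
            if u == v or (u, v) in net.edges:
                if kind == 0 or kind == 2:
                    continue
                continue
            if spec.avoid_triangles and _would_form_triangle(net.edges, m, u, v):
                continue
            add_edge(u, v, sign)
            break
        else:
            raise GenerationError("could not place a decoy edge without a triangle")

    net.validate()
    return net, ledger


def base_shape(shape: str, dose: np.ndarray, amplitude: float) -> np.ndarray:
    """Noise-free log2FC of one canonical shape over positive doses (mM)."""
    d = np.asarray(dose, dtype=float)
    a = amplitude
    if shape == "saturating_up":
        return a * (1.0 - np.exp(-d / 0.05))
    if shape == "sigmoid_threshold":
        return a / (1.0 + (0.3 / d) ** 2)
    if shape == "monotone_down":
        return np.clip(-a * np.log10(d / 0.01) / 3.0, -a, 0.0)
    if shape == "bell":
        return a * np.exp(-(np.log10(d / 0.2) ** 2) / 0.5)
    if shape == "inverse_bell":
        return -base_shape("bell", d, a)
    raise ValueError(f"unknown shape {shape!r}")


def generate_expression(
    spec: SyntheticExpressionSpec,
    genes: list[str] | None = None,
) -> tuple[ExpressionMatrix, dict[str, str]]:
    """Expression matrix with known true shapes per gene.

    Absolute log2 expression is ``baseline + shape(dose) + noise`` with
    zero-dose columns at ``baseline + noise``; replicate noise is i.i.d.
    Gaussian on the log2 scale.  Returns the matrix and the gene -> true
    shape map.
    """
    n = spec.n_genes
    if genes is None:
        genes = [f"g{i:03d}" for i in range(n)]
    if len(genes) != n:
        raise ValueError(f"need {n} gene names, got {len(genes)}")
    rng = np.random.default_rng(spec.seed)
    pos = np.array([d for d in spec.dose_grid if d > 0])
    truth: dict[str, str] = {}
    shape_rows = []
    i = 0
    for shape in SHAPES:
        for _ in range(spec.shape_counts.get(shape, 0)):
            truth[genes[i]] = shape
            shape_rows.append(base_shape(shape, pos, spec.amplitude))
            i += 1
    profile = np.vstack(shape_rows) if shape_rows else np.empty((0, pos.size))

    samples = [(d, r + 1) for d in spec.dose_grid for r in range(spec.replicates)]
    values = np.empty((n, len(samples)))
    for j, (d, _r) in enumerate(samples):
        mean = spec.baseline + (0.0 if d == 0 else profile[:, pos.tolist().index(d)])
        values[:, j] = mean + rng.normal(0.0, spec.noise_sd, size=n)
    return ExpressionMatrix(genes=list(genes), samples=samples, values=values), truth


def generate_annotations(
    groups: dict[str, str],
    n_terms: int = 20,
    enrich_factor: float = 5.0,
    background_rate: float = 0.1,
    seed: int = 0,
    universe: list[str] | None = None,
) -> tuple[AnnotationSet, dict[str, str]]:
    """Annotations with one term planted into each gene group.

    ``groups`` maps genes to group labels; genes in ``universe`` but not
    in ``groups`` are background-only.  Background terms annotate every
    gene at ``background_rate``; each group's designated term annotates
    its members at ``min(1, enrich_factor * background_rate)`` and
    everyone else at the background rate.  Returns the annotation set and
    the group -> designated term map.
    """
    if enrich_factor < 1:
        raise ValueError("enrich_factor must be >= 1")
    if not 0.0 < background_rate < 1.0:
        raise ValueError("background_rate must be in (0, 1)")
    rng = np.random.default_rng(seed)
    all_genes = sorted(set(groups) | set(universe or []))
    gene2terms: dict[str, set[str]] = {g: set() for g in all_genes}
    names: dict[str, str] = {}

    for i in range(n_terms):
        term = f"GO:1{i:06d}"
        names[term] = f"background term {i}"
        mask = rng.random(len(all_genes)) < background_rate
        for g, hit in zip(all_genes, mask):
            if hit:
                gene2terms[g].add(term)

    planted_rate = min(1.0, enrich_factor * background_rate)
    designated: dict[str, str] = {}
    for j, grp in enumerate(sorted({v for v in groups.values()})):
        term = f"GO:2{j:06d}"
        names[term] = f"planted term for group {grp}"
        designated[grp] = term
        draws = rng.random(len(all_genes))
        for g, u in zip(all_genes, draws):
            rate = planted_rate if groups.get(g) == grp else background_rate
            if u < rate:
                gene2terms[g].add(term)

    return AnnotationSet({g: t for g, t in gene2terms.items() if t}, names), designated
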