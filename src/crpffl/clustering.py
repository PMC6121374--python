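"""Hierarchical grouping of dose-response profiles and profile-shape labeling.

Profiles are compared by Pearson correlation (distance ``1 - r``) and
grouped by average-linkage agglomerative clustering, separately for
single-Y and multi-Y FFL target genes (group labels SG1..SGk and
MG1..MGk).  Each group's mean profile is assigned one of five canonical
dose-response shapes observed for cAMP-CRP targets:

* ``saturating_up``   — rises from trace cAMP doses and plateaus by ~1 mM
  (central-metabolism behaviour);
* ``sigmoid_threshold`` — switch-like rise that only takes off above
  ~0.3 mM cAMP (catabolite-repression-style transporters);
* ``monotone_down``   — log-linear decrease with dose (CRP acting as a
  repressor);
* ``bell``            — peak at intermediate doses (~0.1-0.3 mM), the
  signature of opposing regulatory arms;
* ``inverse_bell``    — trough at intermediate doses.

Single-Y and multi-Y groups with similar mean profiles are merged into
functional groups (FG1..FGn) used downstream as gene sets for GO
enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.stats import pearsonr

from .doseresponse import DoseResponseProfile
from .motif import FFLInstance

log = logging.getLogger(__name__)

__all__ = [
    "ShapeConfig",
    "ProfileGroup",
    "FunctionalGroup",
    "correlation_distance",
    "hierarchical_groups",
    "label_shape",
    "build_profile_groups",
    "group_cohesion",
    "merge_functional_groups",
    "silhouette_k",
]

SHAPES = ("saturating_up", "sigmoid_threshold", "monotone_down", "bell", "inverse_bell")


def correlation_distance(p: Sequence[float], q: Sequence[float]) -> float:
    """Pearson correlation distance ``1 - r`` in [0, 2].

    A zero-variance vector carries no shape information; its distance to
    anything (itself included) is defined as 1 and logged.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"length mismatch: {p.size} vs {q.size}")
    if p.std() == 0.0 or q.std() == 0.0:
        log.debug("zero-variance profile in correlation_distance; distance := 1")
        return 1.0
    r = float(np.corrcoef(p, q)[0, 1])
    return float(np.clip(1.0 - r, 0.0, 2.0))


def _condensed_distances(mat: np.ndarray) -> np.ndarray:
    n = mat.shape[0]
    out = np.empty(n * (n - 1) // 2)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            out[k] = correlation_distance(mat[i], mat[j])
            k += 1
    return out


def hierarchical_groups(
    profiles: list[DoseResponseProfile], k: int
) -> tuple[dict[str, int], np.ndarray, list[str]]:
    """Average-linkage clustering on correlation distance, cut to exactly k groups.

    Profiles are processed in lexicographic gene order, which makes the
    result invariant to the input permutation.  Flat groups are relabeled
    1..k by descending member count (ties broken by the smallest gene
    name), so group 1 is always the largest.

    Returns (gene -> group index, linkage matrix, gene order used).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(profiles):
        raise ValueError(f"k={k} exceeds the number of profiles ({len(profiles)})")
    order = sorted(profiles, key=lambda p: p.gene)
    genes = [p.gene for p in order]
    mat = np.vstack([p.log2fc for p in order])
    if len(order) == 1:
        return {genes[0]: 1}, np.empty((0, 4)), genes
    Z = linkage(_condensed_distances(mat), method="average")
    raw = cut_tree(Z, n_clusters=k).ravel()
    # stable relabeling: biggest group first, ties by smallest member gene
    members: dict[int, list[str]] = {}
    for g, c in zip(genes, raw):
        members.setdefault(int(c), []).append(g)
    ranked = sorted(members, key=lambda c: (-len(members[c]), min(members[c])))
    relabel = {c: i + 1 for i, c in enumerate(ranked)}
    return {g: relabel[int(c)] for g, c in zip(genes, raw)}, Z, genes


@dataclass(frozen=True)
class ShapeConfig:
    """Thresholds for the rule-based shape labels.

    ``min_span`` is the absolute log2 span a profile must cover for any
    label (matching the 0.5 log2FC responsiveness filter);
    ``monotone_tol`` is the slack allowed against monotonicity;
    ``late_rise_frac``/``late_rise_dose`` define the sigmoid rule (>= 70%
    of the rise at doses >= 0.3 mM); ``early_rise_frac``/``early_rise_dose``
    define the saturating rule (>= 50% of the rise reached by 0.1 mM).
    """

    min_span: float = 0.5
    monotone_tol: float = 0.1
    late_rise_frac: float = 0.7
    late_rise_dose: float = 0.3
    early_rise_frac: float = 0.5
    early_rise_dose: float = 0.1


def label_shape(
    mean_profile: Sequence[float],
    dose_grid: Sequence[float],
    config: ShapeConfig = ShapeConfig(),
) -> str:
    """Label a mean log2FC profile over the positive dose grid.

    Rules are evaluated in order (bell, inverse_bell, monotone_down,
    sigmoid_threshold, saturating_up); a profile matching none is
    ``unclassified``.  Rise/drop fractions are relative to the profile's
    own endpoints, so labels are invariant to adding a constant; the
    ``min_span`` requirement is on the absolute log2 scale.
    """
    p = np.asarray(mean_profile, dtype=float)
    d = np.asarray(dose_grid, dtype=float)
    if p.size != d.size:
        raise ValueError("profile and dose grid length mismatch")
    if p.size < 5:
        raise ValueError("need at least 5 doses to label a shape")
    c = config

    # bell / inverse bell: unique interior extremum, both edges well below/above
    imax = int(p.argmax())
    if 0 < imax < p.size - 1 and (p == p[imax]).sum() == 1:
        if p[imax] - p[0] >= c.min_span and p[imax] - p[-1] >= c.min_span:
            return "bell"
    imin = int(p.argmin())
    if 0 < imin < p.size - 1 and (p == p[imin]).sum() == 1:
        if p[0] - p[imin] >= c.min_span and p[-1] - p[imin] >= c.min_span:
            return "inverse_bell"

    diffs = np.diff(p)
    total = p[-1] - p[0]
    if (diffs <= c.monotone_tol).all() and -total >= c.min_span:
        return "monotone_down"
    if (diffs >= -c.monotone_tol).all() and total >= c.min_span:
        late = d >= c.late_rise_dose
        j = int(np.flatnonzero(late)[0]) - 1 if late.any() else p.size - 1
        late_rise = p[-1] - p[j] if j >= 0 else total
        if late_rise / total >= c.late_rise_frac:
            return "sigmoid_threshold"
        early = np.flatnonzero(d <= c.early_rise_dose)
        if early.size:
            early_rise = p[int(early[-1])] - p[0]
            if early_rise / total >= c.early_rise_frac:
                return "saturating_up"
    return "unclassified"


@dataclass
class ProfileGroup:
    """One flat cluster of dose-response profiles (an SGi or MGi group)."""

    group_id: str
    members: list[FFLInstance]
    genes: list[str]
    mean_profile: np.ndarray
    shape: str
    type_composition: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("a profile group must have at least one gene")


@dataclass
class FunctionalGroup:
    """Merged profile groups with similar mean profiles (FG1..FGn)."""

    fg_id: str
    member_groups: list[str]
    genes: list[str]
    mean_profile: np.ndarray


def build_profile_groups(
    profiles: list[DoseResponseProfile],
    k: int,
    prefix: str,
    instances: list[FFLInstance] | None = None,
    shape_config: ShapeConfig = ShapeConfig(),
) -> list[ProfileGroup]:
    """Cluster profiles into k groups and package them as labeled ProfileGroups.

    ``prefix`` is "SG" for single-Y and "MG" for multi-Y runs.  When FFL
    instances are supplied, each group records the instances whose target
    gene fell in it and the set of FFL types they represent.
    """
    assignment, _Z, _genes = hierarchical_groups(profiles, k)
    by_gene = {p.gene: p for p in profiles}
    dose_grid = profiles[0].doses
    groups: list[ProfileGroup] = []
    for idx in range(1, k + 1):
        genes = sorted(g for g, c in assignment.items() if c == idx)
        mean = np.vstack([by_gene[g].log2fc for g in genes]).mean(axis=0)
        members = [i for i in (instances or []) if i.z in genes]
        groups.append(
            ProfileGroup(
                group_id=f"{prefix}{idx}",
                members=members,
                genes=genes,
                mean_profile=mean,
                shape=label_shape(mean, dose_grid, shape_config),
                type_composition=frozenset(i.ffl_type for i in members),
            )
        )
    return groups


def group_cohesion(group: ProfileGroup, profiles: list[DoseResponseProfile]) -> float:
    """Mean pairwise Pearson r among member profiles (1.0 for singletons)."""
    mat = [p.log2fc for p in profiles if p.gene in set(group.genes)]
    if len(mat) < 2:
        return 1.0
    rs = [
        pearsonr(mat[i], mat[j]).statistic
        for i in range(len(mat))
        for j in range(i + 1, len(mat))
    ]
    return float(np.mean(rs))


def _mean_corr(p: np.ndarray, q: np.ndarray) -> float:
    return 1.0 - correlation_distance(p, q)


def merge_functional_groups(
    sg: list[ProfileGroup],
    mg: list[ProfileGroup],
    min_corr: float = 0.8,
) -> list[FunctionalGroup]:
    """Merge single-Y and multi-Y groups into functional groups.

    Every SG group seeds one FG (in SG order).  Each MG group joins the FG
    of the SG group whose mean profile correlates best with it, provided
    that correlation reaches ``min_corr``; MG groups left unattached join
    an already-formed FG by the same rule against the FG mean profile, or
    else seed their own FG.
    """
    fgs: list[dict] = [
        {"members": [g.group_id], "genes": set(g.genes), "profiles": [g.mean_profile]}
        for g in sg
    ]
    unattached: list[ProfileGroup] = []
    for m in mg:
        if fgs:
            corrs = [_mean_corr(m.mean_profile, g.mean_profile) for g in sg]
            best = int(np.argmax(corrs)) if corrs else -1
            if corrs and corrs[best] >= min_corr:
                fgs[best]["members"].append(m.group_id)
                fgs[best]["genes"] |= set(m.genes)
                fgs[best]["profiles"].append(m.mean_profile)
                continue
        unattached.append(m)
    for m in unattached:
        corrs = [
            _mean_corr(m.mean_profile, np.vstack(fg["profiles"]).mean(axis=0))
            for fg in fgs
        ]
        if corrs and max(corrs) >= min_corr:
            best = int(np.argmax(corrs))
            fgs[best]["members"].append(m.group_id)
            fgs[best]["genes"] |= set(m.genes)
            fgs[best]["profiles"].append(m.mean_profile)
        else:
            fgs.append(
                {"members": [m.group_id], "genes": set(m.genes),
                 "profiles": [m.mean_profile]}
            )
    return [
        FunctionalGroup(
            fg_id=f"FG{i + 1}",
            member_groups=fg["members"],
            genes=sorted(fg["genes"]),
            mean_profile=np.vstack(fg["profiles"]).mean(axis=0),
        )
        for i, fg in enumerate(fgs)
    ]


def silhouette_k(
    profiles: list[DoseResponseProfile], k_range: Sequence[int]
) -> int:
    """Optional k selection: best mean silhouette over correlation distance."""
    from sklearn.metrics import silhouette_score
    from scipy.spatial.distance import squareform

    order = sorted(profiles, key=lambda p: p.gene)
    mat = np.vstack([p.log2fc for p in order])
    dm = squareform(_condensed_distances(mat))
    best_k, best_s = None, -np.inf
    for k in k_range:
        if not 2 <= k < len(order):
            continue
        assignment, _, genes = hierarchical_groups(profiles, k)
        labels = [assignment[g] for g in genes]
        s = silhouette_score(dm, labels, metric="precomputed")
        if s > best_s:
            best_k, best_s = k, s
    if best_k is None:
        raise ValueError("no feasible k in range")
    return best_k
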