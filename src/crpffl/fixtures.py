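"""Packaged census of CRP-mediated FFLs by type, and its summary statistics.

The package ships the published census of 202 CRP-anchored feed-forward
loops as a type -> ordered target-gene list (duplicates preserved: a gene
printed twice under one type is the target of two distinct loops through
different intermediate TFs).  Intermediate-TF identities are not part of
the published lists, so gene multiplicity across all lists is the only
available single-Y/multi-Y signal: an instance whose gene occurs exactly
once overall is counted single-Y.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from importlib import resources

from .motif import FFL_TYPES

__all__ = ["Table1Fixture", "FixtureStats", "load_table1", "fixture_stats", "headline_percent"]

#: Published number of CRP-regulated genes in the interaction snapshot the
#: census was built from; denominator of the headline coverage figure.
CRP_REGULON_SIZE = 432


@dataclass(frozen=True)
class Table1Fixture:
    """FFL type -> ordered list of target-gene instances."""

    lists: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        unknown = set(self.lists) - set(FFL_TYPES)
        if unknown:
            raise ValueError(f"unknown FFL types in fixture: {sorted(unknown)}")

    @property
    def total(self) -> int:
        return sum(len(v) for v in self.lists.values())


@dataclass(frozen=True)
class FixtureStats:
    per_type_counts: dict[str, int]
    per_type_distinct_genes: dict[str, int]
    total_instances: int
    distinct_genes: int
    single_y_instances: int
    multi_y_instances: int
    single_y_genes: int
    multi_y_genes: int
    gene_multiplicity: dict[str, int]


def load_table1() -> Table1Fixture:
    """Load the packaged census fixture (validated against known list lengths)."""
    lists: dict[str, list[str]] = {}
    text = resources.files("crpffl.data").joinpath("table1_census.tsv").read_text()
    for line in text.splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("type\t"):
            continue
        t, gene = line.split("\t")
        lists.setdefault(t, []).append(gene)
    fx = Table1Fixture({t: tuple(v) for t, v in lists.items()})
    expected = {"Coh1": 49, "Coh2": 15, "Coh3": 2, "Coh4": 26,
                "InCoh1": 87, "InCoh2": 8, "InCoh3": 1, "InCoh4": 14}
    actual = {t: len(v) for t, v in fx.lists.items()}
    if actual != expected:
        raise RuntimeError(f"packaged census corrupt: {actual}")
    return fx


def fixture_stats(fx: Table1Fixture) -> FixtureStats:
    """Summary arithmetic over the census lists.

    Multiplicity is counted over the concatenation of all per-type lists;
    instances of genes occurring exactly once are single-Y, the rest
    multi-Y (a gene appearing in two types is thereby multi-Y).
    """
    mult: Counter[str] = Counter()
    for genes in fx.lists.values():
        mult.update(genes)
    single_genes = {g for g, c in mult.items() if c == 1}
    return FixtureStats(
        per_type_counts={t: len(fx.lists.get(t, ())) for t in FFL_TYPES},
        per_type_distinct_genes={t: len(set(fx.lists.get(t, ()))) for t in FFL_TYPES},
        total_instances=sum(mult.values()),
        distinct_genes=len(mult),
        single_y_instances=sum(c for g, c in mult.items() if c == 1),
        multi_y_instances=sum(c for g, c in mult.items() if c > 1),
        single_y_genes=len(single_genes),
        multi_y_genes=len(mult) - len(single_genes),
        gene_multiplicity=dict(mult),
    )


def headline_percent(n_ffl_genes: int, n_regulon_genes: int = CRP_REGULON_SIZE) -> int:
    """Share of CRP-regulated genes that sit in an expression-supported FFL.

    Rounded to whole percent: 147 FFL genes over a 432-gene regulon gives 34.
    """
    if n_regulon_genes <= 0:
        raise ValueError("regulon size must be positive")
    return round(100.0 * n_ffl_genes / n_regulon_genes)
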