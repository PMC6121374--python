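"""Signed transcriptional regulatory networks from TF->gene interaction tables.

The substrate of the feed-forward-loop census is a directed graph whose
edges carry a resolved regulatory sign: +1 for activation, -1 for
repression.  Interaction tables in the RegulonDB/EcoCyc flat-file style
also report *dual* regulators (both signs observed) and interactions of
*unknown* effect; those edges cannot be given a single sign and are kept
in an excluded-edge ledger instead of the signed graph, so that

    |resolved edges| + |excluded pairs| = |distinct (regulator, target) pairs|

always holds.  Identifier matching is case-insensitive (databases mix
``crp``/``CRP``); the display form is preserved for output.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

log = logging.getLogger(__name__)

__all__ = [
    "Effect",
    "Evidence",
    "RegulatoryInteraction",
    "SignedRegulatoryNetwork",
    "ParseError",
    "read_interactions",
    "build_network",
    "write_network",
    "write_excluded",
]


class ParseError(ValueError):
    """An interaction table row that cannot be interpreted."""


class Effect(enum.Enum):
    ACTIVATION = "activation"
    REPRESSION = "repression"
    DUAL = "dual"
    UNKNOWN = "unknown"


class Evidence(enum.Enum):
    STRONG = "strong"
    WEAK = "weak"
    UNSPECIFIED = "unspecified"


#: Case-insensitive spellings accepted in the effect column.
_EFFECT_TOKENS: Mapping[str, Effect] = {
    "+": Effect.ACTIVATION,
    "+1": Effect.ACTIVATION,
    "1": Effect.ACTIVATION,
    "-1": Effect.REPRESSION,
    "−1": Effect.REPRESSION,
    "activation": Effect.ACTIVATION,
    "activator": Effect.ACTIVATION,
    "positive": Effect.ACTIVATION,
    "-": Effect.REPRESSION,
    "−": Effect.REPRESSION,  # unicode minus
    "repression": Effect.REPRESSION,
    "repressor": Effect.REPRESSION,
    "negative": Effect.REPRESSION,
    "+-": Effect.DUAL,
    "-+": Effect.DUAL,
    "+/-": Effect.DUAL,
    "±": Effect.DUAL,
    "dual": Effect.DUAL,
    "unknown": Effect.UNKNOWN,
    "?": Effect.UNKNOWN,
}

_EVIDENCE_TOKENS: Mapping[str, Evidence] = {
    "strong": Evidence.STRONG,
    "weak": Evidence.WEAK,
    "": Evidence.UNSPECIFIED,
    "unspecified": Evidence.UNSPECIFIED,
}

EFFECT_SIGN = {Effect.ACTIVATION: +1, Effect.REPRESSION: -1}


def canonical(name: str) -> str:
    """Canonical matching key for a gene/TF identifier."""
    return name.strip().casefold()


@dataclass(frozen=True)
class RegulatoryInteraction:
    """One row of an interaction table: regulator acts on target with an effect."""

    regulator: str
    target: str
    effect: Effect
    evidence: Evidence = Evidence.UNSPECIFIED

    def __post_init__(self) -> None:
        if not canonical(self.regulator) or not canonical(self.target):
            raise ValueError("regulator and target must be non-empty")

    @property
    def key(self) -> tuple[str, str]:
        return (canonical(self.regulator), canonical(self.target))


@dataclass
class SignedRegulatoryNetwork:
    """Directed graph with one resolved sign (+1/-1) per (regulator, target) pair.

    ``excluded`` records ordered pairs dropped during sign resolution with
    the reason (``dual``, ``unknown``, ``conflict`` or ``evidence``); it is
    disjoint from ``edges`` by construction.
    """

    display: dict[str, str] = field(default_factory=dict)  # key -> display form
    tfs: set[str] = field(default_factory=set)  # keys of regulator nodes
    edges: dict[tuple[str, str], int] = field(default_factory=dict)
    excluded: dict[tuple[str, str], str] = field(default_factory=dict)

    @property
    def nodes(self) -> set[str]:
        return set(self.display)

    def sign(self, regulator: str, target: str) -> int | None:
        return self.edges.get((canonical(regulator), canonical(target)))

    def successors(self, regulator: str) -> list[str]:
        u = canonical(regulator)
        return sorted(v for (a, v) in self.edges if a == u)

    def name_of(self, key: str) -> str:
        return self.display.get(key, key)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignedRegulatoryNetwork):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and self.tfs == other.tfs
            and self.edges == other.edges
            and self.excluded == other.excluded
        )

    def validate(self) -> None:
        for (u, v) in self.edges:
            assert u in self.display and v in self.display, "edge endpoint not registered"
            assert u in self.tfs, "regulator without TF flag"
        assert not (set(self.edges) & set(self.excluded)), "ledger overlaps resolved edges"


def read_interactions(
    path: str | Path,
    *,
    sep: str = "\t",
    comment: str = "#",
) -> list[RegulatoryInteraction]:
    """Read a regulator/target/effect[/evidence] table.

    Lines starting with ``comment`` are skipped; a header line is detected by
    a first field spelled ``regulator`` (any case).  Unrecognized effect
    strings map to ``unknown`` with a logged warning.  An empty file yields
    an empty list.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"interaction table not found: {path}")
    records: list[RegulatoryInteraction] = []
    first_data_line = True
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith(comment):
                continue
            fields = [f.strip() for f in line.split(sep)]
            if first_data_line:
                first_data_line = False
                if fields[0].casefold() in {"regulator", "tf", "source"}:
                    continue
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 fields, got {len(fields)}")
            reg, tgt, eff_tok = fields[0], fields[1], fields[2]
            effect = _EFFECT_TOKENS.get(eff_tok.casefold())
            if effect is None:
                log.warning("%s:%d: unrecognized effect %r -> unknown", path, lineno, eff_tok)
                effect = Effect.UNKNOWN
            ev_tok = fields[3].casefold() if len(fields) > 3 else ""
            evidence = _EVIDENCE_TOKENS.get(ev_tok)
            if evidence is None:
                log.warning("%s:%d: unrecognized evidence %r -> unspecified", path, lineno, fields[3])
                evidence = Evidence.UNSPECIFIED
            records.append(RegulatoryInteraction(reg, tgt, effect, evidence))
    return records


def build_network(
    interactions: Iterable[RegulatoryInteraction],
    tf_set: set[str],
    min_evidence: str = "any",
) -> SignedRegulatoryNetwork:
    """Resolve interactions into a signed network.

    Activation resolves to +1, repression to -1.  Dual/unknown pairs, pairs
    whose rows carry conflicting signs, and pairs failing the evidence
    filter go to the excluded ledger.  The result is independent of the
    input row order.
    """
    if not tf_set:
        raise ValueError("tf_set must be non-empty")
    if min_evidence not in {"any", "strong"}:
        raise ValueError("min_evidence must be 'any' or 'strong'")
    tf_keys = {canonical(t) for t in tf_set}

    net = SignedRegulatoryNetwork()
    per_pair: dict[tuple[str, str], set[Effect]] = {}
    weak_only: dict[tuple[str, str], bool] = {}
    for rec in interactions:
        key = rec.key
        # order-independent display form: lexicographically smallest spelling
        for k, disp in zip(key, (rec.regulator.strip(), rec.target.strip())):
            if k not in net.display or disp < net.display[k]:
                net.display[k] = disp
        if min_evidence == "strong" and rec.evidence is not Evidence.STRONG:
            weak_only.setdefault(key, True)
            per_pair.setdefault(key, set())
            continue
        weak_only[key] = False
        per_pair.setdefault(key, set()).add(rec.effect)

    for key in sorted(per_pair):
        effects = per_pair[key]
        if weak_only[key] and not effects:
            net.excluded[key] = "evidence"
            continue
        if Effect.DUAL in effects:
            net.excluded[key] = "dual"
            continue
        if effects == {Effect.UNKNOWN}:
            net.excluded[key] = "unknown"
            continue
        signs = {EFFECT_SIGN[e] for e in effects if e in EFFECT_SIGN}
        if len(signs) > 1:
            log.info("conflicting signs for %s -> %s; treated as dual and excluded", *key)
            net.excluded[key] = "conflict"
            continue
        net.edges[key] = signs.pop()

    net.tfs = {u for (u, _v) in net.edges} | (tf_keys & net.nodes)
    net.validate()
    return net


def write_network(net: SignedRegulatoryNetwork, path: str | Path) -> None:
    """Edge-list TSV of resolved edges (regulator, target, sign)."""
    with Path(path).open("w") as fh:
        fh.write("regulator\ttarget\tsign\n")
        for (u, v) in sorted(net.edges):
            fh.write(f"{net.name_of(u)}\t{net.name_of(v)}\t{net.edges[(u, v)]:+d}\n")


def write_excluded(net: SignedRegulatoryNetwork, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("regulator\ttarget\treason\n")
        for (u, v) in sorted(net.excluded):
            fh.write(f"{net.name_of(u)}\t{net.name_of(v)}\t{net.excluded[(u, v)]}\n")
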