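"""Feed-forward loop enumeration and eight-type classification.

A feed-forward loop (FFL) is the three-node motif in which a master TF X
regulates an intermediate TF Y, and both X and Y regulate a target gene Z.
With a sign on each of the three edges there are eight types.  The loop is
*coherent* when the direct X->Z effect equals the net indirect effect
through Y, i.e. ``sign_xz == sign_xy * sign_yz``, and *incoherent*
otherwise; the conventional type labels are

    ========  =======  =======  =======
    type      X->Y     Y->Z     X->Z
    ========  =======  =======  =======
    Coh1        +        +        +
    Coh2        -        +        -
    Coh3        +        -        -
    Coh4        -        -        +
    InCoh1      +        -        +
    InCoh2      -        -        -
    InCoh3      +        +        -
    InCoh4      -        +        +
    ========  =======  =======  =======

A target regulated (with X) by exactly one intermediate TF forms a
*single-Y* FFL (sFFL); two or more intermediates on the same target make
each of its loops *multi-Y* (mFFL).  One (X, Y) pair driving several
targets is a *multi-output* FFL.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .regnet import SignedRegulatoryNetwork, canonical

__all__ = [
    "FFL_TYPES",
    "SIGNS_TO_TYPE",
    "FFLInstance",
    "FFLCensus",
    "classify_signs",
    "enumerate_ffls",
    "multi_output_groups",
    "census_summary",
    "write_census",
]

FFL_TYPES = ("Coh1", "Coh2", "Coh3", "Coh4", "InCoh1", "InCoh2", "InCoh3", "InCoh4")

SIGNS_TO_TYPE: dict[tuple[int, int, int], str] = {
    (+1, +1, +1): "Coh1",
    (-1, +1, -1): "Coh2",
    (+1, -1, -1): "Coh3",
    (-1, -1, +1): "Coh4",
    (+1, -1, +1): "InCoh1",
    (-1, -1, -1): "InCoh2",
    (+1, +1, -1): "InCoh3",
    (-1, +1, +1): "InCoh4",
}

_TYPE_RANK = {t: i for i, t in enumerate(FFL_TYPES)}


def classify_signs(sign_xy: int, sign_yz: int, sign_xz: int) -> str:
    """Type label for one signed (X, Y, Z) triangle."""
    for s in (sign_xy, sign_yz, sign_xz):
        if s not in (+1, -1):
            raise ValueError(f"edge sign must be +1 or -1, got {s!r}")
    return SIGNS_TO_TYPE[(sign_xy, sign_yz, sign_xz)]


def is_coherent(ffl_type: str) -> bool:
    return ffl_type.startswith("Coh")


@dataclass(frozen=True, order=True)
class FFLInstance:
    """One classified (X, Y, Z) triangle."""

    x: str
    y: str
    z: str
    sign_xy: int
    sign_yz: int
    sign_xz: int
    ffl_type: str

    def __post_init__(self) -> None:
        if len({self.x, self.y, self.z}) != 3:
            raise ValueError("X, Y, Z must be three distinct nodes")
        if classify_signs(self.sign_xy, self.sign_yz, self.sign_xz) != self.ffl_type:
            raise ValueError("ffl_type inconsistent with edge signs")


@dataclass
class FFLCensus:
    """All FFL instances anchored on one master TF, with arity bookkeeping.

    ``arity[z]`` is the number of distinct intermediate TFs regulating
    target z (jointly across types); instances with arity 1 form the
    single-Y partition, the rest the multi-Y partition.
    """

    master: str
    instances: list[FFLInstance] = field(default_factory=list)

    @property
    def per_type_counts(self) -> dict[str, int]:
        counts = {t: 0 for t in FFL_TYPES}
        for inst in self.instances:
            counts[inst.ffl_type] += 1
        return counts

    @property
    def arity(self) -> dict[str, int]:
        ys: dict[str, set[str]] = {}
        for inst in self.instances:
            ys.setdefault(inst.z, set()).add(inst.y)
        return {z: len(s) for z, s in ys.items()}

    @property
    def sffl(self) -> list[FFLInstance]:
        ar = self.arity
        return [i for i in self.instances if ar[i.z] == 1]

    @property
    def mffl(self) -> list[FFLInstance]:
        ar = self.arity
        return [i for i in self.instances if ar[i.z] > 1]

    @property
    def genes(self) -> list[str]:
        return sorted({i.z for i in self.instances})

    def restrict_to_genes(self, keep: set[str]) -> "FFLCensus":
        """Census over target genes in ``keep`` only (arity recomputed)."""
        keep_keys = {canonical(g) for g in keep}
        kept = [i for i in self.instances if canonical(i.z) in keep_keys]
        return FFLCensus(self.master, kept)


def enumerate_ffls(
    net: SignedRegulatoryNetwork,
    master: str,
    tf_set: set[str],
) -> FFLCensus:
    """Enumerate every FFL (master, y, z) with all three edges resolved.

    Intermediates are drawn from ``tf_set``; self-loops are ignored and a
    target may itself be a TF.  Output order is deterministic: by type,
    then target, then intermediate.
    """
    m = canonical(master)
    if m not in net.nodes:
        raise ValueError(f"master TF {master!r} is not a node of the network")
    tf_keys = {canonical(t) for t in tf_set} & net.nodes

    instances: list[FFLInstance] = []
    for y in sorted(tf_keys - {m}):
        s_xy = net.edges.get((m, y))
        if s_xy is None:
            continue
        for (u, z), s_yz in net.edges.items():
            if u != y or z == m or z == y:
                continue
            s_xz = net.edges.get((m, z))
            if s_xz is None:
                continue
            instances.append(
                FFLInstance(
                    net.name_of(m), net.name_of(y), net.name_of(z),
                    s_xy, s_yz, s_xz, classify_signs(s_xy, s_yz, s_xz),
                )
            )
    instances.sort(key=lambda i: (_TYPE_RANK[i.ffl_type], canonical(i.z), canonical(i.y)))
    return FFLCensus(net.name_of(m), instances)


def multi_output_groups(census: FFLCensus) -> dict[tuple[str, str], list[str]]:
    """(X, Y) pairs jointly regulating two or more targets, with their targets."""
    by_pair: dict[tuple[str, str], list[str]] = {}
    for inst in census.instances:
        by_pair.setdefault((inst.x, inst.y), []).append(inst.z)
    return {
        pair: sorted(set(zs), key=canonical)
        for pair, zs in sorted(by_pair.items())
        if len(set(zs)) >= 2
    }


def census_summary(census: FFLCensus) -> pd.DataFrame:
    """Per-type table: FFL count, distinct intermediate TFs, distinct genes, gene list.

    A trailing ``Total`` row aggregates over all types; single-Y/multi-Y
    instance counts are attached in ``DataFrame.attrs``.
    """
    rows = []
    for t in FFL_TYPES:
        insts = [i for i in census.instances if i.ffl_type == t]
        genes = sorted({i.z for i in insts}, key=canonical)
        tfs = {i.y for i in insts}
        rows.append(
            {"type": t, "n_ffls": len(insts), "n_tfs": len(tfs),
             "n_genes": len(genes), "genes": ",".join(genes)}
        )
    all_genes = sorted({i.z for i in census.instances}, key=canonical)
    rows.append(
        {"type": "Total", "n_ffls": len(census.instances),
         "n_tfs": len({i.y for i in census.instances}),
         "n_genes": len(all_genes), "genes": ",".join(all_genes)}
    )
    df = pd.DataFrame(rows).set_index("type")
    df.attrs["n_sffl"] = len(census.sffl)
    df.attrs["n_mffl"] = len(census.mffl)
    return df


def write_census(census: FFLCensus, path) -> None:
    """Census TSV: one row per instance with signs, type and arity class."""
    ar = census.arity
    rows = [
        {"x": i.x, "y": i.y, "z": i.z,
         "sign_xy": i.sign_xy, "sign_yz": i.sign_yz, "sign_xz": i.sign_xz,
         "type": i.ffl_type,
         "arity_class": "single" if ar[i.z] == 1 else "multi"}
        for i in census.instances
    ]
    pd.DataFrame(rows, columns=["x", "y", "z", "sign_xy", "sign_yz",
                                "sign_xz", "type", "arity_class"]).to_csv(
        path, sep="\t", index=False)
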