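"""End-to-end pipeline: interaction table + expression matrix -> census,
profile groups, functional groups and enrichment tables.

Stage order mirrors the two-step design of the analysis: (i) build the
signed network and enumerate master-TF FFLs; (ii) compute dose-response
profiles, drop unresponsive genes, restrict the census to responsive
targets, cluster single-Y and multi-Y target profiles separately, merge
similar groups into functional groups and run GO enrichment per group.
All outputs are TSV/JSON and byte-stable for a fixed input and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import clustering, doseresponse, enrichment, motif, regnet

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name for actionable messages."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run, with the analysis defaults.

    ``tf_set_path`` may name a one-identifier-per-line file; when absent
    the TF set is inferred as every regulator in the interaction table.
    """

    interactions: str
    expression: str
    output_dir: str
    annotations: str | None = None
    term_parents: str | None = None
    master: str = "crp"
    tf_set_path: str | None = None
    min_evidence: str = "any"
    threshold: float = 0.5
    filter_mode: str = "any"
    k_sffl: int = 5
    k_mffl: int = 6
    max_p: float = 0.01
    min_corr: float = 0.8
    shape_config: clustering.ShapeConfig = field(default_factory=clustering.ShapeConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("threshold", "max_p", "min_corr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.k_sffl < 1 or self.k_mffl < 1:
            raise ValueError("cluster counts must be >= 1")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Flat ``key = value`` config file; '#' comments allowed."""
        kv: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            kv[key.strip()] = val.strip()
        typed: dict[str, object] = {}
        for key, val in kv.items():
            if key in {"threshold", "max_p", "min_corr"}:
                typed[key] = float(val)
            elif key in {"k_sffl", "k_mffl", "seed"}:
                typed[key] = int(val)
            else:
                typed[key] = val
        typed.update(overrides)
        return cls(**typed)  # type: ignore[arg-type]


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
        return wrapped
    return deco


@_stage("regnet")
def _build_network(cfg: PipelineConfig):
    interactions = regnet.read_interactions(cfg.interactions)
    if cfg.tf_set_path:
        tf_set = {
            line.strip()
            for line in Path(cfg.tf_set_path).read_text().splitlines()
            if line.strip() and not line.startswith("#")
        }
    else:
        tf_set = {rec.regulator for rec in interactions}
    if not tf_set:
        raise ValueError("empty TF set (no regulators found)")
    return regnet.build_network(interactions, tf_set, cfg.min_evidence), tf_set, len(interactions)


def _cluster_side(profiles, instances, k, prefix, cfg):
    if not profiles:
        return []
    k_eff = min(k, len(profiles))
    if k_eff < k:
        log.warning("%s: only %d profiles, reducing k from %d", prefix, len(profiles), k)
    return clustering.build_profile_groups(
        profiles, k_eff, prefix, instances, cfg.shape_config
    )


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and write the report bundle to ``cfg.output_dir``.

    Returns the run summary (also written as ``summary.json``).
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    net, tf_set, n_interactions = _build_network(cfg)
    regnet.write_network(net, out / "network.tsv")
    regnet.write_excluded(net, out / "excluded_edges.tsv")

    census = _stage("motif")(motif.enumerate_ffls)(net, cfg.master, tf_set)

    matrix = _stage("doseresponse")(doseresponse.read_matrix)(cfg.expression, dose_grid=None)
    profiles = doseresponse.compute_profiles(matrix)
    kept, dropped = doseresponse.filter_responsive(profiles, cfg.threshold, cfg.filter_mode)
    doseresponse.write_profiles(profiles, out / "profiles.tsv")
    with (out / "filter_report.tsv").open("w") as fh:
        fh.write("gene\tkept\tmax_abs_log2fc\n")
        for p in profiles:
            flag = int(any(q.gene == p.gene for q in kept))
            fh.write(f"{p.gene}\t{flag}\t{p.max_abs:.6g}\n")

    kept_genes = {p.gene for p in kept}
    census_kept = census.restrict_to_genes(kept_genes)
    motif.write_census(census_kept, out / "census.tsv")

    by_gene = {p.gene: p for p in profiles}
    sffl_genes = sorted({i.z for i in census_kept.sffl})
    mffl_genes = sorted({i.z for i in census_kept.mffl})
    sg = _stage("clustering")(_cluster_side)(
        [by_gene[g] for g in sffl_genes if g in by_gene],
        census_kept.sffl, cfg.k_sffl, "SG", cfg)
    mg = _stage("clustering")(_cluster_side)(
        [by_gene[g] for g in mffl_genes if g in by_gene],
        census_kept.mffl, cfg.k_mffl, "MG", cfg)
    fgs = clustering.merge_functional_groups(sg, mg, cfg.min_corr)

    fg_of_group = {gid: fg.fg_id for fg in fgs for gid in fg.member_groups}
    with (out / "groups.tsv").open("w") as fh:
        fh.write("gene\tgroup_id\tshape\tfg_id\n")
        for grp in [*sg, *mg]:
            for g in grp.genes:
                fh.write(f"{g}\t{grp.group_id}\t{grp.shape}\t{fg_of_group[grp.group_id]}\n")

    enrich_summary: dict[str, int] = {}
    if cfg.annotations:
        ann = _stage("enrichment")(enrichment.read_annotations)(cfg.annotations)
        if cfg.term_parents:
            ann.parents = enrichment.read_term_parents(cfg.term_parents)
            ann = enrichment.propagate_annotations(ann)
        universe = set(matrix.genes)
        for fg in fgs:
            results = _stage("enrichment")(enrichment.enrich_group)(
                set(fg.genes), universe, ann, cfg.max_p)
            enrichment.write_enrichment(results, out / f"enrichment_{fg.fg_id}.tsv")
            enrich_summary[fg.fg_id] = sum(r.significant for r in results)

    summary = {
        "config": {
            **{k: v for k, v in asdict(cfg).items() if k != "shape_config"},
            "shape_config": asdict(cfg.shape_config),
        },
        "seed": cfg.seed,
        "n_interactions": n_interactions,
        "n_resolved_edges": len(net.edges),
        "n_excluded_pairs": len(net.excluded),
        "n_ffls_unfiltered": len(census.instances),
        "n_ffls": len(census_kept.instances),
        "per_type_counts": census_kept.per_type_counts,
        "n_genes": len(census_kept.genes),
        "n_kept_genes": len(kept),
        "n_dropped_genes": len(dropped),
        "n_sffl": len(census_kept.sffl),
        "n_mffl": len(census_kept.mffl),
        "groups": {
            g.group_id: {"genes": g.genes, "shape": g.shape,
                         "types": sorted(g.type_composition)}
            for g in [*sg, *mg]
        },
        "functional_groups": {
            fg.fg_id: {"member_groups": fg.member_groups, "genes": fg.genes}
            for fg in fgs
        },
        "n_significant_terms": enrich_summary,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary
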