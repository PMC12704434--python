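"""End-to-end family analysis and the structured JSON summary.

``summarize_gcf`` runs classification, consensus ordering, reconstruction
and (for families of three or more members) the openness analysis, and
flattens everything into one JSON-serializable dictionary — the document
the rest of the ecosystem (exports, dashboards, downstream scripts)
consumes. Smaller families get ``openness: null`` plus a reason string, as
gamma cannot be estimated from one or two members.
"""

from __future__ import annotations

from typing import Optional

from .model import GCF, OrthologGroup
from .openness import FitConfig, OpennessResult, analyze_openness
from .pangenome import (
    ClassificationConfig,
    PresenceAbsenceMatrix,
    build_presence_absence,
    classify_ogs,
    consensus_order,
    og_mean_lengths,
    reconstruct_bgc,
)

MIN_OPENNESS_MEMBERS = 3


def build_og_table(
    gcf: GCF,
    matrix: PresenceAbsenceMatrix,
    categories: dict[str, str],
    order: list[str],
) -> list[OrthologGroup]:
    """Assemble per-OG summaries (prevalence, copy totals, mean protein
    length, consensus rank, category)."""
    members: dict[str, list[tuple[str, str]]] = {og: [] for og in matrix.og_ids}
    for gene in gcf.genes():
        members[gene.og_id].append((gene.bgc_id, gene.gene_id))
    lengths = og_mean_lengths(gcf)
    rank = {og: i for i, og in enumerate(order)}
    present = matrix.presence().sum(axis=0)
    table = []
    for j, og in enumerate(matrix.og_ids):
        table.append(
            OrthologGroup(
                og_id=og,
                members=members[og],
                prevalence=float(present[j]) / matrix.n_bgcs,
                copy_total=int(matrix.counts[:, j].sum()),
                mean_length=lengths.get(og),
                consensus_index=rank[og],
                category=categories[og],
            )
        )
    return table


def _fit_dict(metric_result, n_permutations: int, seed: int) -> dict:
    best = metric_result.best
    return {
        "k": best.k,
        "gamma": best.gamma,
        "r2": best.r2,
        "method": best.method,
        "category": metric_result.category,
        "n_permutations": n_permutations,
        "seed": seed,
    }


def summarize_gcf(
    gcf: GCF,
    core_threshold: float = 1.0,
    n_permutations: int = 30,
    seed: int = 0,
    fit_config: Optional[FitConfig] = None,
    include_permutation_curves: bool = False,
) -> dict:
    """Run the full analysis and return the JSON-serializable bundle.

    Requires a total ortholog assignment on ``gcf`` (run the greedy
    grouper or load an ortholog table first).
    """
    config = ClassificationConfig(core_threshold=core_threshold)
    matrix = build_presence_absence(gcf)
    categories = classify_ogs(matrix, config)
    order = consensus_order(gcf, matrix)
    og_table = build_og_table(gcf, matrix, categories, order)
    core = reconstruct_bgc(gcf, "core", config, matrix)
    maximum = reconstruct_bgc(gcf, "max", config, matrix)

    openness_block = None
    openness_reason = None
    curves_block = None
    openness_result: Optional[OpennessResult] = None
    if gcf.n_bgcs >= MIN_OPENNESS_MEMBERS:
        openness_result = analyze_openness(
            matrix,
            n_permutations=n_permutations,
            seed=seed,
            config=fit_config,
            gcf_id=gcf.gcf_id,
        )
        openness_block = {
            metric: _fit_dict(mr, openness_result.n_permutations, seed)
            for metric, mr in openness_result.metrics.items()
        }
        curves_block = {}
        for metric, mr in openness_result.metrics.items():
            entry = {
                "x": [int(v) for v in mr.curve.x],
                "mean_y": [float(v) for v in mr.curve.mean_y],
                "exhaustive": mr.curve.exhaustive,
            }
            if include_permutation_curves:
                entry["per_permutation_y"] = [
                    [float(v) for v in row] for row in mr.curve.per_permutation_y
                ]
            curves_block[metric] = entry
    else:
        openness_reason = (
            f"family has {gcf.n_bgcs} member(s); openness needs at least "
            f"{MIN_OPENNESS_MEMBERS} BGCs for a reliable gamma estimate"
        )

    classes: list[str] = sorted({c for m in gcf.members for c in m.bgc_class})
    summary = {
        "gcf_id": gcf.gcf_id,
        "n_bgcs": gcf.n_bgcs,
        "classes": classes,
        "core_threshold": core_threshold,
        "og_table": [
            {
                "og_id": og.og_id,
                "category": og.category,
                "prevalence": og.prevalence,
                "copy_total": og.copy_total,
                "mean_length": og.mean_length,
                "consensus_index": og.consensus_index,
                "diversity": None,  # reserved; no defined estimator yet
            }
            for og in og_table
        ],
        "presence_absence": {
            "bgc_ids": list(matrix.bgc_ids),
            "og_ids": list(matrix.og_ids),
            "counts": [[int(v) for v in row] for row in matrix.counts],
        },
        "consensus_order": order,
        "reconstruction": {
            "core": [
                {"og_id": e.og_id, "category": e.category, "mean_length": e.mean_length}
                for e in core
            ],
            "core_empty": len(core) == 0,
            "max": [
                {"og_id": e.og_id, "category": e.category, "mean_length": e.mean_length}
                for e in maximum
            ],
        },
        "openness": openness_block,
        "openness_reason": openness_reason,
        "curves": curves_block,
    }
    return summary
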