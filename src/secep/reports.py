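"""End-to-end pipeline orchestration, KM export and run manifests.

The pipeline chains the stages secretome -> classify -> screen (->
specificity), persisting every intermediate as plain TSV so any stage can
be re-run standalone from prior outputs and results diff cleanly.  A JSON
run manifest records the configuration snapshot, seed, input digests,
stage timings and output inventory.
"""

from __future__ import annotations

import json
import logging
import time as _time
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .classify import classify_secep, cohort_gene_stats, intersect_secep
from .combos import CohortContext, ScreenConfig, evaluate_combo, screen
from .io import ExpressionCohort, LfqMatrix, file_digest, split_protein_id
from .secretome import (
    anova_validate,
    call_subtype_specific,
    cell_line_means,
    handle_missing,
    make_reference_profiles,
    profile_match,
    ward_cluster_order,
    zscore_rows,
)

log = logging.getLogger(__name__)

__all__ = ["run_secretome_stage", "run_classify_stage", "run_pipeline", "km_export"]


def run_secretome_stage(
    matrix: LfqMatrix,
    out_dir,
    anova_p: float = 0.05,
    r_threshold: float = 0.8,
    min_valid_per_group: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """LFQ matrix -> secretion calls TSV + cluster-order TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    filtered = handle_missing(matrix, min_valid_per_group=min_valid_per_group, impute=False)
    z = zscore_rows(filtered)
    mz = cell_line_means(z)
    profiles = make_reference_profiles(z)
    matches = profile_match(mz, profiles, r_threshold=r_threshold)
    anova = anova_validate(filtered)
    calls = call_subtype_specific(z, mz, matches, anova, anova_p_threshold=anova_p)
    calls.to_csv(out / "secretome_calls.tsv", sep="\t", index=False, float_format="%.6g")
    # cluster ordering for heatmap export requires a complete matrix
    imputed = zscore_rows(
        handle_missing(matrix, min_valid_per_group=min_valid_per_group, impute=True, seed=seed)
    )
    order, _ = ward_cluster_order(imputed.values, axis="rows")
    pd.DataFrame({"protein_id": order}).to_csv(out / "cluster_order.tsv", sep="\t", index=False)
    return calls


def run_classify_stage(
    cohorts: list[ExpressionCohort],
    calls: pd.DataFrame,
    out_dir,
    alpha: float = 0.05,
    require_concordance: bool = True,
) -> pd.DataFrame:
    """Per-cohort SeCEP classification; returns the cross-cohort intersection."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    per_cohort = {}
    for cohort in cohorts:
        stats_df = cohort_gene_stats(cohort)
        res = classify_secep(stats_df, calls, alpha=alpha, require_concordance=require_concordance)
        res.secep.to_csv(out / f"secep_{cohort.name}.tsv", sep="\t", index=False, float_format="%.6g")
        res.discordant.to_csv(
            out / f"secep_discordant_{cohort.name}.tsv", sep="\t", index=False, float_format="%.6g"
        )
        per_cohort[cohort.name] = res.secep
    working = intersect_secep(per_cohort)
    working.to_csv(out / "secep_intersection.tsv", sep="\t", index=False, float_format="%.6g")
    return working


def run_pipeline(
    matrix: LfqMatrix,
    cohorts: list[ExpressionCohort],
    out_dir,
    seed: int = 0,
    anova_p: float = 0.05,
    r_threshold: float = 0.8,
    alpha: float = 0.05,
    screen_config: ScreenConfig | None = None,
    input_paths: dict | None = None,
) -> dict:
    """Full workflow: secretion calling, SeCEP classification, combination screen.

    Returns the manifest dict (also written to ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if screen_config is None:
        screen_config = ScreenConfig()
    timings = {}
    t0 = _time.perf_counter()
    calls = run_secretome_stage(matrix, out, anova_p=anova_p, r_threshold=r_threshold, seed=seed)
    timings["secretome_s"] = round(_time.perf_counter() - t0, 3)

    t0 = _time.perf_counter()
    working = run_classify_stage(cohorts, calls, out, alpha=alpha)
    timings["classify_s"] = round(_time.perf_counter() - t0, 3)

    t0 = _time.perf_counter()
    genes = sorted(set(working["gene_id"]) & set.intersection(*(set(c.z.index) for c in cohorts)))
    results = pd.DataFrame()
    if genes:
        results = screen(cohorts, genes, screen_config, out_path=out / "screen_results.tsv")
    else:
        log.warning("no SeCEP genes survived classification; screen skipped")
        (out / "screen_results.tsv").write_text("")
    timings["screen_s"] = round(_time.perf_counter() - t0, 3)

    manifest = {
        "tool": "secep",
        "version": __version__,
        "seed": seed,
        "config": {
            "anova_p": anova_p,
            "r_threshold": r_threshold,
            "alpha": alpha,
            "screen": asdict(screen_config) | {"subtype_scope": list(screen_config.subtype_scope)},
            "bh_family": "all genes in cohort matrix",
        },
        "inputs": {
            name: file_digest(path) for name, path in (input_paths or {}).items()
        },
        "cohorts": [c.name for c in cohorts],
        "n_secretion_calls": int(len(calls)),
        "n_secep_genes": int(len(working)),
        "n_screen_rows": int(len(results)),
        "n_screen_passing": int(results["passes"].sum()) if len(results) else 0,
        "timings": timings,
        "outputs": sorted(p.name for p in out.glob("*.tsv")),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def km_export(cohort: ExpressionCohort, genes, config: ScreenConfig, out_path) -> pd.DataFrame:
    """Two-group KM curve table with figure-style annotations.

    The header block mirrors the usual plot annotations: per group N
    (number of patients), NE (number of events), plus the log-rank p and
    the HR with its 95% CI; the body is the per-group survival step table.
    """
    from .survival import km_estimate

    ctx = CohortContext(cohort, config, genes=list(genes))
    rec = evaluate_combo(ctx, tuple(sorted(genes)), config)
    mask = ctx.mask(tuple(sorted(genes)))
    if mask.sum() == 0 or mask.all():
        raise ValueError("altered group is empty (or everyone is altered); nothing to export")
    time = ctx.surv.time
    event = ctx.surv.event
    g = mask[ctx.surv.order]
    rows = []
    for label, sel in (("altered", g), ("not_altered", ~g)):
        km = km_estimate(time[sel], event[sel])
        t = km.to_table()
        t.insert(0, "group", label)
        rows.append(t)
    table = pd.concat(rows, ignore_index=True)
    header = [
        f"# genes: {'+'.join(sorted(genes))}",
        f"# cohort: {cohort.name} endpoint: {cohort.endpoint} scope: {'+'.join(config.subtype_scope)}",
        f"# N_altered={rec['n_altered']} NE_altered={rec['n_events_altered']}",
        f"# N_not_altered={rec['n'] - rec['n_altered']} NE_not_altered={rec['n_events_unaltered']}",
        f"# logrank_p={rec['logrank_p']:.6g} HR={rec['hr']:.6g} "
        f"CI=[{rec['ci_low']:.6g}, {rec['ci_high']:.6g}]",
    ]
    with open(out_path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        table.to_csv(fh, sep="\t", index=False, float_format="%.10g")
    return table
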