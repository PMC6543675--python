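"""Subtype-specific secretion calling from an LFQ intensity matrix.

The pipeline stage is: row z-scoring of log2 intensities, pattern matching
of per-cell-line mean z profiles against reference profiles (Pearson r),
one-way ANOVA across cell lines as the statistical validation, and a
partition of the validated proteins into subtype x direction x support
classes.  Ward/euclidean hierarchical clustering supplies the heatmap row
ordering, and an overlap report quantifies agreement with known-secretome
reference sets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from statsmodels.stats.multitest import multipletests

from .io import LfqMatrix

log = logging.getLogger(__name__)

__all__ = [
    "zscore_rows",
    "handle_missing",
    "cell_line_means",
    "make_reference_profiles",
    "profile_match",
    "anova_validate",
    "call_subtype_specific",
    "ward_cluster_order",
    "overlap_report",
]


def zscore_rows(matrix: LfqMatrix) -> LfqMatrix:
    """Z-score each protein row over its observed entries (population sd).

    Rows with fewer than two observed values, or zero spread, cannot be
    standardised; they are dropped with a logged warning.  Missing entries
    stay missing.
    """
    vals = matrix.values.to_numpy(dtype=float)
    obs = np.isfinite(vals)
    n_obs = obs.sum(axis=1)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(np.where(obs, vals, np.nan), axis=1)
        sd = np.nanstd(np.where(obs, vals, np.nan), axis=1)  # population sd
    ok = (n_obs >= 2) & (sd > 0)
    dropped = matrix.values.index[~ok]
    if len(dropped):
        log.warning("zscore_rows: dropping %d rows with <2 observed values or zero spread", len(dropped))
    z = (vals[ok] - mean[ok, None]) / sd[ok, None]
    out = pd.DataFrame(z, index=matrix.values.index[ok], columns=matrix.values.columns)
    return LfqMatrix(values=out, samples=matrix.samples)


def handle_missing(
    matrix: LfqMatrix,
    min_valid_per_group: int = 3,
    impute: bool = False,
    seed: int = 0,
    shift_sd: float = 1.8,
    width_sd: float = 0.3,
) -> LfqMatrix:
    """Filter on per-cell-line detection and optionally impute.

    A protein is kept only if it is observed in at least
    ``min_valid_per_group`` samples of at least one cell line.  When
    ``impute`` is set, remaining missing values are drawn from a
    down-shifted normal (mean = row mean - 1.8 * row sd, sd = 0.3 * row sd),
    the usual convention for values missing because they fell below the
    detection limit.
    """
    if min_valid_per_group < 1:
        raise ValueError("min_valid_per_group must be >= 1")
    vals = matrix.values
    obs = vals.notna()
    keep = pd.Series(False, index=vals.index)
    for cl in matrix.cell_lines:
        cols = matrix.columns_of(cl)
        keep |= obs[cols].sum(axis=1) >= min_valid_per_group
    if not keep.any():
        raise ValueError("no quantifiable proteins after missing-value filtering")
    out = vals.loc[keep].copy()
    if impute:
        rng = np.random.default_rng(seed)
        arr = out.to_numpy(dtype=float)
        miss = ~np.isfinite(arr)
        mean = np.nanmean(arr, axis=1)
        sd = np.nanstd(arr, axis=1)
        sd = np.where(sd > 0, sd, 1.0)
        draws = rng.normal(
            loc=(mean - shift_sd * sd)[:, None],
            scale=(width_sd * sd)[:, None],
            size=arr.shape,
        )
        arr[miss] = draws[miss]
        out = pd.DataFrame(arr, index=out.index, columns=out.columns)
    return LfqMatrix(values=out, samples=matrix.samples)


def cell_line_means(matrix: LfqMatrix) -> pd.DataFrame:
    """Per-cell-line mean of each protein row (proteins x cell lines)."""
    cols = {cl: matrix.columns_of(cl) for cl in matrix.cell_lines}
    return pd.DataFrame(
        {cl: matrix.values[c].mean(axis=1) for cl, c in cols.items()}
    )


def make_reference_profiles(matrix: LfqMatrix, include_single_line: bool = True) -> pd.DataFrame:
    """Reference secretion profiles over cell-line means.

    The four canonical profiles target both cell lines of a cancer subtype
    (basal-up/-down, luminal-up/-down; the control line always sits at the
    non-target level).  ``include_single_line`` adds one up and one down
    profile per individual cancer cell line so that proteins altered in
    only one line of a subtype can still be matched.  Pearson correlation
    is location/scale free, so only the shape of a profile matters.
    """
    lines = matrix.cell_lines
    rows: dict[str, list[float]] = {}
    for subtype in ("basal", "luminal"):
        members = matrix.lines_of_subtype(subtype)
        if not members:
            continue
        up = [1.0 if cl in members else 0.0 for cl in lines]
        rows[f"{subtype}-up"] = up
        rows[f"{subtype}-down"] = [-v for v in up]
        if include_single_line and len(members) > 1:
            for cl in members:
                single = [1.0 if c == cl else 0.0 for c in lines]
                rows[f"{cl}-up"] = single
                rows[f"{cl}-down"] = [-v for v in single]
    return pd.DataFrame.from_dict(rows, orient="index", columns=lines)


def profile_match(
    mean_z: pd.DataFrame,
    profiles: pd.DataFrame,
    r_threshold: float = 0.8,
) -> pd.DataFrame:
    """Assign each protein the reference profile with maximal Pearson r.

    Proteins whose best correlation falls below ``r_threshold`` (or whose
    mean-z vector has zero variance) are reported as unmatched.  Ties are
    broken by profile order, which makes the assignment deterministic.
    """
    if not (-1 < r_threshold < 1):
        raise ValueError("r_threshold must lie in (-1, 1)")
    cols = list(mean_z.columns)
    P = profiles[cols].to_numpy(dtype=float)
    X = mean_z.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    Pc = P - P.mean(axis=1, keepdims=True)
    xs = np.sqrt((Xc**2).sum(axis=1))
    ps = np.sqrt((Pc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ Pc.T) / np.outer(xs, ps)
    r = np.where(np.isfinite(r), r, -np.inf)  # zero-variance rows never match
    best = np.argmax(r, axis=1)  # argmax keeps the first (profile order) on ties
    best_r = r[np.arange(len(X)), best]
    matched = best_r >= r_threshold
    names = profiles.index.to_numpy()
    return pd.DataFrame(
        {
            "profile": np.where(matched, names[best], "unmatched"),
            "pattern_r": np.where(np.isfinite(best_r), best_r, np.nan),
        },
        index=mean_z.index,
    )


def anova_validate(matrix: LfqMatrix, average_tech: bool = True) -> pd.DataFrame:
    """One-way ANOVA of each protein across cell lines.

    Technical replicates are averaged into their biological replicate by
    default so the per-group observations are independent; groups with
    fewer than two observations are dropped for that protein, and proteins
    left with fewer than two usable groups (or no variance at all) get
    a missing p-value.
    """
    ann = matrix.samples.loc[list(matrix.values.columns)]
    vals = matrix.values
    line_arrays = {}
    for cl in matrix.cell_lines:
        cols = matrix.columns_of(cl)
        sub = vals[cols]
        if average_tech:
            bio = ann.loc[cols, "bio_rep"]
            sub = sub.T.groupby(bio.to_numpy()).mean().T
        line_arrays[cl] = sub.to_numpy(dtype=float)

    n = len(vals)
    F = np.full(n, np.nan)
    p = np.full(n, np.nan)
    for i in range(n):
        obs = []
        for cl, arr in line_arrays.items():
            row = arr[i]
            row = row[np.isfinite(row)]
            if row.size >= 2:
                obs.append(row)
        if len(obs) < 2:
            continue
        pooled = np.concatenate(obs)
        if np.ptp(pooled) == 0:  # no variance anywhere: F undefined
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.f_oneway(*obs)
        if np.isfinite(res.statistic):
            F[i], p[i] = res.statistic, res.pvalue
    return pd.DataFrame({"F": F, "anova_p": p}, index=vals.index)


@dataclass
class _ProfileTarget:
    subtype: str
    direction: str
    target_lines: list[str]


def _parse_profile(name: str, matrix: LfqMatrix) -> _ProfileTarget | None:
    if name == "unmatched" or "-" not in name:
        return None
    stem, direction = name.rsplit("-", 1)
    direction = {"up": "increased", "down": "decreased"}.get(direction)
    if direction is None:
        return None
    if stem in ("basal", "luminal"):
        return _ProfileTarget(stem, direction, matrix.lines_of_subtype(stem))
    if stem in matrix.cell_lines:
        subtype = matrix.subtype_of(stem)
        if subtype in ("basal", "luminal"):
            return _ProfileTarget(subtype, direction, [stem])
    return None


def call_subtype_specific(
    matrix: LfqMatrix,
    mean_z: pd.DataFrame,
    matches: pd.DataFrame,
    anova: pd.DataFrame,
    anova_p_threshold: float = 0.05,
    direction_margin: float = 0.5,
    adjust_bh: bool = False,
) -> pd.DataFrame:
    """Partition matched, ANOVA-validated proteins into secretion calls.

    A call (subtype, direction, support) requires: a matched reference
    profile; ANOVA p below the threshold; mean z beyond
    ``direction_margin`` in the supporting line(s); and every cell line
    outside the subtype at the neutral-or-opposite level.  Support is
    ``both_lines`` when the direction holds in every line of the subtype,
    ``one_line`` otherwise.  ``adjust_bh`` optionally applies a BH
    correction to the ANOVA p-values before thresholding.
    """
    p = anova["anova_p"].copy()
    if adjust_bh:
        finite = p.notna()
        adj = p.copy()
        adj[finite] = multipletests(p[finite], method="fdr_bh")[1]
        p = adj
    records = []
    for pid in mean_z.index:
        prof_name = matches.at[pid, "profile"]
        target = _parse_profile(str(prof_name), matrix)
        if target is None:
            continue
        pv = p.get(pid, np.nan)
        if not np.isfinite(pv) or pv >= anova_p_threshold:
            continue
        mz = mean_z.loc[pid]
        sign = 1.0 if target.direction == "increased" else -1.0
        subtype_lines = matrix.lines_of_subtype(target.subtype)
        other_lines = [cl for cl in matrix.cell_lines if cl not in subtype_lines]
        # direction must not hold in any line outside the subtype
        if any(sign * mz[cl] >= direction_margin for cl in other_lines):
            continue
        supporting = [cl for cl in target.target_lines if sign * mz[cl] >= direction_margin]
        if not supporting:
            continue
        # non-target lines of the same subtype must stay neutral/opposite
        off_target = [cl for cl in subtype_lines if cl not in target.target_lines]
        if any(sign * mz[cl] >= direction_margin for cl in off_target):
            continue
        support = "both_lines" if set(supporting) == set(subtype_lines) else "one_line"
        records.append(
            {
                "protein_id": pid,
                "subtype": target.subtype,
                "direction": target.direction,
                "support": support,
                "supporting_cell_lines": "+".join(supporting),
                "anova_p": float(pv),
                "pattern_r": float(matches.at[pid, "pattern_r"]),
                "profile": str(prof_name),
            }
        )
    return pd.DataFrame.from_records(
        records,
        columns=[
            "protein_id", "subtype", "direction", "support",
            "supporting_cell_lines", "anova_p", "pattern_r", "profile",
        ],
    )


def ward_cluster_order(values: pd.DataFrame, axis: str = "rows"):
    """Ward/euclidean leaf ordering of rows or columns.

    Uses Ward linkage on unsquared euclidean distances (the ward.D2
    convention).  Missing values must be imputed first.

    Returns ``(ordered_labels, linkage_matrix)``.
    """
    X = values.to_numpy(dtype=float)
    labels = values.index
    if axis in ("columns", "cols", 1):
        X = X.T
        labels = values.columns
    if X.shape[0] < 2:
        raise ValueError("need at least 2 observations to cluster")
    if not np.isfinite(X).all():
        raise ValueError("missing values present: impute before clustering")
    Z = linkage(X, method="ward")
    order = leaves_list(Z)
    return list(labels[order]), Z


def overlap_report(identified, reference_sets: dict) -> pd.DataFrame:
    """Intersection counts of identified proteins against named reference sets."""
    ident = set(identified)
    n = len(ident)
    rows = []
    for name, ref in reference_sets.items():
        ref = set(ref)
        if not ref:
            warnings.warn(f"reference set {name!r} is empty")
        inter = len(ident & ref)
        rows.append(
            {
                "set": name,
                "n_identified": n,
                "n_reference": len(ref),
                "n_overlap": inter,
                "fraction_of_identified": inter / n if n else 0.0,
            }
        )
    return pd.DataFrame(rows)
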