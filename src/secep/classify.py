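"""SeCEP gene classification against patient expression cohorts.

Links subtype-specific secretion calls to patient transcriptomes: a
per-gene Mann-Whitney-Wilcoxon test between Basal and LumA+LumB patients
on the mRNA z-scores, Benjamini-Hochberg adjustment over the full gene
family measured in the cohort, and the classification rule — a gene is a
basal SeCEP gene iff its adjusted p-value is below alpha and its median
z-score is greater among Basal patients (and symmetrically for luminal),
optionally restricted to genes whose protein showed increased secretion
in the matching subtype (concordance).

The BH family defaults to every gene present in the cohort matrix, not
only the secretome genes; shrinking the family can only shrink adjusted
p-values, so the family size is part of the result provenance and is
logged by the pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations as _combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionCohort

log = logging.getLogger(__name__)

__all__ = [
    "mann_whitney_gene",
    "mann_whitney_matrix",
    "bh_adjust",
    "cohort_gene_stats",
    "classify_secep",
    "intersect_secep",
    "SecepResult",
]

EXACT_MAX_N = 7  # per-group size at or below which the exact path is used


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U of sample *a* (ties count one half)."""
    return float((a[:, None] > b[None, :]).sum() + 0.5 * (a[:, None] == b[None, :]).sum())


def _exact_two_sided_p(a: np.ndarray, b: np.ndarray, u_obs: float) -> float:
    """Exact two-sided p by enumeration of all group-label assignments.

    Counts assignments whose U deviates from the null mean n1*n2/2 at
    least as much as the observed U; handles ties, unlike a table lookup.
    """
    pooled = np.concatenate([a, b])
    n1 = len(a)
    mu = n1 * len(b) / 2.0
    dev = abs(u_obs - mu) - 1e-12
    idx = np.arange(pooled.size)
    hits = 0
    total = comb(pooled.size, n1)
    for chosen in _combinations(idx, n1):
        sel = np.zeros(pooled.size, dtype=bool)
        sel[list(chosen)] = True
        u = _u_statistic(pooled[sel], pooled[~sel])
        if abs(u - mu) >= dev:
            hits += 1
    return hits / total


def mann_whitney_gene(values_a, values_b) -> dict:
    """Two-sided Mann-Whitney-Wilcoxon test for one gene.

    Uses exact enumeration when both groups have at most seven observed
    values and the tie-corrected normal approximation with continuity
    correction otherwise.  Returns the U statistic of group A, both group
    medians, the p-value and the method used.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 1 or b.size < 1:
        raise ValueError("each group needs at least one observed value")
    u = _u_statistic(a, b)
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        p, method = 1.0, "degenerate"
    elif a.size <= EXACT_MAX_N and b.size <= EXACT_MAX_N:
        p, method = _exact_two_sided_p(a, b, u), "exact"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        p, method = float(res.pvalue), "asymptotic"
    return {
        "U": u,
        "p": min(p, 1.0),
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
        "method": method,
    }


def mann_whitney_matrix(z: pd.DataFrame, group_a, group_b) -> pd.DataFrame:
    """Row-wise Mann-Whitney tests of a gene x patient matrix.

    ``group_a``/``group_b`` are patient-id lists.  Large groups take a
    single vectorised asymptotic pass; small groups fall back to the
    per-gene exact path of :func:`mann_whitney_gene`.
    """
    A = z[list(group_a)].to_numpy(dtype=float)
    B = z[list(group_b)].to_numpy(dtype=float)
    n1, n2 = A.shape[1], B.shape[1]
    small = n1 <= EXACT_MAX_N and n2 <= EXACT_MAX_N
    finite = np.isfinite(A).all() and np.isfinite(B).all()
    if small or not finite:
        rows = [mann_whitney_gene(A[i], B[i]) for i in range(len(z))]
        out = pd.DataFrame(rows, index=z.index)
        out = out.rename(columns={"p": "raw_p", "median_a": "median_a", "median_b": "median_b"})
        return out[["U", "raw_p", "median_a", "median_b"]]
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.mannwhitneyu(A, B, alternative="two-sided", method="asymptotic", axis=1)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = np.ptp(np.hstack([A, B]), axis=1) == 0
    p[degenerate] = 1.0
    return pd.DataFrame(
        {
            "U": np.asarray(res.statistic, dtype=float),
            "raw_p": np.minimum(p, 1.0),
            "median_a": np.median(A, axis=1),
            "median_b": np.median(B, axis=1),
        },
        index=z.index,
    )


def bh_adjust(raw_p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(raw_p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def cohort_gene_stats(cohort: ExpressionCohort, family: str = "all") -> pd.DataFrame:
    """Basal vs LumA+LumB Mann-Whitney statistics with BH adjustment.

    The test populations are the Basal patients versus the union of LumA
    and LumB patients (Her2 and Normal-like patients do not enter the
    classification).  ``family='all'`` adjusts over every gene in the
    cohort matrix, which is the convention this pipeline follows; the
    returned frame carries medians per group so the classification rule
    can be applied downstream.
    """
    pam = cohort.clinical["pam50"]
    basal = list(pam.index[pam == "Basal"])
    luminal = list(pam.index[pam.isin(["LumA", "LumB"])])
    if not basal or not luminal:
        raise ValueError("cohort must contain Basal and LumA/LumB patients")
    stats_df = mann_whitney_matrix(cohort.z, basal, luminal)
    stats_df = stats_df.rename(columns={"median_a": "median_basal", "median_b": "median_luminal"})
    stats_df["adjusted_p"] = bh_adjust(stats_df["raw_p"].to_numpy())
    stats_df.attrs["family_size"] = len(stats_df)
    log.info(
        "cohort %s: BH family size %d (%d Basal vs %d LumA/B patients)",
        cohort.name, len(stats_df), len(basal), len(luminal),
    )
    return stats_df


@dataclass
class SecepResult:
    """Classification output: SeCEP genes plus transparency side tables."""

    secep: pd.DataFrame
    discordant: pd.DataFrame
    not_measured: list = field(default_factory=list)


_SECEP_COLUMNS = [
    "gene_id", "secep_subtype", "raw_p", "adjusted_p",
    "median_basal", "median_luminal", "median_difference",
    "secretion_direction", "concordant",
]


def classify_secep(
    stats_df: pd.DataFrame,
    secretion_calls: pd.DataFrame | None = None,
    alpha: float = 0.05,
    require_concordance: bool = True,
) -> SecepResult:
    """Classify genes by secretion-correlated expression pattern.

    A gene is basal-SeCEP iff adjusted_p < alpha and its median z among
    Basal patients exceeds the LumA/B median; luminal-SeCEP for the
    reverse.  When secretion calls are supplied and concordance is
    required, only genes whose protein secretion is *increased* in the
    matching subtype are retained; significant-but-discordant genes are
    reported separately.  Called genes absent from the cohort are listed
    in ``not_measured``.
    """
    calls = None
    not_measured: list = []
    if secretion_calls is not None and len(secretion_calls):
        calls = secretion_calls.copy()
        if "gene_id" not in calls.columns:
            from .io import split_protein_id

            calls["gene_id"] = [split_protein_id(p)[1] for p in calls["protein_id"]]
        calls = calls.drop_duplicates(subset="gene_id").set_index("gene_id")
        not_measured = sorted(set(calls.index) - set(stats_df.index))
        if not_measured:
            log.warning("%d called genes not measured in cohort: %s",
                        len(not_measured), not_measured[:10])

    sig = stats_df["adjusted_p"] < alpha
    diff = stats_df["median_basal"] - stats_df["median_luminal"]
    subtype = np.where(diff > 0, "basal", np.where(diff < 0, "luminal", "none"))

    rows, discordant_rows = [], []
    for gene in stats_df.index[sig]:
        st = subtype[stats_df.index.get_loc(gene)]
        if st == "none":
            continue
        sec_dir, sec_sub = None, None
        if calls is not None:
            if gene not in calls.index:
                continue  # classification restricted to called genes
            sec_dir = calls.at[gene, "direction"]
            sec_sub = calls.at[gene, "subtype"]
        concordant = sec_dir == "increased" and sec_sub == st
        rec = {
            "gene_id": gene,
            "secep_subtype": st,
            "raw_p": float(stats_df.at[gene, "raw_p"]),
            "adjusted_p": float(stats_df.at[gene, "adjusted_p"]),
            "median_basal": float(stats_df.at[gene, "median_basal"]),
            "median_luminal": float(stats_df.at[gene, "median_luminal"]),
            "median_difference": abs(float(diff.loc[gene])),
            "secretion_direction": sec_dir,
            "concordant": bool(concordant) if calls is not None else None,
        }
        if calls is None or concordant or not require_concordance:
            rows.append(rec)
        if calls is not None and not concordant:
            discordant_rows.append(rec)
    return SecepResult(
        secep=pd.DataFrame(rows, columns=_SECEP_COLUMNS),
        discordant=pd.DataFrame(discordant_rows, columns=_SECEP_COLUMNS),
        not_measured=not_measured,
    )


def intersect_secep(results: dict) -> pd.DataFrame:
    """Genes classified with the same SeCEP subtype in every cohort.

    ``results`` maps cohort name -> SeCEP DataFrame.  The strict reading
    of cross-cohort consistency: the working SeCEP set is the
    intersection.
    """
    items = list(results.items())
    if not items:
        raise ValueError("no classification results supplied")
    first_name, first = items[0]
    keep = []
    for _, row in first.iterrows():
        gene, st = row["gene_id"], row["secep_subtype"]
        if all(
            ((df["gene_id"] == gene) & (df["secep_subtype"] == st)).any()
            for _, df in items[1:]
        ):
            keep.append(row)
    out = pd.DataFrame(keep, columns=first.columns)
    out.attrs["cohorts"] = [name for name, _ in items]
    return out.reset_index(drop=True)
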