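"""Synthetic LFQ secretome matrices and paired survival cohorts.

The generator produces data with exactly the statistical structure the
analysis assumes, so every stage of the pipeline is testable end to end
without any external download:

* an LFQ matrix over a five-cell-line panel (two basal, two luminal, one
  non-malignant control; three biological x two technical replicates per
  line) with planted subtype-specific secretion shifts and
  intensity-dependent missingness;
* a discovery/validation pair of patient cohorts with PAM50 labels,
  standard-normal gene z-scores, planted subtype-differential genes, a
  latent co-overexpressing patient subgroup per planted combination, and
  right-censored exponential survival coupled to subgroup membership
  through a hazard ratio.

All randomness flows from a single master seed through a documented
counter scheme (``numpy`` ``SeedSequence`` spawn keys: 0 = LFQ,
1 = discovery cohort, 2 = validation cohort), so adding one table never
perturbs another.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from scipy.optimize import brentq

from .io import ExpressionCohort, LfqMatrix, write_cohort, write_lfq

__all__ = [
    "CellLineSpec",
    "PlantedCombo",
    "SimConfig",
    "simulate_lfq",
    "simulate_cohort_pair",
    "write_fixture_bundle",
    "read_fixture_bundle",
    "expected_event_fraction",
    "solve_combo_shift",
]


@dataclass(frozen=True)
class CellLineSpec:
    name: str
    subtype: str  # basal | luminal | control
    n_bio: int = 3
    n_tech: int = 2


DEFAULT_PANEL = (
    CellLineSpec("MDA-231", "basal"),
    CellLineSpec("HCC1806", "basal"),
    CellLineSpec("MCF7", "luminal"),
    CellLineSpec("T47D", "luminal"),
    CellLineSpec("MCF10A", "control"),
)


@dataclass(frozen=True)
class PlantedCombo:
    """A latent high-risk patient subgroup defined by joint overexpression."""

    genes: tuple
    subtype: str = "Basal"
    fraction: float = 0.15
    hazard_ratio: float = 3.0

    def __post_init__(self):
        if not (0 < self.fraction < 1):
            raise ValueError("subgroup fraction must lie in (0, 1)")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard ratio must be positive")


@dataclass
class SimConfig:
    """Study conditions for the synthetic data.

    LFQ side: 500 proteins with 50 planted basal-increased at a 1.5-unit
    shift against replicate noise sd 0.4 and 10% intensity-biased
    missingness.  Patient side: 150 Basal + 150 LumA + 150 LumB patients,
    2,000 genes, 100 planted basal-shifted by delta = 1.0 z.  Survival is
    exponential at 0.006 events/month with a 180-month administrative
    horizon and 15% uniform dropout, giving a realistic ~55% event
    fraction for a long-running breast-cancer overall-survival cohort.
    """

    seed: int = 0
    # LFQ matrix
    n_proteins: int = 500
    cell_lines: tuple = DEFAULT_PANEL
    n_planted_secretion: int = 50
    planted_secretion_subtype: str = "basal"
    secretion_shift: float = 1.5
    lfq_baseline_mean: float = 26.0
    lfq_baseline_sd: float = 2.0
    lfq_noise_sd: float = 0.4
    missing_rate: float = 0.10
    missing_intensity_bias: float = 1.0
    # patient cohorts
    n_patients_by_subtype: dict = field(
        default_factory=lambda: {"Basal": 150, "LumA": 150, "LumB": 150}
    )
    n_genes: int = 2000
    n_planted_diff_genes: int = 100
    diff_shift: float = 1.0
    diff_subtype: str = "Basal"
    planted_combos: tuple = ()
    baseline_hazard: float = 0.006  # events per month
    horizon_months: float = 180.0
    dropout_rate: float = 0.15
    endpoint: str = "OS"

    def gene_ids(self):
        width = len(str(self.n_genes))
        return [f"G{i + 1:0{width}d}" for i in range(self.n_genes)]

    def to_yaml(self, path):
        data = dataclasses.asdict(self)
        data["cell_lines"] = [dataclasses.asdict(c) for c in self.cell_lines]
        data["planted_combos"] = [
            {**dataclasses.asdict(c), "genes": list(c.genes)} for c in self.planted_combos
        ]
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path):
        data = yaml.safe_load(Path(path).read_text())
        data["cell_lines"] = tuple(CellLineSpec(**c) for c in data.get("cell_lines", []))
        data["planted_combos"] = tuple(
            PlantedCombo(**{**c, "genes": tuple(c["genes"])})
            for c in data.get("planted_combos", [])
        )
        return cls(**data)


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(stream,)))


# ------------------------------------------------------------------ LFQ side

def simulate_lfq(config: SimConfig):
    """Generate an :class:`LfqMatrix` plus a planted-protein truth table.

    Planted proteins receive ``secretion_shift`` in every replicate column
    of the target subtype's cell lines; replicate noise is
    N(0, lfq_noise_sd); missingness probability decreases with intensity
    (rows that end up with <2 observed values are redrawn).
    """
    rng = _rng(config, 0)
    samples = []
    for cl in config.cell_lines:
        for b in range(1, cl.n_bio + 1):
            for t in range(1, cl.n_tech + 1):
                samples.append(
                    {
                        "sample_id": f"{cl.name}_b{b}_t{t}",
                        "cell_line": cl.name,
                        "subtype": cl.subtype,
                        "bio_rep": b,
                        "tech_rep": t,
                    }
                )
    sheet = pd.DataFrame(samples).set_index("sample_id")
    target_cols = np.array(
        [sheet.loc[sid, "subtype"] == config.planted_secretion_subtype for sid in sheet.index]
    )
    gene_ids = config.gene_ids()
    if config.n_proteins > config.n_genes:
        raise ValueError("n_proteins cannot exceed n_genes (shared namespace)")
    protein_ids = [f"P{i + 1:04d}|{gene_ids[i]}" for i in range(config.n_proteins)]
    planted = np.zeros(config.n_proteins, dtype=bool)
    planted[: config.n_planted_secretion] = True

    n_s = len(sheet)
    baseline = rng.normal(config.lfq_baseline_mean, config.lfq_baseline_sd, config.n_proteins)
    vals = baseline[:, None] + rng.normal(0.0, config.lfq_noise_sd, (config.n_proteins, n_s))
    vals[np.ix_(planted, target_cols)] += config.secretion_shift

    # intensity-biased missingness: standardise matrix-wide, higher
    # abundance -> lower dropout probability; E[p] equals missing_rate.
    mu, sd = vals.mean(), vals.std()
    s = (vals - mu) / sd
    pmiss = np.clip(
        2.0 * config.missing_rate * stats.norm.sf(config.missing_intensity_bias * s), 0, 0.95
    )
    miss = rng.random(vals.shape) < pmiss
    # degenerate rows (<2 observed) are redrawn rather than emitted
    for _ in range(100):
        bad = (~miss).sum(axis=1) < 2
        if not bad.any():
            break
        import warnings

        warnings.warn(f"regenerating {bad.sum()} degenerate LFQ rows")
        miss[bad] = rng.random((bad.sum(), n_s)) < pmiss[bad]
    out = vals.copy()
    out[miss] = np.nan
    matrix = LfqMatrix(
        values=pd.DataFrame(out, index=protein_ids, columns=sheet.index),
        samples=sheet,
    )
    truth = pd.DataFrame(
        {
            "protein_id": protein_ids,
            "gene_id": gene_ids[: config.n_proteins],
            "planted": planted,
            "subtype": np.where(planted, config.planted_secretion_subtype, ""),
            "direction": np.where(planted, "increased", ""),
        }
    )
    return matrix, truth


# -------------------------------------------------------------- patient side

def solve_combo_shift(fraction: float, n_genes: int, mu_max: float = 12.0) -> float:
    """Shift (z units) for subgroup members so the AND-mask captures ~fraction.

    With a fraction ``f`` of the population shifted by ``mu`` on each of
    ``g`` genes, the per-gene median ``m`` satisfies
    ``f * Phi_bar(m - mu) + (1 - f) * Phi_bar(m) = 1/2`` and the expected
    altered fraction is ``f * p_m**g + (1 - f) * p_n**g`` with
    ``p_m = Phi_bar(m - mu)``, ``p_n = Phi_bar(m)``.  Solved for ``mu`` by
    bisection; a target below the no-shift baseline ``0.5**g`` (e.g. any
    single-gene fraction other than 0.5) is infeasible under a median
    split and raises with guidance.
    """

    def expected_fraction(mu: float) -> float:
        def med_eq(m):
            return fraction * stats.norm.sf(m - mu) + (1 - fraction) * stats.norm.sf(m) - 0.5

        m = brentq(med_eq, -40, 40)
        p_m = stats.norm.sf(m - mu)
        p_n = stats.norm.sf(m)
        return fraction * p_m**n_genes + (1 - fraction) * p_n**n_genes

    lo = expected_fraction(0.0)  # = 0.5 ** n_genes
    if fraction <= lo:
        raise ValueError(
            f"subgroup fraction {fraction} is infeasible for a {n_genes}-gene "
            f"median-split mask (minimum ~{lo:.3g}); use more genes or a larger fraction"
        )
    return brentq(lambda mu: expected_fraction(mu) - fraction, 0.0, mu_max)


def expected_event_fraction(config: SimConfig, hazard: float | None = None) -> float:
    """Closed-form event probability under exponential hazard + censoring."""
    lam = config.baseline_hazard if hazard is None else hazard
    T, q = config.horizon_months, config.dropout_rate
    p_admin = 1.0 - np.exp(-lam * T)
    p_drop = 1.0 - p_admin / (lam * T)  # E[1 - exp(-lam U)], U ~ Uniform(0, T)
    return (1 - q) * p_admin + q * p_drop


def _simulate_one_cohort(config: SimConfig, rng: np.random.Generator, name: str):
    gene_ids = config.gene_ids()
    subtype_names = list(config.n_patients_by_subtype)
    patients, pam50 = [], []
    for st in subtype_names:
        n = config.n_patients_by_subtype[st]
        start = len(patients)
        patients.extend(f"{name}_{st}_{i + 1:04d}" for i in range(n))
        pam50.extend([st] * n)
    pam50 = np.array(pam50)
    n_pat = len(patients)

    z = rng.normal(0.0, 1.0, (config.n_genes, n_pat))
    diff_genes = gene_ids[: config.n_planted_diff_genes]
    in_target = pam50 == config.diff_subtype
    z[: config.n_planted_diff_genes, :][:, in_target] += config.diff_shift

    gene_index = {g: i for i, g in enumerate(gene_ids)}
    seen: set = set()
    members = np.zeros(n_pat, dtype=bool)
    member_idx: list = []
    combo_truth = []
    for combo in config.planted_combos:
        overlap = seen & set(combo.genes)
        if overlap:
            raise ValueError(f"gene(s) {sorted(overlap)} appear in more than one planted combo")
        seen |= set(combo.genes)
        missing = [g for g in combo.genes if g not in gene_index]
        if missing:
            raise ValueError(f"planted combo genes not in gene list: {missing}")
        scope = np.flatnonzero(pam50 == combo.subtype)
        if scope.size == 0:
            raise ValueError(f"no {combo.subtype} patients for planted combo {combo.genes}")
        n_sub = int(round(combo.fraction * scope.size))
        chosen = rng.choice(scope, size=n_sub, replace=False)
        mu = solve_combo_shift(combo.fraction, len(combo.genes))
        rows = [gene_index[g] for g in combo.genes]
        z[np.ix_(rows, chosen)] += mu
        members[chosen] = True
        member_idx.append(chosen)
        combo_truth.append(
            {
                "genes": list(combo.genes),
                "subtype": combo.subtype,
                "fraction": combo.fraction,
                "hazard_ratio": combo.hazard_ratio,
                "shift": mu,
                "members": [patients[i] for i in chosen],
            }
        )

    # survival: exponential with per-patient hazard; membership in any
    # planted subgroup multiplies the baseline hazard by that combo's HR
    hazard = np.full(n_pat, config.baseline_hazard)
    for rec, idx in zip(combo_truth, member_idx):
        hazard[idx] = config.baseline_hazard * rec["hazard_ratio"]
    event_time = rng.exponential(1.0 / hazard)
    censor = np.full(n_pat, config.horizon_months)
    dropout = rng.random(n_pat) < config.dropout_rate
    censor[dropout] = rng.uniform(0.0, config.horizon_months, int(dropout.sum()))
    time = np.minimum(event_time, censor)
    event = event_time <= censor
    time = np.maximum(np.round(time, 2), 0.01)

    clinical = pd.DataFrame(
        {"pam50": pam50, "time_months": time, "event": event},
        index=pd.Index(patients, name="patient_id"),
    )
    cohort = ExpressionCohort(
        name=name,
        z=pd.DataFrame(z, index=gene_ids, columns=patients),
        clinical=clinical,
        endpoint=config.endpoint,
    )
    truth = {
        "diff_genes": diff_genes,
        "diff_subtype": config.diff_subtype,
        "combos": combo_truth,
        "members_any": [patients[i] for i in np.flatnonzero(members)],
    }
    return cohort, truth


def simulate_cohort_pair(config: SimConfig):
    """Independent discovery/validation cohorts plus their truth tables."""
    discovery, truth_d = _simulate_one_cohort(config, _rng(config, 1), "discovery")
    validation, truth_v = _simulate_one_cohort(config, _rng(config, 2), "validation")
    return discovery, validation, {"discovery": truth_d, "validation": truth_v}


# ---------------------------------------------------------------- fixtures

def write_fixture_bundle(config: SimConfig, out_dir) -> dict:
    """Write the full synthetic input bundle in the pipeline's TSV dialects.

    Emits the LFQ matrix + sample sheet, both cohorts' expression and
    clinical tables, the truth tables, and the config as YAML.  Returns
    the path inventory.  Byte-identical across calls with the same config.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, lfq_truth = simulate_lfq(config)
    discovery, validation, truth = simulate_cohort_pair(config)
    paths = {
        "lfq_matrix": out / "lfq_matrix.tsv",
        "lfq_samples": out / "lfq_samples.tsv",
        "lfq_truth": out / "lfq_truth.tsv",
        "expr_discovery": out / "expr_discovery.tsv",
        "clinical_discovery": out / "clinical_discovery.tsv",
        "expr_validation": out / "expr_validation.tsv",
        "clinical_validation": out / "clinical_validation.tsv",
        "cohort_truth": out / "cohort_truth.json",
        "config": out / "config.yaml",
    }
    write_lfq(matrix, paths["lfq_matrix"], paths["lfq_samples"])
    lfq_truth.to_csv(paths["lfq_truth"], sep="\t", index=False)
    write_cohort(discovery, paths["expr_discovery"], paths["clinical_discovery"])
    write_cohort(validation, paths["expr_validation"], paths["clinical_validation"])
    paths["cohort_truth"].write_text(json.dumps(truth, indent=1, sort_keys=True))
    config.to_yaml(paths["config"])
    return {k: str(v) for k, v in paths.items()}


def read_fixture_bundle(bundle_dir):
    """Load a fixture bundle back through the standard pipeline readers."""
    from .io import read_cohort, read_lfq

    d = Path(bundle_dir)
    config = SimConfig.from_yaml(d / "config.yaml")
    matrix = read_lfq(d / "lfq_matrix.tsv", d / "lfq_samples.tsv")
    discovery = read_cohort(
        d / "expr_discovery.tsv", d / "clinical_discovery.tsv", "discovery", config.endpoint
    )
    validation = read_cohort(
        d / "expr_validation.tsv", d / "clinical_validation.tsv", "validation", config.endpoint
    )
    truth = json.loads((d / "cohort_truth.json").read_text())
    return config, matrix, discovery, validation, truth
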