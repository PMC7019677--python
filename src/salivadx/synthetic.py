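"""Synthetic two-group cohort generator.

The salivary-biomarker study this package reanalyses published only group
summaries (per-gene mean +/- SD of relative expression, group sizes, an age
distribution and covariate frequencies), not per-subject values. This module
generates cohorts with exactly that statistical structure so every
downstream stage — quantification round-trips, group summaries, ROC/AUC,
panel building, age stratification — is testable end to end.

Per gene and group, expression is drawn from a log-normal distribution whose
parameters are solved from the target mean and SD (moment matching): relative
expression is strictly positive, right-skewed, and the original data were
reported as non-normal. A zero-truncated normal alternative is available via
``distribution="truncated_normal"`` for sensitivity checks.

Seeding uses independent substreams per (gene, group) derived from a single
master seed, so adding a gene to the configuration does not perturb the draws
of existing genes.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .containers import CASE, CONTROL, ExpressionMatrix

__all__ = [
    "GeneLevels",
    "AgeModel",
    "CohortConfig",
    "SyntheticCohort",
    "default_config",
    "simulate_cohort",
    "simulate_ct_plate",
]

_GROUPS = (CONTROL, CASE)


@dataclass(frozen=True)
class GeneLevels:
    """Target group moments for one gene, on the relative-expression scale."""

    control_mean: float
    control_sd: float
    case_mean: float
    case_sd: float
    #: additive expression change per year of age within each group (default:
    #: no age dependence; the source cohort reported but did not model one).
    age_effect: float = 0.0

    def moments(self, group: str) -> tuple[float, float]:
        if group == CONTROL:
            return self.control_mean, self.control_sd
        return self.case_mean, self.case_sd


@dataclass(frozen=True)
class AgeModel:
    """Per-group normal age distribution truncated to [min, max] years."""

    control_mean: float = 53.2
    control_sd: float = 17.4
    control_min: float = 25.0
    control_max: float = 83.0
    case_mean: float = 61.2
    case_sd: float = 18.1
    case_min: float = 24.0
    case_max: float = 97.0

    def params(self, group: str) -> tuple[float, float, float, float]:
        if group == CONTROL:
            return self.control_mean, self.control_sd, self.control_min, self.control_max
        return self.case_mean, self.case_sd, self.case_min, self.case_max


@dataclass
class CohortConfig:
    """Full specification of a synthetic two-group cohort."""

    genes: dict[str, GeneLevels]
    n_control: int = 34
    n_case: int = 33
    age: AgeModel = field(default_factory=AgeModel)
    #: covariate name -> (control rate, case rate) Bernoulli probabilities
    covariates: dict[str, tuple[float, float]] = field(default_factory=dict)
    distribution: str = "lognormal"  # or "truncated_normal"
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.genes:
            raise ValueError("configuration must name at least one gene")
        for name, g in self.genes.items():
            for fieldname in ("control_mean", "control_sd", "case_mean", "case_sd"):
                v = getattr(g, fieldname)
                if not np.isfinite(v) or v <= 0:
                    raise ValueError(
                        f"{name}.{fieldname} must be strictly positive, got {v!r}")
        if self.n_control < 2 or self.n_case < 2:
            raise ValueError("need at least 2 samples per group")
        if self.distribution not in ("lognormal", "truncated_normal"):
            raise ValueError(f"unknown distribution {self.distribution!r}")
        for name, (p0, p1) in self.covariates.items():
            if not (0 <= p0 <= 1 and 0 <= p1 <= 1):
                raise ValueError(f"covariate {name!r} rates must lie in [0, 1]")

    def n(self, group: str) -> int:
        return self.n_control if group == CONTROL else self.n_case

    def to_dict(self) -> dict:
        d = asdict(self)
        d["genes"] = {k: asdict(v) for k, v in self.genes.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        genes = {}
        for name, g in d["genes"].items():
            genes[name] = GeneLevels(**g)
        age = d.get("age", {})
        if isinstance(age, AgeModel):
            age_model = age
        elif set(age) <= {"control", "case"} and age:
            # nested YAML form: {control: {mean, sd, min, max}, case: {...}}
            age_model = AgeModel(
                control_mean=age["control"]["mean"], control_sd=age["control"]["sd"],
                control_min=age["control"]["min"], control_max=age["control"]["max"],
                case_mean=age["case"]["mean"], case_sd=age["case"]["sd"],
                case_min=age["case"]["min"], case_max=age["case"]["max"])
        else:
            age_model = AgeModel(**age)
        covs = {k: (float(v["control"]), float(v["case"])) if isinstance(v, Mapping)
                else (float(v[0]), float(v[1]))
                for k, v in d.get("covariates", {}).items()}
        return cls(genes=genes, n_control=int(d.get("n_control", 34)),
                   n_case=int(d.get("n_case", 33)), age=age_model, covariates=covs,
                   distribution=d.get("distribution", "lognormal"),
                   seed=int(d.get("seed", 0)))

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_config(seed: int = 0) -> CohortConfig:
    """The packaged default cohort: printed six-gene group moments, n=34/33."""
    text = (resources.files("salivadx") / "data" / "cohort_defaults.yaml").read_text()
    cfg = CohortConfig.from_dict(yaml.safe_load(text))
    cfg.seed = seed
    return cfg


@dataclass
class SyntheticCohort:
    """A simulated cohort: expression matrix + metadata + provenance."""

    expression: ExpressionMatrix
    provenance: dict

    @property
    def metadata(self) -> pd.DataFrame:
        return self.expression.metadata

    def to_csv(self, path) -> None:
        self.expression.to_tidy().to_csv(path, index=False)


# -- substream derivation -----------------------------------------------------

def _stream(master_seed: int, *tags: str | int) -> np.random.Generator:
    """Deterministic child RNG keyed by string/int tags.

    String tags are hashed with CRC32 so streams depend on names, not on the
    order genes appear in the configuration.
    """
    key = [int(master_seed) & 0xFFFFFFFF]
    for t in tags:
        if isinstance(t, str):
            key.append(zlib.crc32(t.encode()) & 0xFFFFFFFF)
        else:
            key.append(int(t) & 0xFFFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(key))


def _draw_positive(rng: np.random.Generator, mean: float, sd: float, n: int,
                   distribution: str) -> np.ndarray:
    if distribution == "lognormal":
        # moment-matched log-normal: E = mean, SD = sd exactly
        sigma2 = np.log1p((sd / mean) ** 2)
        mu = np.log(mean) - sigma2 / 2.0
        return rng.lognormal(mu, np.sqrt(sigma2), size=n)
    # zero-truncated normal located at (mean, sd); the realised moments are
    # slightly shifted when mean/sd is small — documented sensitivity variant
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)


def simulate_cohort(config: CohortConfig, seed: int | None = None) -> SyntheticCohort:
    """Draw a cohort from *config*; identical (config, seed) gives identical data.

    Ages come first (their own substream per group); expression draws are then
    optionally tilted along age with the per-gene ``age_effect`` slope,
    centred at the group age mean so configured group means are preserved.
    """
    config.validate()
    master = config.seed if seed is None else seed

    frames = {}
    meta_rows = []
    sample_ids: dict[str, list[str]] = {}
    for gi, group in enumerate(_GROUPS):
        n = config.n(group)
        prefix = "C" if group == CONTROL else "T"
        sample_ids[group] = [f"{prefix}{i + 1:03d}" for i in range(n)]

        mean_a, sd_a, lo_a, hi_a = config.age.params(group)
        age_rng = _stream(master, "age", gi)
        a, b = (lo_a - mean_a) / sd_a, (hi_a - mean_a) / sd_a
        ages = stats.truncnorm.rvs(a, b, loc=mean_a, scale=sd_a, size=n,
                                   random_state=age_rng)

        cov_cols = {}
        for cov, (p_ctrl, p_case) in config.covariates.items():
            p = p_ctrl if group == CONTROL else p_case
            cov_rng = _stream(master, "covariate", cov, gi)
            cov_cols[cov] = cov_rng.random(n) < p

        meta = pd.DataFrame({"group": group, "age": ages, **cov_cols},
                            index=pd.Index(sample_ids[group], name="sample_id"))
        meta_rows.append(meta)

        cols = {}
        for gene, levels in config.genes.items():
            mean, sd = levels.moments(group)
            g_rng = _stream(master, "expr", gene, gi)
            x = _draw_positive(g_rng, mean, sd, n, config.distribution)
            if levels.age_effect != 0.0:
                x = x + levels.age_effect * (ages - mean_a)
                # additive age tilt can push small values negative; floor to
                # keep the positivity invariant (no-op at the default slope 0)
                x = np.maximum(x, 1e-6)
            cols[gene] = x
        frames[group] = pd.DataFrame(cols, index=meta.index)

    expr = pd.concat([frames[g] for g in _GROUPS])
    metadata = pd.concat(meta_rows)
    em = ExpressionMatrix(expr, metadata)
    provenance = {"config": config.to_dict(), "seed": int(master)}
    return SyntheticCohort(expression=em, provenance=provenance)


def simulate_ct_plate(cohort: SyntheticCohort, reference_ct_mean: float = 20.0,
                      replicate_sd: float = 0.0, n_replicates: int = 3,
                      calibrator_delta_ct: float = 0.0,
                      sample_shift_sd: float = 0.0,
                      reference_gene: str = "GAPDH",
                      seed: int = 0) -> pd.DataFrame:
    """Invert quantification: emit a long-format triplicate Ct table.

    For sample i with relative expression e and per-sample loading shift d_i,
    the reference gene sits at ``reference_ct_mean + d_i`` and the target at
    ``reference + calibrator_delta_ct - log2(e)``, so quantifying the plate
    with calibrator policy ``none`` (and the default calibrator dCt of 0)
    recovers e exactly when ``replicate_sd`` is zero. Replicate noise is iid
    normal on the cycle scale.

    Returns a DataFrame with columns (sample_id, gene, replicate, ct).
    """
    if replicate_sd < 0:
        raise ValueError("replicate_sd must be non-negative")
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0xFFFFFFFF,
                                                        zlib.crc32(b"ct_plate")]))
    expr = cohort.expression.expr
    shifts = (rng.normal(0.0, sample_shift_sd, size=len(expr))
              if sample_shift_sd > 0 else np.zeros(len(expr)))

    rows = []
    for (sid, shift) in zip(expr.index, shifts):
        ref_true = reference_ct_mean + shift
        targets = {reference_gene: ref_true}
        for gene in expr.columns:
            e = expr.at[sid, gene]
            targets[gene] = ref_true + calibrator_delta_ct - np.log2(e)
        for gene, true_ct in targets.items():
            noise = (rng.normal(0.0, replicate_sd, size=n_replicates)
                     if replicate_sd > 0 else np.zeros(n_replicates))
            for r in range(n_replicates):
                rows.append((sid, gene, r + 1, true_ct + noise[r]))
    return pd.DataFrame(rows, columns=["sample_id", "gene", "replicate", "ct"])
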