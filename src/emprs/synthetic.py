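"""Synthetic cohort generator.

Emulates the statistical structure of a longitudinal ageing cohort of
amyloid-high, cognitively normal older adults in which genotype modulates
the rate of cognitive decline:

* panel genotypes drawn under Hardy-Weinberg equilibrium at per-variant
  minor-allele frequencies;
* APOE simulated as phased rs429358/rs7412 haplotype pairs drawn from
  epsilon-allele frequencies (e1 never generated), exported unphased;
* Klotho KL-VS zygosity with a configurable homozygote fraction;
* per-subject cognitive trajectories that are linear in time with random
  intercepts: y_ij = b_i + slope_i * t_j + eps_ij, where carrying a risk
  group lowers slope_i (accelerated decline) and never shifts the
  intercept, so genotype associations are longitudinal only;
* demographic covariates and per-tracer amyloid-PET SUVR values.

Visits default to months 0, 18, 36, 54, 72 and 90 (7.5 years of
follow-up); visits after baseline are dropped independently at a
configurable rate (missing completely at random), the baseline visit is
always retained.

Default effect sizes place the standardized group separation of
per-subject slopes at the published panel weights: a slope decrement
``delta`` for a risk group yields an analytic Cohen's d of
``delta / (residual_sd / sqrt(Sxx))`` between carrier and non-carrier
ordinary-least-squares slopes, with Sxx the centered sum of squares of
the visit months.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .panel import RS_APOE_E2, RS_APOE_E4, RS_KLOTHO, VariantPanel, load_reference_panel
from .scoring import GenotypeRecord

__all__ = [
    "SimulationConfig",
    "SimulatedCohort",
    "simulate_genotypes",
    "simulate_trajectories",
    "simulate_trajectories_from_slopes",
    "simulate_covariates",
    "simulate_suvr",
    "simulate_cohort",
    "analytic_slope_sd",
    "slope_effect_for_d",
    "default_slope_effects",
    "klvs_fixture_cohort",
]

COMPOSITES = ("global", "verbal_episodic_memory", "aibl_pacc")

TRACER_THRESHOLDS = {"PiB": 1.4, "florbetapir": 1.05, "flutemetamol": 0.55}

# Minor-allele frequencies typical of European-ancestry reference panels;
# KL (rs9536314) is driven by kl_vs_homozygote_fraction instead.
DEFAULT_MAF = {
    "CR1": 0.20,
    "BIN1": 0.30,
    "INPP5D": 0.47,
    "KIBRA": 0.40,
    "MEF2C": 0.39,
    "HLA cluster": 0.28,
    "CD2AP": 0.27,
    "NME8": 0.46,
    "ZCWPW1": 0.29,
    "EPHA1": 0.21,
    "CSMD1": 0.48,
    "CLU": 0.38,
    "PTK2B": 0.37,
    "SPON1": 0.09,
    "BDNF": 0.19,
    "CELF1": 0.32,
    "MS4A6A": 0.40,
    "PICALM": 0.36,
    "SORL1": 0.04,
    "FERMT2": 0.09,
    "SLC24A4": 0.22,
    "ABCA7": 0.10,
    "CD33": 0.31,
    "CASS4": 0.08,
    "COMT": 0.48,
}

# Epsilon-allele frequencies chosen so that e4 carriage is ~42%, the
# enrichment seen in amyloid-high cognitively normal samples.
DEFAULT_APOE_FREQS = {"e2": 0.06, "e3": 0.70, "e4": 0.24}

_EPS_TO_CALLS = {  # epsilon haplotype -> (rs429358 allele, rs7412 allele)
    "e2": ("T", "T"),
    "e3": ("T", "C"),
    "e4": ("C", "C"),
}


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated cohort.

    ``slope_effects`` maps gene to the per-month slope decrement conferred
    by risk-group membership (minor-allele carriage; epsilon-4 carriage
    for APOE), in composite-score units per month. ``None`` selects
    defaults calibrated to the packaged panel weights (see
    :func:`default_slope_effects`).
    """

    n_subjects: int = 226
    visit_months: tuple[float, ...] = (0.0, 18.0, 36.0, 54.0, 72.0, 90.0)
    maf_per_variant: dict[str, float] | None = None
    slope_effects: dict[str, float] | None = None
    base_slope: float = -0.004
    intercept_sd: float = 0.8
    residual_sd: float = 0.4
    apoe_haplotype_freqs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_APOE_FREQS)
    )
    kl_vs_homozygote_fraction: float = 6 / 232
    dropout_rate: float = 0.12
    abeta_high_fraction: float = 1.0
    tracer_probs: dict[str, float] = field(
        default_factory=lambda: {"PiB": 0.60, "flutemetamol": 0.25, "florbetapir": 0.15}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        months = tuple(self.visit_months)
        if months[0] != 0 or any(b <= a for a, b in zip(months, months[1:])):
            raise ConfigError("visit_months must be strictly increasing from 0")
        if self.intercept_sd < 0 or self.residual_sd < 0:
            raise ConfigError("standard deviations must be >= 0")
        if not 0 <= self.dropout_rate <= 1:
            raise ConfigError("dropout_rate must be in [0, 1]")
        if not 0 <= self.kl_vs_homozygote_fraction <= 0.25:
            raise ConfigError("kl_vs_homozygote_fraction must be in [0, 0.25]")
        if not 0 <= self.abeta_high_fraction <= 1:
            raise ConfigError("abeta_high_fraction must be in [0, 1]")
        if self.maf_per_variant is not None:
            for gene, maf in self.maf_per_variant.items():
                if not 0 < maf <= 0.5:
                    raise ConfigError(f"{gene}: MAF must be in (0, 0.5], got {maf}")
        freqs = self.apoe_haplotype_freqs
        if set(freqs) - {"e2", "e3", "e4"}:
            raise ConfigError("APOE haplotype frequencies must cover e2/e3/e4 only")
        if abs(sum(freqs.values()) - 1.0) > 1e-9:
            raise ConfigError("APOE haplotype frequencies must sum to 1")

    def maf(self, gene: str) -> float:
        if self.maf_per_variant and gene in self.maf_per_variant:
            return self.maf_per_variant[gene]
        if gene not in DEFAULT_MAF:
            raise ConfigError(f"no minor-allele frequency configured for {gene!r}")
        return DEFAULT_MAF[gene]


@dataclass
class SimulatedCohort:
    genotypes: list[GenotypeRecord]
    trajectories: pd.DataFrame  # subject, visit_month, composite, value
    covariates: pd.DataFrame  # subject, age, sex, education, fsiq, gds
    suvr: pd.DataFrame  # subject, visit_month, tracer, suvr


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stage]))


def sxx(visit_months) -> float:
    """Centered sum of squares of the visit schedule."""
    t = np.asarray(visit_months, dtype=float)
    return float(np.sum((t - t.mean()) ** 2))


def analytic_slope_sd(config: SimulationConfig) -> float:
    """SD of a per-subject OLS slope under the full visit schedule."""
    return config.residual_sd / math.sqrt(sxx(config.visit_months))


def slope_effect_for_d(d: float, config: SimulationConfig) -> float:
    """Slope decrement producing an analytic carrier/non-carrier Cohen's d."""
    return d * analytic_slope_sd(config)


def default_slope_effects(
    config: SimulationConfig, panel: VariantPanel | None = None
) -> dict[str, float]:
    """Per-gene slope decrements reproducing the panel weights as analytic d."""
    panel = panel if panel is not None else load_reference_panel()
    return {e.gene: slope_effect_for_d(e.weight, config) for e in panel}


# ------------------------------------------------------------------ genotypes


def simulate_genotypes(
    panel: VariantPanel, config: SimulationConfig
) -> list[GenotypeRecord]:
    """Draw panel genotypes for ``config.n_subjects`` subjects.

    Non-APOE variants follow Hardy-Weinberg equilibrium at their MAF; APOE
    is drawn as two epsilon haplotypes and exported as unphased
    rs429358/rs7412 calls; the KL MAF is the square root of the configured
    VS/VS homozygote fraction so that the fraction is matched in
    expectation under HWE.
    """
    n = config.n_subjects
    rng = _rng(config, 0)
    subjects = [f"S{i + 1:04d}" for i in range(n)]
    calls_per_subject: list[dict[str, tuple[str, str]]] = [{} for _ in range(n)]

    for entry in panel:
        if entry.is_apoe:
            eps = list(config.apoe_haplotype_freqs)
            probs = np.array([config.apoe_haplotype_freqs[e] for e in eps])
            haps = rng.choice(eps, size=(n, 2), p=probs / probs.sum())
            for i in range(n):
                h1, h2 = haps[i]
                c1, s1 = _EPS_TO_CALLS[h1]
                c2, s2 = _EPS_TO_CALLS[h2]
                calls_per_subject[i][RS_APOE_E4] = tuple(sorted((c1, c2)))
                calls_per_subject[i][RS_APOE_E2] = tuple(sorted((s1, s2)))
            continue
        if entry.rsid == RS_KLOTHO:
            maf = math.sqrt(config.kl_vs_homozygote_fraction)
        else:
            maf = config.maf(entry.gene)
        counts = rng.binomial(2, maf, size=n) if maf > 0 else np.zeros(n, dtype=int)
        minor, major = entry.minor_allele, entry.major_allele
        for i, c in enumerate(counts):
            alleles = [minor] * int(c) + [major] * (2 - int(c))
            calls_per_subject[i][entry.rsid] = tuple(sorted(alleles))

    return [
        GenotypeRecord.from_calls(subj, calls)
        for subj, calls in zip(subjects, calls_per_subject)
    ]


def _risk_flag(record: GenotypeRecord, panel: VariantPanel, gene: str) -> bool:
    """Generative risk-group membership: minor-allele carriage under the
    dominant model (epsilon-4 carriage for APOE)."""
    entry = panel[gene]
    if entry.is_apoe:
        return bool(record.apoe_e4_count)
    call = record.calls[entry.rsid]
    return entry.minor_allele in call


def true_slopes(
    genotypes: list[GenotypeRecord],
    config: SimulationConfig,
    panel: VariantPanel | None = None,
) -> dict[str, float]:
    """Genotype-determined true slope per subject (no noise)."""
    panel = panel if panel is not None else load_reference_panel()
    effects = (
        config.slope_effects
        if config.slope_effects is not None
        else default_slope_effects(config, panel)
    )
    slopes = {}
    for rec in genotypes:
        decrement = sum(
            eff for gene, eff in effects.items() if _risk_flag(rec, panel, gene)
        )
        slopes[rec.subject] = config.base_slope - decrement
    return slopes


def simulate_trajectories(
    genotypes: list[GenotypeRecord],
    config: SimulationConfig,
    panel: VariantPanel | None = None,
    composites: tuple[str, ...] = COMPOSITES,
) -> pd.DataFrame:
    """Longitudinal composite scores for each genotyped subject.

    y_ij = b_i + slope_i * t_j + eps_ij with b_i ~ N(0, intercept_sd^2)
    and eps_ij ~ N(0, residual_sd^2), independently per composite; the
    genotype-determined slope_i is shared across composites. A missed
    visit (probability ``dropout_rate``, baseline exempt) drops all of
    that visit's composites.
    """
    if not genotypes:
        raise ValueError("empty genotype list")
    slopes = true_slopes(genotypes, config, panel)
    return simulate_trajectories_from_slopes(slopes, config, composites)


def simulate_trajectories_from_slopes(
    slopes: dict[str, float],
    config: SimulationConfig,
    composites: tuple[str, ...] = COMPOSITES,
) -> pd.DataFrame:
    """Trajectories from explicitly supplied per-subject true slopes."""
    if not slopes:
        raise ValueError("no subjects supplied")
    rng = _rng(config, 1)
    months = np.asarray(config.visit_months, dtype=float)
    rows = []
    for subject in slopes:
        present = np.ones(len(months), dtype=bool)
        if config.dropout_rate > 0 and len(months) > 1:
            present[1:] = rng.random(len(months) - 1) >= config.dropout_rate
        s = slopes[subject]
        for comp in composites:
            b = rng.normal(0.0, config.intercept_sd)
            eps = rng.normal(0.0, config.residual_sd, size=len(months))
            y = b + s * months + eps
            for j, t in enumerate(months):
                if present[j]:
                    rows.append((subject, float(t), comp, float(y[j])))
    return pd.DataFrame(
        rows, columns=["subject", "visit_month", "composite", "value"]
    )


# ----------------------------------------------------------------- covariates


def simulate_covariates(
    subjects: list[str], config: SimulationConfig
) -> pd.DataFrame:
    """Demographics matching an amyloid-high cognitively normal sample:
    age ~ N(72.2, 6.6) truncated at 60, 51% female, four education bands,
    premorbid IQ ~ N(108, 7.5), depressive symptoms ~ Poisson(1)."""
    rng = _rng(config, 2)
    n = len(subjects)
    age = rng.normal(72.2, 6.6, size=n)
    while (low := age < 60).any():
        age[low] = rng.normal(72.2, 6.6, size=int(low.sum()))
    sex = rng.binomial(1, 0.513, size=n)  # 1 = female
    education = rng.choice(4, size=n, p=[0.089, 0.375, 0.223, 0.313])
    fsiq = rng.normal(108.1, 7.5, size=n)
    gds = rng.poisson(1.0, size=n)
    return pd.DataFrame(
        {
            "subject": subjects,
            "age": np.round(age, 2),
            "sex": sex,
            "education": education,
            "fsiq": np.round(fsiq, 2),
            "gds": gds,
        }
    )


def simulate_suvr(subjects: list[str], config: SimulationConfig) -> pd.DataFrame:
    """Baseline amyloid-PET SUVR per subject, tracer drawn per configured
    mix; a configurable fraction lies at or above its tracer threshold."""
    rng = _rng(config, 3)
    n = len(subjects)
    tracers = list(config.tracer_probs)
    probs = np.array([config.tracer_probs[t] for t in tracers], dtype=float)
    assigned = rng.choice(tracers, size=n, p=probs / probs.sum())
    high = rng.random(n) < config.abeta_high_fraction
    rows = []
    for i, subj in enumerate(subjects):
        thr = TRACER_THRESHOLDS[assigned[i]]
        if high[i]:
            suvr = thr * (1.0 + abs(rng.normal(0.20, 0.12)))
        else:
            suvr = thr * (1.0 - rng.uniform(0.05, 0.35))
        rows.append((subj, 0.0, assigned[i], round(float(suvr), 4)))
    return pd.DataFrame(rows, columns=["subject", "visit_month", "tracer", "suvr"])


# --------------------------------------------------------------------- cohort


def simulate_cohort(
    config: SimulationConfig, panel: VariantPanel | None = None
) -> SimulatedCohort:
    """One complete analyzable cohort: genotypes, trajectories, covariates
    and SUVR records, all deterministic given the config seed."""
    panel = panel if panel is not None else load_reference_panel()
    genotypes = simulate_genotypes(panel, config)
    trajectories = simulate_trajectories(genotypes, config, panel)
    subjects = [g.subject for g in genotypes]
    covariates = simulate_covariates(subjects, config)
    suvr = simulate_suvr(subjects, config)
    return SimulatedCohort(genotypes, trajectories, covariates, suvr)


def klvs_fixture_cohort(
    n_subjects: int = 232, n_kl_homozygotes: int = 6, seed: int = 20180423
) -> list[GenotypeRecord]:
    """Deterministic genotype set with an exact KL-VS homozygote count.

    Synthetic stand-in for a genotyped enrolment sample: HWE draws with
    the KL calls of the first ``n_kl_homozygotes`` subjects (in subject
    order) overwritten to VS/VS and all remaining KL calls redrawn from
    the non-homozygous genotypes, so the exclusion step retains exactly
    ``n_subjects - n_kl_homozygotes`` records.
    """
    if n_kl_homozygotes > n_subjects:
        raise ValueError("more homozygotes requested than subjects")
    config = SimulationConfig(n_subjects=n_subjects, seed=seed)
    panel = load_reference_panel()
    records = simulate_genotypes(panel, config)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    maf = math.sqrt(config.kl_vs_homozygote_fraction)
    p_het = 2 * maf * (1 - maf) / (1 - maf**2)  # het | not homozygous VS
    for i, rec in enumerate(records):
        if i < n_kl_homozygotes:
            rec.calls[RS_KLOTHO] = ("VS", "VS")
        else:
            het = rng.random() < p_het
            rec.calls[RS_KLOTHO] = ("VS", "WT") if het else ("WT", "WT")
        rec.annotate()
    return records
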