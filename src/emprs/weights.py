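"""Effect-size weight derivation from longitudinal slopes.

The per-variant weight is a Cohen's d between the distributions of
per-subject verbal-episodic-memory slopes in the two dominant-model
genotype groups of a reference sample: minor-allele carriers versus
non-carriers (epsilon-4 carriers versus non-carriers for APOE). The
group whose mean slope is lower — faster decline — is assigned as the
risk genotype, and d is reported non-negative, so direction of effect
lives entirely in the risk-genotype label.

Per-subject slopes can be extracted two ways:

* ``"ols"`` — ordinary least squares of the composite on visit months,
  independently per subject;
* ``"blup"`` — fixed time effect plus the subject's predicted random
  slope from a linear mixed model with correlated random intercepts and
  slopes (best linear unbiased prediction; shrinks noisy individual
  slopes toward the population mean).

With balanced visit schedules the two orderings coincide up to a uniform
shrinkage, so group effect sizes are essentially identical; with
irregular follow-up BLUP down-weights subjects observed briefly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .panel import VariantPanel, VariantPanelEntry
from .scoring import GenotypeRecord

__all__ = [
    "SlopeResult",
    "EffectSizeResult",
    "split_cohort",
    "subject_slopes",
    "cohens_d",
    "derive_weights",
    "results_to_panel",
]


@dataclass
class SlopeResult:
    """Per-subject slope estimates plus exclusion bookkeeping."""

    slopes: pd.DataFrame  # subject, slope, n_visits
    excluded_subjects: list[str]
    method: str


@dataclass
class EffectSizeResult:
    """Two-group slope comparison for one panel variant."""

    gene: str
    carrier_mean: float
    carrier_sd: float
    n_carriers: int
    noncarrier_mean: float
    noncarrier_sd: float
    n_noncarriers: int
    d: float
    ci_low: float
    ci_high: float
    risk_genotype: str
    flags: tuple[str, ...] = ()


def split_cohort(
    subject_ids: list[str], reference_fraction: float, seed: int
) -> tuple[list[str], list[str]]:
    """Random disjoint reference/test partition, deterministic given seed.

    Sizes are round(fraction * n) and the remainder; e.g. 226 subjects at
    fraction 151/226 split 151/75.
    """
    subjects = list(subject_ids)
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects to split")
    if not 0 < reference_fraction < 1:
        raise ValueError(f"reference_fraction must be in (0, 1), got {reference_fraction}")
    n_ref = int(round(reference_fraction * len(subjects)))
    n_ref = min(max(n_ref, 1), len(subjects) - 1)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    ref = sorted(subjects[i] for i in order[:n_ref])
    test = sorted(subjects[i] for i in order[n_ref:])
    return ref, test


def subject_slopes(
    trajectories: pd.DataFrame,
    method: str = "blup",
    composite: str | None = None,
) -> SlopeResult:
    """Per-subject slope of the composite on visit months.

    ``trajectories`` is long-format (subject, visit_month, value[,
    composite]); rows with missing values are dropped, and subjects with
    fewer than two remaining visits are excluded and reported.
    """
    if method not in ("ols", "blup"):
        raise ValueError(f"unknown slope method {method!r}")
    df = trajectories
    if composite is not None:
        df = df[df["composite"] == composite]
    df = df.dropna(subset=["value"])
    counts = df.groupby("subject")["visit_month"].nunique()
    keep = counts[counts >= 2].index
    excluded = sorted(set(df["subject"]) - set(keep))
    df = df[df["subject"].isin(keep)]
    if df.empty:
        raise ValueError("all subjects excluded: no subject has >= 2 visits")

    ols = _ols_slopes(df)
    if method == "ols":
        slopes = ols
    else:
        slopes = _blup_slopes(df, ols)
    out = slopes.merge(
        counts.rename("n_visits").reset_index(), on="subject", validate="1:1"
    )
    return SlopeResult(slopes=out, excluded_subjects=excluded, method=method)


def _ols_slopes(df: pd.DataFrame) -> pd.DataFrame:
    def slope(g: pd.DataFrame) -> float:
        t = g["visit_month"].to_numpy(float)
        y = g["value"].to_numpy(float)
        tc = t - t.mean()
        return float(np.dot(tc, y - y.mean()) / np.dot(tc, tc))

    s = df.groupby("subject")[["visit_month", "value"]].apply(slope)
    return s.rename("slope").reset_index()

def _blup_slopes(df: pd.DataFrame, ols: pd.DataFrame) -> pd.DataFrame:
    # Degenerate noise-free data: every within-subject residual vanishes,
    # shrinkage is zero and the BLUPs are the per-subject OLS lines.
    resid_max = (
        df.groupby("subject")[["visit_month", "value"]]
        .apply(_max_abs_ols_residual)
        .max()
    )
    if resid_max < 1e-10:
        return ols.copy()
    endog = df["value"].to_numpy(float)
    exog = sm.add_constant(df["visit_month"].to_numpy(float))
    groups = df["subject"].to_numpy()
    model = sm.MixedLM(endog, exog, groups=groups, exog_re=exog)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=True, method=["lbfgs", "powell"])
    fixed_slope = float(fit.fe_params[1])
    re = fit.random_effects
    rows = [(subj, fixed_slope + float(re[subj].iloc[1])) for subj in re]
    return pd.DataFrame(rows, columns=["subject", "slope"])


def _max_abs_ols_residual(g: pd.DataFrame) -> float:
    t = g["visit_month"].to_numpy(float)
    y = g["value"].to_numpy(float)
    tc = t - t.mean()
    b = np.dot(tc, y - y.mean()) / np.dot(tc, tc)
    resid = y - (y.mean() + b * tc)
    return float(np.max(np.abs(resid)))


def cohens_d(group_a, group_b) -> tuple[float, float, float]:
    """Standardized mean difference (a minus b) with a 95% CI.

    d = (mean_a - mean_b) / s_pooled, s_pooled the pooled SD; the CI uses
    the large-sample SE sqrt((n_a+n_b)/(n_a*n_b) + d^2/(2(n_a+n_b-2)))
    and a normal 1.96 multiplier.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    pooled = math.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    if pooled == 0:
        raise ValueError("pooled standard deviation is zero")
    d = (a.mean() - b.mean()) / pooled
    se = math.sqrt((na + nb) / (na * nb) + d**2 / (2 * (na + nb - 2)))
    return d, d - 1.96 * se, d + 1.96 * se


def derive_weights(
    slopes: pd.DataFrame,
    genotypes: list[GenotypeRecord],
    panel: VariantPanel,
) -> tuple[list[EffectSizeResult], list[str]]:
    """Per-variant effect sizes of slope decline between dominant-model
    groups, oriented so d >= 0 with the faster-declining group assigned
    as the risk genotype.

    ``slopes`` is the frame from :func:`subject_slopes` (subject, slope).
    Variants with an empty or single-subject group are skipped and
    returned in the second element.

    Returns (results, skipped_genes).
    """
    slope_by_subject = dict(zip(slopes["subject"], slopes["slope"]))
    records = [g for g in genotypes if g.subject in slope_by_subject]
    if not records:
        raise ValueError("no overlap between slope subjects and genotypes")
    results: list[EffectSizeResult] = []
    skipped: list[str] = []
    for entry in panel:
        carrier, noncarrier = [], []
        for rec in records:
            flag = _carrier_flag(rec, entry)
            if flag is None:
                continue
            (carrier if flag else noncarrier).append(slope_by_subject[rec.subject])
        if len(carrier) < 2 or len(noncarrier) < 2:
            skipped.append(entry.gene)
            continue
        try:
            d_raw, _, _ = cohens_d(carrier, noncarrier)
        except ValueError:
            skipped.append(entry.gene)
            continue
        flags: list[str] = []
        # Risk group = faster-declining (lower mean slope). Carriers decline
        # faster when d_raw < 0 (their mean slope is smaller). Ties go to the
        # carrier group with weight 0.
        if d_raw < 0:
            risk_is_carrier = True
            d, lo, hi = cohens_d(noncarrier, carrier)
        elif d_raw > 0:
            risk_is_carrier = False
            d, lo, hi = cohens_d(carrier, noncarrier)
        else:
            risk_is_carrier = True
            d, lo, hi = 0.0, *cohens_d(noncarrier, carrier)[1:]
            flags.append("tied_groups")
        results.append(
            EffectSizeResult(
                gene=entry.gene,
                carrier_mean=float(np.mean(carrier)),
                carrier_sd=float(np.std(carrier, ddof=1)),
                n_carriers=len(carrier),
                noncarrier_mean=float(np.mean(noncarrier)),
                noncarrier_sd=float(np.std(noncarrier, ddof=1)),
                n_noncarriers=len(noncarrier),
                d=d,
                ci_low=lo,
                ci_high=hi,
                risk_genotype=_risk_label(entry, risk_is_carrier),
                flags=tuple(flags),
            )
        )
    return results, skipped


def _carrier_flag(rec: GenotypeRecord, entry: VariantPanelEntry) -> bool | None:
    if entry.is_apoe:
        if rec.apoe_e4_count is None:
            return None
        return rec.apoe_e4_count >= 1
    call = rec.calls.get(entry.rsid)
    if call is None:
        return None
    return entry.minor_allele in call


def _risk_label(entry: VariantPanelEntry, risk_is_carrier: bool) -> str:
    if entry.is_apoe:
        return "e4+" if risk_is_carrier else "e4-"
    if risk_is_carrier:
        return f"{entry.minor_allele}+"
    return f"{entry.major_allele}/{entry.major_allele}"


def results_to_panel(
    results: list[EffectSizeResult], template: VariantPanel
) -> VariantPanel:
    """Assemble derived effect sizes into a scoring-ready panel, keeping
    variant metadata from the template panel."""
    from dataclasses import replace

    entries = []
    for res in results:
        base = template[res.gene]
        entries.append(
            replace(
                base,
                risk_genotype=res.risk_genotype,
                weight=res.d,
                ci_low=res.ci_low,
                ci_high=res.ci_high,
                source="derived",
                flags=res.flags,
            )
        )
    return VariantPanel(entries)
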