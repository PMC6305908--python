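"""Cognitive composite scores and amyloid-status classification.

Three composites are supported, each an equal-weight mean of oriented
z-scores of its component neuropsychological tests:

* ``global`` — CDR sum of boxes (-), MMSE (+), Logical Memory II (+),
  CVLT-II recognition false positives (-), Clock drawing (+);
* ``verbal_episodic_memory`` — CDR sum of boxes (-), Logical Memory II
  (+), CVLT-II recognition false positives (-);
* ``aibl_pacc`` — a preclinical-Alzheimer's composite of CVLT-II long
  delay free recall (+), Logical Memory II (+), MMSE (+) and WAIS-III
  Digit Symbol-Coding (+).

Orientation -1 marks tests where higher raw scores are worse.
Z-scores are taken against norms (mean/SD per test) computed on the
baseline visits of a designated reference sample. Composites are then
residualized on demographic covariates — age, sex, education, premorbid
IQ and depressive symptoms — with the adjustment model fitted on baseline
data only and applied unchanged to every visit, so within-subject change
is not absorbed by the correction. The PACC composite omits age from its
covariate set (age is instead carried as a model covariate downstream).

Amyloid status: a subject is Abeta-high if any PET SUVR record meets or
exceeds its tracer-specific threshold (PiB >= 1.4, florbetapir >= 1.05,
flutemetamol >= 0.55, inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CompositeDefinition",
    "COMPOSITE_DEFINITIONS",
    "TRACER_THRESHOLDS",
    "baseline_norms",
    "compute_composite",
    "residualize",
    "classify_abeta",
]

TRACER_THRESHOLDS = {"PiB": 1.4, "florbetapir": 1.05, "flutemetamol": 0.55}

FULL_COVARIATES = ("age", "sex", "education", "fsiq", "gds")


@dataclass(frozen=True)
class CompositeDefinition:
    """A named composite: (test, orientation) components and the covariate
    set used for residualization."""

    name: str
    components: tuple[tuple[str, int], ...]
    covariate_set: tuple[str, ...] = FULL_COVARIATES

    def __post_init__(self) -> None:
        for test, orient in self.components:
            if orient not in (+1, -1):
                raise ValueError(f"{self.name}/{test}: orientation must be +1 or -1")

    @property
    def tests(self) -> tuple[str, ...]:
        return tuple(t for t, _ in self.components)


COMPOSITE_DEFINITIONS = {
    "global": CompositeDefinition(
        "global",
        (
            ("CDR_SB", -1),
            ("MMSE", +1),
            ("LMII", +1),
            ("CVLT_II_FP", -1),
            ("Clock", +1),
        ),
    ),
    "verbal_episodic_memory": CompositeDefinition(
        "verbal_episodic_memory",
        (("CDR_SB", -1), ("LMII", +1), ("CVLT_II_FP", -1)),
    ),
    "aibl_pacc": CompositeDefinition(
        "aibl_pacc",
        (("CVLT_II_LDFR", +1), ("LMII", +1), ("MMSE", +1), ("WAIS_III_DSC", +1)),
        covariate_set=("sex", "education", "fsiq", "gds"),  # no age correction
    ),
}


def baseline_norms(
    raw_scores: pd.DataFrame, reference_subjects: list[str] | None = None
) -> pd.DataFrame:
    """Per-test mean/SD from baseline (month 0) visits of the reference
    sample; returns a frame indexed by test with columns mean, sd."""
    df = raw_scores[raw_scores["visit_month"] == 0]
    if reference_subjects is not None:
        df = df[df["subject"].isin(reference_subjects)]
    if df.empty:
        raise ValueError("no baseline records to compute norms from")
    norms = df.groupby("test")["value"].agg(mean="mean", sd="std")
    return norms


def compute_composite(
    raw_scores: pd.DataFrame,
    definition: CompositeDefinition,
    norms: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Equal-weight oriented z-composite per subject-visit.

    ``raw_scores`` is long-format (subject, visit_month, test, value);
    visits missing any component test yield no composite row. When
    ``covariates`` is given, the composite is residualized on the
    definition's covariate set (see :func:`residualize`).

    Returns (subject, visit_month, composite, value).
    """
    for test in definition.tests:
        if test not in norms.index:
            raise KeyError(f"no norms for component test {test!r}")
        sd = float(norms.loc[test, "sd"])
        if not np.isfinite(sd) or sd <= 0:
            raise ValueError(f"norm SD for {test!r} must be positive, got {sd}")
    known = set(norms.index)
    unknown = set(raw_scores["test"]) - known
    if unknown & set(definition.tests):
        raise KeyError(f"unknown tests in input: {sorted(unknown)}")

    wide = raw_scores.pivot_table(
        index=["subject", "visit_month"], columns="test", values="value"
    )
    missing_tests = [t for t in definition.tests if t not in wide.columns]
    if missing_tests:
        raise KeyError(f"component tests absent from input: {missing_tests}")
    z = pd.DataFrame(index=wide.index)
    for test, orient in definition.components:
        mu = float(norms.loc[test, "mean"])
        sd = float(norms.loc[test, "sd"])
        z[test] = orient * (wide[test] - mu) / sd
    composite = z[list(definition.tests)].mean(axis=1, skipna=False)
    out = composite.dropna().rename("value").reset_index()
    out.insert(2, "composite", definition.name)
    if covariates is not None:
        out = residualize(out, covariates, definition.covariate_set)
    return out


def residualize(
    composite: pd.DataFrame,
    covariates: pd.DataFrame,
    covariate_set: tuple[str, ...],
) -> pd.DataFrame:
    """Linear covariate adjustment fitted on baseline rows, applied to all.

    An OLS model of the baseline composite on the covariates supplies the
    coefficients; the covariate-predicted component (minus the baseline
    intercept) is subtracted at every visit. Because every visit of a
    subject receives the same correction, within-subject slopes are
    unchanged.
    """
    if not covariate_set:
        return composite
    missing = [c for c in covariate_set if c not in covariates.columns]
    if missing:
        raise KeyError(f"covariate columns absent: {missing}")
    merged = composite.merge(covariates, on="subject", how="left", validate="m:1")
    if merged[list(covariate_set)].isna().any().any():
        bad = merged.loc[
            merged[list(covariate_set)].isna().any(axis=1), "subject"
        ].unique()
        raise ValueError(f"missing covariates for subjects: {sorted(bad)[:5]}")
    base = merged[merged["visit_month"] == 0]
    if len(base) <= len(covariate_set) + 1:
        raise ValueError("too few baseline records to fit covariate adjustment")
    X = np.column_stack(
        [np.ones(len(base))] + [base[c].to_numpy(float) for c in covariate_set]
    )
    beta, *_ = np.linalg.lstsq(X, base["value"].to_numpy(float), rcond=None)
    Xall = np.column_stack(
        [np.ones(len(merged))] + [merged[c].to_numpy(float) for c in covariate_set]
    )
    adjusted = merged["value"].to_numpy(float) - Xall[:, 1:] @ beta[1:]
    out = composite.copy()
    out["value"] = adjusted
    return out


def classify_abeta(suvr_records: pd.DataFrame) -> pd.Series:
    """Abeta-high status per subject: True iff any SUVR record meets or
    exceeds its tracer's threshold (any-time-point rule, inclusive).

    ``suvr_records`` needs columns subject, tracer, suvr.
    """
    if suvr_records.empty:
        raise ValueError("no SUVR records supplied")
    unknown = set(suvr_records["tracer"]) - set(TRACER_THRESHOLDS)
    if unknown:
        raise KeyError(f"unknown tracers: {sorted(unknown)}")
    if (suvr_records["suvr"] <= 0).any():
        raise ValueError("SUVR values must be positive")
    thr = suvr_records["tracer"].map(TRACER_THRESHOLDS)
    high = suvr_records["suvr"] >= thr
    return high.groupby(suvr_records["subject"]).any()
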