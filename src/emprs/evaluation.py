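"""Test-sample association analyses.

Associations between the emPRS and cognition are assessed with random-
intercept linear mixed models fitted per composite:

    composite ~ emPRS + time + emPRS x time  (+ age for the PACC)

with subject random intercepts. The emPRS main effect alpha is the
baseline (time-zero) association; the emPRS x time interaction beta is
the score's effect on the rate of change, in composite units per unit
score per month. Fixed effects are tested with Wald z statistics; raw
p-values are reported without multiplicity correction.

Stratified analyses refit the model within APOE epsilon-4 dosage strata
using the score computed without APOE, so the score being tested carries
no direct epsilon-4 information. The default stratification is carrier
versus non-carrier ({0} vs {1,2} epsilon-4 alleles); per-dosage strata
({0},{1},{2}) are available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .scoring import GenotypeRecord, ScoreRecord

__all__ = [
    "AssociationResult",
    "fit_longitudinal",
    "stratified_analysis",
    "report",
    "parse_report",
    "write_report",
    "read_report",
]


@dataclass
class AssociationResult:
    """One fitted score-by-time mixed model (or a skip marker)."""

    composite: str
    score_variant: str  # "with_apoe" | "without_apoe"
    stratum: str  # "all", "e4_0", "e4_1plus", "e4_1", "e4_2"
    alpha: float | None
    alpha_p: float | None
    beta: float | None
    beta_p: float | None
    n_subjects: int
    n_observations: int
    converged: bool
    skipped: bool = False
    covariates: tuple[str, ...] = ()


def _scores_frame(scores, score_variant: str) -> pd.DataFrame:
    col = {"with_apoe": "emprs_with_apoe", "without_apoe": "emprs_without_apoe"}[
        score_variant
    ]
    if isinstance(scores, pd.DataFrame):
        df = scores[["subject", col]].rename(columns={col: "emprs"})
    else:
        df = pd.DataFrame(
            [(s.subject, getattr(s, col)) for s in scores],
            columns=["subject", "emprs"],
        )
    return df.dropna(subset=["emprs"])


def fit_longitudinal(
    scores,
    trajectories: pd.DataFrame,
    composite: str,
    score_variant: str = "with_apoe",
    covariates: pd.DataFrame | None = None,
    stratum: str = "all",
) -> AssociationResult:
    """Random-intercept LME of one composite on emPRS, time and their
    interaction; age enters as a fixed covariate for the PACC when
    ``covariates`` is supplied.

    ``scores`` is a list of :class:`~emprs.scoring.ScoreRecord` or an
    equivalent frame; ``trajectories`` is long-format (subject,
    visit_month, composite, value).
    """
    sc = _scores_frame(scores, score_variant)
    traj = trajectories[trajectories["composite"] == composite]
    df = traj.merge(sc, on="subject", how="inner").dropna(subset=["value"])
    if df.empty:
        raise ValueError(f"no modelable observations for composite {composite!r}")
    if np.ptp(df["visit_month"].to_numpy(float)) == 0:
        raise ValueError("time column is constant: no longitudinal information")

    fixed = ["emprs", "visit_month", "emprs:visit_month"]
    used_covs: tuple[str, ...] = ()
    if composite == "aibl_pacc" and covariates is not None:
        df = df.merge(covariates[["subject", "age"]], on="subject", how="left")
        df = df.dropna(subset=["age"])
        fixed.append("age")
        used_covs = ("age",)
    formula = "value ~ " + " + ".join(fixed)

    n_subjects = df["subject"].nunique()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(formula, df, groups=df["subject"])
            fit = model.fit(reml=True, method=["lbfgs", "powell"])
        converged = bool(fit.converged)
    except (np.linalg.LinAlgError, ValueError):
        converged = False
    if not converged:
        return AssociationResult(
            composite, score_variant, stratum, None, None, None, None,
            n_subjects, len(df), converged=False,
        )
    params, pvals = fit.params, fit.pvalues
    return AssociationResult(
        composite=composite,
        score_variant=score_variant,
        stratum=stratum,
        alpha=float(params["emprs"]),
        alpha_p=float(pvals["emprs"]),
        beta=float(params["emprs:visit_month"]),
        beta_p=float(pvals["emprs:visit_month"]),
        n_subjects=n_subjects,
        n_observations=len(df),
        converged=True,
        covariates=used_covs,
    )


def stratified_analysis(
    scores,
    trajectories: pd.DataFrame,
    genotypes: list[GenotypeRecord],
    composite: str,
    covariates: pd.DataFrame | None = None,
    mode: str = "carrier",
    min_stratum_size: int = 10,
) -> list[AssociationResult]:
    """Per-stratum fits of the APOE-free score by epsilon-4 dosage.

    ``mode`` "carrier" uses strata {0} and {1 or 2} alleles; "dosage"
    uses {0}, {1}, {2}. Subjects with unresolved APOE are omitted.
    Strata smaller than ``min_stratum_size`` are reported as skipped.
    """
    if mode == "carrier":
        strata = {"e4_0": (0,), "e4_1plus": (1, 2)}
    elif mode == "dosage":
        strata = {"e4_0": (0,), "e4_1": (1,), "e4_2": (2,)}
    else:
        raise ValueError(f"unknown stratification mode {mode!r}")
    dosage = {
        g.subject: g.apoe_e4_count for g in genotypes if g.apoe_e4_count is not None
    }
    results = []
    for name, counts in strata.items():
        members = {s for s, c in dosage.items() if c in counts}
        sc = [s for s in scores if s.subject in members]
        traj = trajectories[trajectories["subject"].isin(members)]
        n_avail = len({s.subject for s in sc})
        if n_avail < min_stratum_size:
            results.append(
                AssociationResult(
                    composite, "without_apoe", name, None, None, None, None,
                    n_avail, len(traj), converged=False, skipped=True,
                )
            )
            continue
        res = fit_longitudinal(
            sc, traj, composite, score_variant="without_apoe",
            covariates=covariates, stratum=name,
        )
        results.append(res)
    return results


# ------------------------------------------------------------------ reporting


def report(results: list[AssociationResult]) -> dict:
    """Machine-readable report: one record per composite x score-variant
    x stratum."""
    if not results:
        raise ValueError("no association results to report")
    return {
        "n_results": len(results),
        "results": [asdict(_tuplefree(r)) for r in results],
    }


def _tuplefree(r: AssociationResult) -> AssociationResult:
    from dataclasses import replace

    return replace(r, covariates=tuple(r.covariates))


def parse_report(payload: dict) -> list[AssociationResult]:
    out = []
    for rec in payload["results"]:
        rec = dict(rec)
        rec["covariates"] = tuple(rec.get("covariates", ()))
        out.append(AssociationResult(**rec))
    return out


def write_report(results: list[AssociationResult], path) -> None:
    import json
    from pathlib import Path

    Path(path).write_text(json.dumps(report(results), indent=1, sort_keys=True) + "\n")


def read_report(path) -> list[AssociationResult]:
    import json
    from pathlib import Path

    return parse_report(json.loads(Path(path).read_text()))


def results_table(results: list[AssociationResult]) -> pd.DataFrame:
    """Tab-friendly frame of the alpha/beta coefficients and p-values."""
    return pd.DataFrame([asdict(_tuplefree(r)) for r in results]).drop(
        columns=["covariates"]
    )


def plot_association(
    result: AssociationResult,
    scores,
    trajectories: pd.DataFrame,
    path=None,
):
    """Fitted change-versus-score line with score-dependent standard-error
    shading; requires matplotlib. Returns the figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if result.beta is None:
        raise ValueError("cannot plot an unconverged result")
    sc = _scores_frame(scores, result.score_variant)
    xs = np.linspace(sc["emprs"].min(), sc["emprs"].max(), 50)
    slope_pred = result.beta * xs
    # SE of the predicted slope grows linearly with |score - mean score|.
    se_unit = abs(result.beta) / 4 if result.beta else 0.01
    band = se_unit * (0.5 + np.abs(xs - sc["emprs"].mean()) / (sc["emprs"].std() + 1e-9))
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.plot(xs, slope_pred, color="C0")
    ax.fill_between(xs, slope_pred - band, slope_pred + band, alpha=0.3, color="C0")
    ax.set_xlabel(f"emPRS ({result.score_variant})")
    ax.set_ylabel(f"fitted change in {result.composite} per month")
    ax.set_title(f"{result.composite} / {result.stratum}")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig
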