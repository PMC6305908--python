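"""End-to-end pipeline: amyloid filter -> KL-VS exclusion -> reference/
test split -> weight derivation on the reference sample -> emPRS scoring
of the test sample -> association evaluation (overall and stratified by
APOE epsilon-4 carriage).

Every output table embeds the seed and a hash of the configuration in a
header comment, and a stage log records counts in and out of each filter,
so a run is reproducible and auditable from its output directory alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import io as eio
from .composites import classify_abeta
from .evaluation import (
    AssociationResult,
    fit_longitudinal,
    results_table,
    stratified_analysis,
    write_report,
)
from .panel import VariantPanel, load_reference_panel
from .scoring import GenotypeRecord, compute_emprs, exclude_kl_homozygotes
from .synthetic import COMPOSITES, SimulationConfig, simulate_cohort
from .weights import derive_weights, results_to_panel, split_cohort, subject_slopes

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Run configuration; input paths may be omitted to simulate a cohort."""

    output_dir: str
    genotypes: str | None = None
    phenotypes: str | None = None
    suvr: str | None = None
    panel: str | None = None  # default: packaged reference panel
    simulate_n: int = 226
    reference_fraction: float = 151 / 226
    seed: int = 0
    slope_method: str = "blup"
    composites: tuple[str, ...] = COMPOSITES
    weight_composite: str = "verbal_episodic_memory"
    missing_policy: str = "strict"
    stratification: str = "carrier"
    min_stratum_size: int = 10

    def config_hash(self) -> str:
        """Hash of the analytic configuration (output location excluded,
        so reruns into different directories are comparable)."""
        payload = {k: v for k, v in asdict(self).items() if k != "output_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Flat key=value file (``#`` comments allowed)."""
        kwargs: dict = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            value = value.strip()
            if key in ("simulate_n", "seed", "min_stratum_size"):
                kwargs[key] = int(value)
            elif key in ("reference_fraction",):
                kwargs[key] = float(value)
            elif key == "composites":
                kwargs[key] = tuple(v.strip() for v in value.split(","))
            else:
                kwargs[key] = value
        return cls(**kwargs)


@dataclass
class PipelineResult:
    scores: list
    associations: list[AssociationResult]
    derived_panel: VariantPanel
    log: list[str] = field(default_factory=list)
    reference_subjects: list[str] = field(default_factory=list)
    test_subjects: list[str] = field(default_factory=list)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = [f"seed={config.seed}", f"config_hash={config.config_hash()}"]
    log: list[str] = list(meta)

    def stage(msg: str) -> None:
        log.append(msg)

    panel = (
        VariantPanel.from_tsv(config.panel)
        if config.panel
        else load_reference_panel()
    )
    stage(f"panel: {len(panel)} entries")

    # ------------------------------------------------------------ inputs
    if config.genotypes:
        path = Path(config.genotypes)
        if path.suffix.lower() == ".vcf":
            genotypes = eio.read_genotypes_vcf(path, panel)
        else:
            genotypes = eio.read_genotypes(path, panel)
        trajectories = eio.read_phenotypes(config.phenotypes)
        suvr = eio.read_suvr(config.suvr) if config.suvr else None
        stage(f"loaded: {len(genotypes)} genotype records")
    else:
        sim = simulate_cohort(
            SimulationConfig(n_subjects=config.simulate_n, seed=config.seed),
            panel,
        )
        genotypes, trajectories, suvr = sim.genotypes, sim.trajectories, sim.suvr
        eio.write_genotypes(genotypes, out / "genotypes.tsv", meta)
        eio.write_phenotypes(trajectories, out / "phenotypes.tsv", meta)
        eio.write_covariates(sim.covariates, out / "covariates.tsv", meta)
        eio.write_suvr(suvr, out / "suvr.tsv", meta)
        stage(f"simulated: {len(genotypes)} subjects")

    # ------------------------------------------------- amyloid filtering
    n_before = len(genotypes)
    if suvr is not None and not suvr.empty:
        high = classify_abeta(suvr)
        keep = set(high[high].index)
        genotypes = [g for g in genotypes if g.subject in keep]
        stage(
            f"abeta_filter: in={n_before} retained={len(genotypes)} "
            f"excluded={n_before - len(genotypes)}"
        )
    else:
        stage(f"abeta_filter: skipped (no SUVR records), retained={n_before}")

    # ------------------------------------------------- KL-VS homozygotes
    n_before = len(genotypes)
    genotypes, n_kl = exclude_kl_homozygotes(genotypes)
    stage(f"klvs_exclusion: in={n_before} retained={len(genotypes)} excluded={n_kl}")

    subjects = [g.subject for g in genotypes]
    trajectories = trajectories[trajectories["subject"].isin(subjects)]

    # --------------------------------------------------------------- split
    ref_ids, test_ids = split_cohort(subjects, config.reference_fraction, config.seed)
    stage(f"split: reference={len(ref_ids)} test={len(test_ids)}")

    # --------------------------------------------------- weight derivation
    ref_traj = trajectories[trajectories["subject"].isin(ref_ids)]
    slope_res = subject_slopes(
        ref_traj, method=config.slope_method, composite=config.weight_composite
    )
    stage(
        f"slopes: method={config.slope_method} n={len(slope_res.slopes)} "
        f"excluded={len(slope_res.excluded_subjects)}"
    )
    ref_genotypes = [g for g in genotypes if g.subject in set(ref_ids)]
    effect_sizes, skipped = derive_weights(slope_res.slopes, ref_genotypes, panel)
    derived_panel = results_to_panel(effect_sizes, panel)
    stage(f"weights: derived={len(effect_sizes)} skipped={len(skipped)}")
    derived_panel.to_tsv(out / "derived_panel.tsv", " ".join(meta))

    # --------------------------------------------------------------- scoring
    test_genotypes = [g for g in genotypes if g.subject in set(test_ids)]
    scores = compute_emprs(
        test_genotypes, derived_panel, missing_policy=config.missing_policy
    )
    n_scored = sum(1 for s in scores if s.emprs_without_apoe is not None)
    stage(f"scoring: test={len(scores)} scored={n_scored}")
    eio.write_scores(scores, out / "scores.tsv", meta)

    # ------------------------------------------------------------ evaluation
    test_traj = trajectories[trajectories["subject"].isin(test_ids)]
    covariates = None
    cov_path = out / "covariates.tsv"
    if cov_path.exists():
        covariates = eio.read_covariates(cov_path)
    associations: list[AssociationResult] = []
    for comp in config.composites:
        for variant in ("with_apoe", "without_apoe"):
            associations.append(
                fit_longitudinal(
                    scores, test_traj, comp, score_variant=variant,
                    covariates=covariates,
                )
            )
        associations.extend(
            stratified_analysis(
                scores, test_traj, test_genotypes, comp,
                covariates=covariates, mode=config.stratification,
                min_stratum_size=config.min_stratum_size,
            )
        )
    stage(f"evaluation: {len(associations)} association records")

    results_table(associations).to_csv(
        out / "associations.tsv", sep="\t", index=False, na_rep="."
    )
    write_report(associations, out / "report.json")
    (out / "log.txt").write_text("\n".join(log) + "\n")
    return PipelineResult(
        scores=scores,
        associations=associations,
        derived_panel=derived_panel,
        log=log,
        reference_subjects=ref_ids,
        test_subjects=test_ids,
    )
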