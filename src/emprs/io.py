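"""Tabular file formats.

All tables are tab-separated with a header row, UTF-8, ``.`` for missing
values; lines starting with ``#`` are metadata comments (the pipeline
embeds its seed and config hash there). Genotypes are long-format
(subject, rsid, allele1, allele2); alleles are normalized to the panel's
canonical spelling case-insensitively. A minimal VCF reader (restricted
to panel rsIDs, GT field, unphased accepted) is provided for genotype
ingestion.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .panel import VariantPanel
from .scoring import GenotypeRecord, ScoreRecord

__all__ = [
    "read_genotypes",
    "read_genotypes_vcf",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "read_covariates",
    "write_covariates",
    "read_suvr",
    "write_suvr",
    "write_scores",
    "read_scores",
]

logger = logging.getLogger("emprs")

MISSING = "."

# Nucleotide spellings of the protein-level allele labels used by the
# panel (BDNF Val66Met, COMT Val158Met, Klotho KL-VS F352V).
NUCLEOTIDE_SYNONYMS = {
    "rs6265": {"G": "Val", "A": "Met"},
    "rs4680": {"G": "Val", "A": "Met"},
    "rs9536314": {"T": "WT", "G": "VS"},
}


def _canonical_alleles(panel: VariantPanel) -> dict[str, dict[str, str]]:
    """rsID -> uppercase allele spelling -> canonical spelling."""
    table: dict[str, dict[str, str]] = {}
    for entry in panel:
        if entry.is_apoe:
            for rs in entry.rsids:
                table[rs] = {"C": "C", "T": "T"}
            continue
        table[entry.rsid] = {
            entry.minor_allele.upper(): entry.minor_allele,
            entry.major_allele.upper(): entry.major_allele,
        }
        for nt, label in NUCLEOTIDE_SYNONYMS.get(entry.rsid, {}).items():
            if label in (entry.minor_allele, entry.major_allele):
                table[entry.rsid][nt] = label
    return table


def _read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=[MISSING], dtype=str)


def _write_table(
    df: pd.DataFrame, path: str | Path, comments: list[str] | None = None
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for c in comments or []:
            fh.write(f"# {c}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep=MISSING)


def read_genotypes(path: str | Path, panel: VariantPanel) -> list[GenotypeRecord]:
    """Long-format genotype table -> annotated records.

    Unknown rsIDs are ignored (count logged); duplicate subject/rsID rows
    with conflicting calls raise; missing calls (``.``) leave the rsID
    absent from the record.
    """
    df = _read_table(path)
    required = ["subject", "rsid", "allele1", "allele2"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing genotype columns {missing_cols}")
    canon = _canonical_alleles(panel)
    calls: dict[str, dict[str, tuple[str, str]]] = {}
    order: list[str] = []
    n_unknown = 0
    for row in df.itertuples(index=False):
        subject, rsid = str(row.subject), str(row.rsid)
        if rsid not in canon:
            n_unknown += 1
            continue
        if pd.isna(row.allele1) or pd.isna(row.allele2):
            calls.setdefault(subject, {})
            if subject not in order:
                order.append(subject)
            continue
        alleles = []
        for raw in (str(row.allele1), str(row.allele2)):
            key = raw.upper()
            if key not in canon[rsid]:
                raise ValueError(
                    f"{path}: unknown allele {raw!r} for {rsid} "
                    f"(expected one of {sorted(canon[rsid].values())})"
                )
            alleles.append(canon[rsid][key])
        call = tuple(sorted(alleles))
        subject_calls = calls.setdefault(subject, {})
        if subject not in order:
            order.append(subject)
        if rsid in subject_calls and subject_calls[rsid] != call:
            raise ValueError(
                f"{path}: conflicting duplicate call for {subject}/{rsid}"
            )
        subject_calls[rsid] = call
    if n_unknown:
        logger.info("read_genotypes: ignored %d rows with unknown rsIDs", n_unknown)
    return [GenotypeRecord.from_calls(s, calls[s]) for s in order]


def write_genotypes(
    records: list[GenotypeRecord],
    path: str | Path,
    comments: list[str] | None = None,
) -> None:
    rows = []
    for rec in records:
        for rsid in sorted(rec.calls):
            a1, a2 = rec.calls[rsid]
            rows.append((rec.subject, rsid, a1, a2))
    df = pd.DataFrame(rows, columns=["subject", "rsid", "allele1", "allele2"])
    _write_table(df, path, comments)


def read_genotypes_vcf(path: str | Path, panel: VariantPanel) -> list[GenotypeRecord]:
    """Panel-restricted VCF ingestion: biallelic SNVs matched by ID, GT
    genotypes (phased or unphased); records with missing GT omit the call.
    """
    from cyvcf2 import VCF

    wanted = set(panel.rsids)
    canon = _canonical_alleles(panel)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    calls: dict[str, dict[str, tuple[str, str]]] = {s: {} for s in samples}
    n_unknown = 0
    for variant in vcf:
        rsid = variant.ID
        if rsid not in wanted:
            n_unknown += 1
            continue
        alleles = [variant.REF] + list(variant.ALT)
        for sample, gt in zip(samples, variant.genotypes):
            i, j = gt[0], gt[1]
            if i < 0 or j < 0:
                continue
            pair = []
            for idx in (i, j):
                raw = alleles[idx]
                key = raw.upper()
                if key not in canon[rsid]:
                    raise ValueError(
                        f"{path}: VCF allele {raw!r} at {rsid} not in panel"
                    )
                pair.append(canon[rsid][key])
            calls[sample][rsid] = tuple(sorted(pair))
    if n_unknown:
        logger.info("read_genotypes_vcf: skipped %d non-panel records", n_unknown)
    return [GenotypeRecord.from_calls(s, calls[s]) for s in samples]


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Long-format composite table (subject, visit_month, composite, value)."""
    df = _read_table(path)
    required = ["subject", "visit_month", "composite", "value"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing phenotype columns {missing_cols}")
    dup = df.duplicated(subset=["subject", "visit_month", "composite"], keep=False)
    if dup.any():
        conflicting = df[dup].drop_duplicates(
            subset=["subject", "visit_month", "composite", "value"]
        )
        if conflicting.duplicated(
            subset=["subject", "visit_month", "composite"]
        ).any():
            raise ValueError(f"{path}: inconsistent duplicate phenotype records")
        df = df.drop_duplicates(subset=["subject", "visit_month", "composite"])
    df["visit_month"] = df["visit_month"].astype(float)
    df["value"] = df["value"].astype(float)
    return df.reset_index(drop=True)


def write_phenotypes(
    df: pd.DataFrame, path: str | Path, comments: list[str] | None = None
) -> None:
    _write_table(df, path, comments)


def read_covariates(path: str | Path) -> pd.DataFrame:
    df = _read_table(path)
    if "subject" not in df.columns:
        raise ValueError(f"{path}: missing 'subject' column")
    for col in df.columns:
        if col != "subject":
            df[col] = df[col].astype(float)
    return df


def write_covariates(
    df: pd.DataFrame, path: str | Path, comments: list[str] | None = None
) -> None:
    _write_table(df, path, comments)


def read_suvr(path: str | Path) -> pd.DataFrame:
    df = _read_table(path)
    required = ["subject", "visit_month", "tracer", "suvr"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing SUVR columns {missing_cols}")
    df["visit_month"] = df["visit_month"].astype(float)
    df["suvr"] = df["suvr"].astype(float)
    return df


def write_suvr(
    df: pd.DataFrame, path: str | Path, comments: list[str] | None = None
) -> None:
    _write_table(df, path, comments)


def write_scores(
    scores: list[ScoreRecord], path: str | Path, comments: list[str] | None = None
) -> None:
    df = pd.DataFrame(
        [
            (
                s.subject,
                s.emprs_with_apoe,
                s.emprs_without_apoe,
                s.n_variants_contributing,
                ";".join(s.flags) if s.flags else None,
            )
            for s in scores
        ],
        columns=[
            "subject",
            "emprs_with_apoe",
            "emprs_without_apoe",
            "n_variants_contributing",
            "flags",
        ],
    )
    _write_table(df, path, comments)


def read_scores(path: str | Path) -> list[ScoreRecord]:
    df = _read_table(path)
    out = []
    for row in df.itertuples(index=False):
        out.append(
            ScoreRecord(
                subject=str(row.subject),
                emprs_with_apoe=(
                    None if pd.isna(row.emprs_with_apoe) else float(row.emprs_with_apoe)
                ),
                emprs_without_apoe=(
                    None
                    if pd.isna(row.emprs_without_apoe)
                    else float(row.emprs_without_apoe)
                ),
                n_variants_contributing=int(row.n_variants_contributing),
                flags=[] if pd.isna(row.flags) else str(row.flags).split(";"),
            )
        )
    return out
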