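"""emPRS computation and genotype-level derivations.

The episodic-memory-weighted polygenic risk score of a subject is

    emPRS = sum_n RA_n * d_n

over the panel entries *n*, where RA_n is 1 when the subject carries the
variant's assigned risk genotype and 0 otherwise, and d_n is the variant's
effect-size weight. Two variants of the score are computed per subject:
with the APOE entry included (emPRS+APOE) and with it excluded
(emPRS-APOE); their difference for an epsilon-4 carrier is exactly the
APOE weight.

APOE epsilon genotypes are resolved from the unphased rs429358/rs7412
calls via the standard haplotype table (e2 = T-T, e3 = T-C, e4 = C-C on
the rs429358-rs7412 haplotype). The double heterozygote is resolved as
e2/e4 because the alternative phasing would require the essentially
non-occurring e1 haplotype (rs429358-C with rs7412-T), which is never
emitted; call combinations that admit only e1-containing phasings are
rejected.

Subjects homozygous for the Klotho KL-VS variant (rs9536314) are excluded
from analysis because KL-VS risk is not gene-dosage dependent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .panel import RS_APOE_E2, RS_APOE_E4, RS_KLOTHO, VariantPanel, VariantPanelEntry

__all__ = [
    "GenotypeRecord",
    "ScoreRecord",
    "ApoeResolutionError",
    "apoe_genotype",
    "kl_vs_zygosity",
    "exclude_kl_homozygotes",
    "risk_indicator",
    "compute_emprs",
    "score_subject",
    "exemplar_calls",
]

Call = tuple[str, str]


class ApoeResolutionError(ValueError):
    """Raised when rs429358/rs7412 calls admit no e1-free phasing."""


@dataclass
class GenotypeRecord:
    """Per-subject genotype calls plus derived annotations.

    ``calls`` maps rsID to an unordered biallelic call; missing calls are
    simply absent from the mapping. ``apoe`` / ``apoe_e4_count`` are None
    when either APOE SNP is missing or unresolvable (such subjects are
    flagged and excluded from epsilon-4-stratified analyses).
    """

    subject: str
    calls: dict[str, Call]
    apoe: str | None = None
    apoe_e4_count: int | None = None
    kl_vs: str = "absent"
    flags: list[str] = field(default_factory=list)

    @classmethod
    def from_calls(cls, subject: str, calls: dict[str, Call]) -> "GenotypeRecord":
        rec = cls(subject=subject, calls=dict(calls))
        rec.annotate()
        return rec

    def annotate(self) -> None:
        """(Re)derive the APOE epsilon genotype and KL-VS zygosity."""
        c429358 = self.calls.get(RS_APOE_E4)
        c7412 = self.calls.get(RS_APOE_E2)
        if c429358 is None or c7412 is None:
            self.apoe = None
            self.apoe_e4_count = None
            if "apoe_missing" not in self.flags:
                self.flags.append("apoe_missing")
        else:
            try:
                self.apoe, self.apoe_e4_count = apoe_genotype(c429358, c7412)
            except ApoeResolutionError:
                self.apoe = None
                self.apoe_e4_count = None
                if "apoe_unresolvable" not in self.flags:
                    self.flags.append("apoe_unresolvable")
        kl = self.calls.get(RS_KLOTHO)
        self.kl_vs = kl_vs_zygosity(kl) if kl is not None else "absent"

    def carries(self, allele: str) -> dict[str, bool]:
        return {rs: allele in call for rs, call in self.calls.items()}


@dataclass
class ScoreRecord:
    """emPRS of one subject, with and without the APOE contribution."""

    subject: str
    emprs_with_apoe: float | None
    emprs_without_apoe: float | None
    n_variants_contributing: int
    flags: list[str] = field(default_factory=list)


_EPSILON = {("T", "T"): "e2", ("T", "C"): "e3", ("C", "C"): "e4"}
# key: (rs429358 allele, rs7412 allele) on one haplotype; (C, T) is e1.


def apoe_genotype(rs429358_call: Call, rs7412_call: Call) -> tuple[str, int]:
    """Resolve APOE epsilon genotype from unphased rs429358/rs7412 calls.

    Returns ``(label, e4_count)``, e.g. ``("e3/e4", 1)``. Phasings
    requiring the e1 haplotype are excluded; the double heterozygote
    therefore resolves uniquely to e2/e4.

    Raises
    ------
    ApoeResolutionError
        If every phase-consistent haplotype pair contains e1.
    ValueError
        If a call contains alleles other than C/T.
    """
    for call, rsid in ((rs429358_call, RS_APOE_E4), (rs7412_call, RS_APOE_E2)):
        bad = set(call) - {"C", "T"}
        if bad:
            raise ValueError(f"{rsid}: unexpected alleles {sorted(bad)}")
    phasings = []
    a1, a2 = rs429358_call
    for b1, b2 in {(rs7412_call[0], rs7412_call[1]), (rs7412_call[1], rs7412_call[0])}:
        h1, h2 = (a1, b1), (a2, b2)
        if h1 in _EPSILON and h2 in _EPSILON:
            phasings.append(tuple(sorted((_EPSILON[h1], _EPSILON[h2]))))
    if not phasings:
        raise ApoeResolutionError(
            f"calls rs429358={''.join(rs429358_call)} rs7412={''.join(rs7412_call)} "
            "admit only e1-containing haplotype phasings"
        )
    # (CT, CT) yields both e2/e4 phasings; all consistent pairs are identical.
    eps = sorted(phasings)[0]
    return "/".join(eps), sum(1 for e in eps if e == "e4")


def kl_vs_zygosity(call: Call) -> str:
    n = sum(1 for a in call if a == "VS")
    return {0: "absent", 1: "heterozygous", 2: "homozygous"}[n]


def exclude_kl_homozygotes(
    records: list[GenotypeRecord],
) -> tuple[list[GenotypeRecord], int]:
    """Drop KL-VS homozygotes; returns (retained, n_excluded)."""
    retained = [r for r in records if r.kl_vs != "homozygous"]
    return retained, len(records) - len(retained)


def risk_indicator(record: GenotypeRecord, entry: VariantPanelEntry) -> int | None:
    """RA_n: 1 if the subject carries the entry's risk genotype, else 0.

    Returns None when the required calls are missing (or, for APOE, the
    epsilon genotype could not be resolved).
    """
    if entry.is_apoe:
        if record.apoe_e4_count is None:
            return None
        if entry.risk_genotype == "e4-":  # derived panels may flip the label
            return int(record.apoe_e4_count == 0)
        return int(record.apoe_e4_count >= 1)
    call = record.calls.get(entry.rsid)
    if call is None:
        return None
    allele = entry.risk_allele()
    if entry.risk_is_carrier():
        return int(allele in call)
    return int(call[0] == allele and call[1] == allele)


def score_subject(
    record: GenotypeRecord, panel: VariantPanel, include_apoe: bool = True
) -> tuple[float | None, int, list[str]]:
    """Sum of weights over risk genotypes present; strict on missing calls.

    Returns (score, n_contributing, missing_genes); score is None when any
    panel genotype is missing.
    """
    total = 0.0
    n_contrib = 0
    missing = []
    for entry in panel:
        if entry.is_apoe and not include_apoe:
            continue
        ra = risk_indicator(record, entry)
        if ra is None:
            missing.append(entry.gene)
        elif ra:
            total += entry.weight
            n_contrib += 1
    if missing:
        return None, n_contrib, missing
    return total, n_contrib, missing


def compute_emprs(
    records: list[GenotypeRecord],
    panel: VariantPanel,
    include_apoe: bool = True,
    missing_policy: str = "strict",
) -> list[ScoreRecord]:
    """Compute per-subject emPRS with and without the APOE entry.

    ``include_apoe=False`` drops the APOE entry entirely, in which case
    ``emprs_with_apoe`` is reported as None.

    Missing-genotype policy: "strict" leaves the affected subject's scores
    as None with an ``incomplete`` flag; "available-variant" scores over
    the non-missing entries and rescales by the ratio of total panel
    weight to available weight (flagged ``rescaled``).
    """
    if len(panel) == 0:
        raise ValueError("empty weight panel")
    if missing_policy not in ("strict", "available-variant"):
        raise ValueError(f"unknown missing-genotype policy {missing_policy!r}")
    out = []
    for rec in records:
        with_a, n_with, missing = score_subject(rec, panel, include_apoe=True)
        without_a, n_without, _ = score_subject(rec, panel, include_apoe=False)
        flags = list(rec.flags)
        if missing:
            flags.append("incomplete:" + ",".join(missing))
            if missing_policy == "available-variant":
                flags.append("rescaled")
                with_a = _rescaled_score(rec, panel, include_apoe=True)
                without_a = _rescaled_score(rec, panel, include_apoe=False)
            else:
                with_a = without_a = None
        if not include_apoe:
            with_a = None
        out.append(
            ScoreRecord(
                subject=rec.subject,
                emprs_with_apoe=with_a,
                emprs_without_apoe=without_a,
                n_variants_contributing=n_with if include_apoe else n_without,
                flags=flags,
            )
        )
    return out


def _rescaled_score(
    rec: GenotypeRecord, panel: VariantPanel, include_apoe: bool
) -> float | None:
    total_w = avail_w = score = 0.0
    for entry in panel:
        if entry.is_apoe and not include_apoe:
            continue
        total_w += entry.weight
        ra = risk_indicator(rec, entry)
        if ra is None:
            continue
        avail_w += entry.weight
        score += ra * entry.weight
    if avail_w == 0:
        return None
    return score * total_w / avail_w if total_w > 0 else 0.0


def exemplar_calls(
    panel: VariantPanel, risk_genes: set[str] | frozenset[str] = frozenset()
) -> dict[str, Call]:
    """Construct a complete call set carrying the risk genotype exactly at
    ``risk_genes`` and a non-risk genotype everywhere else.

    Useful for worked examples and score identities: the resulting record
    scores the sum of the weights of ``risk_genes``.
    """
    calls: dict[str, Call] = {}
    for entry in panel:
        risky = entry.gene in risk_genes
        if entry.is_apoe:
            if risky:  # e4/e4
                calls[RS_APOE_E4] = ("C", "C")
                calls[RS_APOE_E2] = ("C", "C")
            else:  # e3/e3
                calls[RS_APOE_E4] = ("T", "T")
                calls[RS_APOE_E2] = ("C", "C")
            continue
        allele = entry.risk_allele()
        other = (
            entry.major_allele if allele != entry.major_allele else entry.minor_allele
        )
        if entry.risk_is_carrier():
            calls[entry.rsid] = (allele, other) if risky else (other, other)
        else:
            calls[entry.rsid] = (allele, allele) if risky else (allele, other)
    unknown = risk_genes - set(panel.genes)
    if unknown:
        raise KeyError(f"risk genes not in panel: {sorted(unknown)}")
    return calls
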