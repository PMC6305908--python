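"""Variant weight panels.

A panel is the fixed set of genetic variants that contribute to the
episodic-memory-weighted polygenic risk score (emPRS), together with
per-variant metadata: minor allele under the dominant model, the assigned
risk genotype (the dominant-model group that declines faster), and the
effect-size weight *d* (Cohen's d on verbal-episodic-memory slopes) with
its 95% confidence interval.

The packaged reference panel (``load_reference_panel``) holds the 27-gene
panel with its published effect-size weights; 21 entries are sourced from
Alzheimer's disease risk loci and 6 from cognition-associated loci.
APOE is a single entry keyed by two SNPs (rs7412, rs429358) whose
haplotypes define the epsilon alleles.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

__all__ = [
    "VariantPanelEntry",
    "VariantPanel",
    "PanelFormatError",
    "load_reference_panel",
]

APOE_GENE = "APOE"
RS_APOE_E4 = "rs429358"
RS_APOE_E2 = "rs7412"
RS_KLOTHO = "rs9536314"

_COLUMNS = [
    "gene",
    "rsids",
    "chromosome",
    "positions",
    "minor_allele",
    "major_allele",
    "risk_genotype",
    "d",
    "ci_low",
    "ci_high",
    "source",
]


class PanelFormatError(ValueError):
    """Raised when a panel file violates the panel dialect."""


@dataclass(frozen=True)
class VariantPanelEntry:
    """One panel row: a gene-level variant with its risk weight.

    ``risk_genotype`` is either a carrier label ``"X+"`` (any copy of
    allele X) or a homozygote label ``"X/X"``; for APOE it is ``"e4+"``
    (epsilon-4 carriage). ``weight`` is a non-negative Cohen's d; the
    direction of effect is absorbed into the risk-genotype assignment.
    """

    gene: str
    rsids: tuple[str, ...]
    chromosome: str
    positions: tuple[int, ...]
    minor_allele: str
    major_allele: str
    risk_genotype: str
    weight: float
    ci_low: float
    ci_high: float
    source: str = "derived"
    flags: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise PanelFormatError(
                f"{self.gene}: weight must be >= 0, got {self.weight}"
            )
        if len(self.rsids) != len(self.positions):
            raise PanelFormatError(
                f"{self.gene}: {len(self.rsids)} rsIDs but "
                f"{len(self.positions)} positions"
            )
        ok = (
            self.risk_genotype.endswith("+")
            or "/" in self.risk_genotype
            or (self.is_apoe and self.risk_genotype == "e4-")
        )
        if not ok:
            raise PanelFormatError(
                f"{self.gene}: risk genotype {self.risk_genotype!r} is neither "
                "a carrier label 'X+' nor a homozygote label 'X/X'"
            )

    @property
    def is_apoe(self) -> bool:
        return self.gene == APOE_GENE

    @property
    def rsid(self) -> str:
        """Primary rsID (the only one for single-SNP entries)."""
        return self.rsids[0]

    def risk_is_carrier(self) -> bool:
        """True if the risk group is defined by carriage of an allele."""
        return self.risk_genotype.endswith("+")

    def risk_allele(self) -> str:
        """The allele named by the risk-genotype label."""
        if self.risk_is_carrier():
            return self.risk_genotype[:-1]
        left, right = self.risk_genotype.split("/")
        if left != right:
            raise PanelFormatError(
                f"{self.gene}: heterozygous risk genotype {self.risk_genotype!r}"
            )
        return left


class VariantPanel:
    """An ordered collection of :class:`VariantPanelEntry`, one per gene."""

    def __init__(self, entries: list[VariantPanelEntry]):
        genes = [e.gene for e in entries]
        dupes = {g for g in genes if genes.count(g) > 1}
        if dupes:
            raise PanelFormatError(f"duplicate gene entries: {sorted(dupes)}")
        self._entries = list(entries)
        self._by_gene = {e.gene: e for e in entries}

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[VariantPanelEntry]:
        return iter(self._entries)

    def __contains__(self, gene: str) -> bool:
        return gene in self._by_gene

    def __getitem__(self, gene: str) -> VariantPanelEntry:
        return self._by_gene[gene]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VariantPanel):
            return NotImplemented
        return self._entries == other._entries

    @property
    def genes(self) -> list[str]:
        return [e.gene for e in self._entries]

    @property
    def rsids(self) -> list[str]:
        return [rs for e in self._entries for rs in e.rsids]

    def total_weight(self, include_apoe: bool = True) -> float:
        return sum(
            e.weight for e in self._entries if include_apoe or not e.is_apoe
        )

    def without_apoe(self) -> "VariantPanel":
        return VariantPanel([e for e in self._entries if not e.is_apoe])

    def subset(self, genes: list[str]) -> "VariantPanel":
        return VariantPanel([self._by_gene[g] for g in genes])

    def with_weights(self, weights: dict[str, float]) -> "VariantPanel":
        """Return a copy with new weights (CIs cleared)."""
        return VariantPanel(
            [
                replace(e, weight=weights.get(e.gene, e.weight))
                for e in self._entries
            ]
        )

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_tsv(cls, path: str | Path) -> "VariantPanel":
        path = Path(path)
        lines = [
            ln
            for ln in path.read_text().splitlines()
            if ln.strip() and not ln.startswith("#")
        ]
        if not lines:
            raise PanelFormatError(f"{path}: empty panel file")
        header = lines[0].rstrip("\n").split("\t")
        if header != _COLUMNS:
            raise PanelFormatError(
                f"{path}: header {header} does not match panel dialect {_COLUMNS}"
            )
        entries = []
        for lineno, line in enumerate(lines[1:], start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(_COLUMNS):
                raise PanelFormatError(
                    f"{path}:{lineno}: expected {len(_COLUMNS)} fields, "
                    f"got {len(fields)}"
                )
            row = dict(zip(_COLUMNS, fields))
            try:
                entry = VariantPanelEntry(
                    gene=row["gene"],
                    rsids=tuple(row["rsids"].split(",")),
                    chromosome=row["chromosome"],
                    positions=tuple(int(p) for p in row["positions"].split(",")),
                    minor_allele=row["minor_allele"],
                    major_allele=row["major_allele"],
                    risk_genotype=row["risk_genotype"],
                    weight=float(row["d"]),
                    ci_low=float(row["ci_low"]),
                    ci_high=float(row["ci_high"]),
                    source=row["source"],
                )
            except (ValueError, PanelFormatError) as exc:
                raise PanelFormatError(f"{path}:{lineno}: {exc}") from exc
            entries.append(entry)
        try:
            return cls(entries)
        except PanelFormatError as exc:
            raise PanelFormatError(f"{path}: {exc}") from exc

    def to_tsv(self, path: str | Path, header_comment: str | None = None) -> None:
        path = Path(path)
        out = []
        if header_comment:
            out.append(f"# {header_comment}")
        out.append("\t".join(_COLUMNS))
        for e in self._entries:
            out.append(
                "\t".join(
                    [
                        e.gene,
                        ",".join(e.rsids),
                        e.chromosome,
                        ",".join(str(p) for p in e.positions),
                        e.minor_allele,
                        e.major_allele,
                        e.risk_genotype,
                        f"{e.weight:.6g}",
                        f"{e.ci_low:.6g}",
                        f"{e.ci_high:.6g}",
                        e.source,
                    ]
                )
            )
        path.write_text("\n".join(out) + "\n")


def load_reference_panel() -> VariantPanel:
    """Load the packaged 27-gene reference panel with published weights."""
    ref = importlib.resources.files("emprs.data").joinpath("reference_panel.tsv")
    with importlib.resources.as_file(ref) as path:
        return VariantPanel.from_tsv(path)
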