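"""Per-organism and per-group census of TCS/PR protein types.

The census counts proteins by canonical architecture type (HK, RR, HKRR,
HKRRHPt, ...), reports what fraction of a proteome is devoted to TCS/PR
signaling (typically 1–2% in prokaryotes), summarises type abundance across
organisms, and tabulates per-phylum presence/absence of the three domain
families.

Percentages and averages are rounded half-up to two decimals, the precision
used in the report tables.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .domain_architecture import classify_architecture, parse_architecture
from .io_formats import GeneRecord


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimals (report convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float, ndigits: int = 2) -> float:
    """``100 × numerator/denominator`` rounded half-up — the report formatter."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round_half_up(100.0 * numerator / denominator, ndigits)


@dataclass
class OrganismCensus:
    """Summary of one organism's TCS/PR protein content.

    ``n_hk_single`` / ``n_rr_single`` / ``n_hpt_single`` count proteins whose
    architecture is exactly one domain ("HK", "RR", "HPt"); these are the
    counts the closed-form neighboring expectations use. Hybrids are counted
    under their own type strings in ``type_counts``.
    """

    organism_id: str
    total_proteins: int
    type_counts: dict[str, int] = field(default_factory=dict)
    phylum: str = ""
    phylogeny: int = 1  # 1 = prokaryote, 2 = eukaryote

    def __post_init__(self) -> None:
        if self.phylogeny not in (1, 2):
            raise ValueError("phylogeny indicator must be 1 (prokaryote) or 2")
        if self.total_proteins < self.total_tcs_pr:
            raise ValueError(
                f"total proteins P={self.total_proteins} smaller than the "
                f"{self.total_tcs_pr} TCS/PR proteins counted"
            )

    @property
    def total_tcs_pr(self) -> int:
        return sum(self.type_counts.values())

    @property
    def pct_tcs_pr(self) -> float:
        return percent(self.total_tcs_pr, self.total_proteins)

    @property
    def n_hk_single(self) -> int:
        return self.type_counts.get("HK", 0)

    @property
    def n_rr_single(self) -> int:
        return self.type_counts.get("RR", 0)

    @property
    def n_hpt_single(self) -> int:
        return self.type_counts.get("HPt", 0)

    def domain_instance_counts(self) -> Counter[str]:
        """Total HK/RR/HPt domain instances across all proteins."""
        out: Counter[str] = Counter()
        for type_string, n in self.type_counts.items():
            for d in parse_architecture(type_string):
                out[d] += n
        return out

    def has_domain(self, domain: str) -> bool:
        return self.domain_instance_counts()[domain] > 0


def census_organism(
    genes: Sequence[GeneRecord],
    total_proteins: int,
    phylum: str = "",
    phylogeny: int = 1,
) -> OrganismCensus:
    """Count protein types for one organism's gene table."""
    ist = [g for g in genes if g.is_ist]
    if total_proteins < len(ist):
        raise ValueError(
            f"total proteins P={total_proteins} smaller than the "
            f"{len(ist)} IST genes in the table"
        )
    counts: Counter[str] = Counter(
        classify_architecture(g.domains) for g in ist
    )
    organism_id = genes[0].organism_id if genes else ""
    return OrganismCensus(
        organism_id=organism_id,
        total_proteins=total_proteins,
        type_counts=dict(counts),
        phylum=phylum,
        phylogeny=phylogeny,
    )


def type_summary(censuses: Iterable[OrganismCensus]) -> pd.DataFrame:
    """Abundance summary per protein type across organisms.

    Columns: type, total proteins found, % of proteomes with the type,
    number of species with the type, and average proteins per organism
    that has the type. Types present in no organism are omitted.
    """
    censuses = list(censuses)
    if not censuses:
        raise ValueError("at least one organism census required")
    n_organisms = len(censuses)
    totals: Counter[str] = Counter()
    species_with: Counter[str] = Counter()
    for c in censuses:
        for t, n in c.type_counts.items():
            if n > 0:
                totals[t] += n
                species_with[t] += 1
    rows = [
        {
            "type": t,
            "total_proteins": totals[t],
            "pct_proteomes_with_type": percent(species_with[t], n_organisms),
            "n_species_with_type": species_with[t],
            "avg_proteins_per_organism": round_half_up(totals[t] / species_with[t]),
        }
        for t in totals
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "type",
            "total_proteins",
            "pct_proteomes_with_type",
            "n_species_with_type",
            "avg_proteins_per_organism",
        ],
    )
    return df.sort_values("total_proteins", ascending=False, ignore_index=True)


def phylum_presence(
    censuses: Iterable[OrganismCensus],
    grouping: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-group presence/absence of the HK/RR and HPt domain families.

    ``pct_with_hk_or_rr`` counts species carrying at least one protein with
    an HK domain or at least one with an RR domain; ``pct_with_hk_and_rr``
    requires both families; ``pct_with_hpt`` is analogous for HPt. The
    "or" variant is the headline presence metric.
    """
    censuses = list(censuses)
    groups: dict[str, list[OrganismCensus]] = {}
    for c in censuses:
        label = grouping[c.organism_id] if grouping is not None else c.phylum
        groups.setdefault(label, []).append(c)
    rows = []
    for label in sorted(groups):
        members = groups[label]
        n = len(members)
        n_or = sum(1 for c in members if c.has_domain("HK") or c.has_domain("RR"))
        n_and = sum(1 for c in members if c.has_domain("HK") and c.has_domain("RR"))
        n_hpt = sum(1 for c in members if c.has_domain("HPt"))
        rows.append(
            {
                "group": label,
                "n_species": n,
                "pct_with_hk_or_rr": percent(n_or, n),
                "pct_with_hk_and_rr": percent(n_and, n),
                "pct_with_hpt": percent(n_hpt, n),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "group",
            "n_species",
            "pct_with_hk_or_rr",
            "pct_with_hk_and_rr",
            "pct_with_hpt",
        ],
    )


def orphan_fraction(genes: Sequence[GeneRecord]) -> float:
    """Fraction of IST genes with no IST gene at an adjacent position.

    Adjacency is strict (±1 position on the same replicon, no gap
    tolerance) — deliberately independent of the gap-tolerant cluster rule.
    Returns 0.0 for a table with no IST genes.
    """
    ist_positions: dict[tuple[str, str], set[int]] = {}
    for g in genes:
        if g.is_ist:
            ist_positions.setdefault((g.organism_id, g.replicon_id), set()).add(
                g.position
            )
    n_ist = sum(len(s) for s in ist_positions.values())
    if n_ist == 0:
        return 0.0
    n_orphan = 0
    for positions in ist_positions.values():
        for p in positions:
            if (p - 1) not in positions and (p + 1) not in positions:
                n_orphan += 1
    return n_orphan / n_ist
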