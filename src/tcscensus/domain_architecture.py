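"""Curation of homology hits into per-protein IST-domain architectures.

The pipeline that turns raw search output into a clean census has four
stages: (1) threshold filtering of hits on e-value and domain coverage,
(2) merging the four search sources (profile-HMM, PSI-BLAST against the
alignment, PSI-BLAST against the consensus, and annotation text mining)
into a non-redundant set, (3) an iterative annotation-curation loop that
discards proteins whose free-text annotation points to an unrelated
function (e.g. serine kinases), and (4) a conserved-motif check that drops
sequences lacking the phosphotransfer histidine (HK, HPt) or the
phospho-accepting aspartate (RR).

Architectures are named by concatenating the domains N→C; when a domain
type occurs k ≥ 2 times its instances are numbered 1..k in order, so
[HK, RR, HK] is the unorthodox kinase "HK1RRHK2" and [HK, RR] the hybrid
kinase "HKRR".
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_formats import DOMAIN_CODES, AlignmentBlock, HitRecord

logger = logging.getLogger(__name__)

#: Motif residue whose conservation each domain type requires.
MOTIF_RESIDUE = {"HK": "H", "HPt": "H", "RR": "D"}

DEFAULT_INCLUSION_TERMS = (
    "histidine kinase",
    "response regulator",
    "histidine phosphotransferase",
    "sensory kinase",
    "hybrid kinase",
)

DEFAULT_EXCLUSION_TERMS = (
    "serine kinase",
    "serine/threonine kinase",
    "tyrosine kinase",
)


@dataclass(frozen=True)
class CurationConfig:
    """Thresholds and term lists that steer hit filtering and curation.

    ``e_value_threshold`` is exclusive (a hit at exactly the threshold is
    rejected) while ``min_coverage`` is inclusive.
    """

    e_value_threshold: float = 1e-6
    min_coverage: float = 0.80
    exclusion_terms: tuple[str, ...] = DEFAULT_EXCLUSION_TERMS
    inclusion_terms: tuple[str, ...] = DEFAULT_INCLUSION_TERMS

    def __post_init__(self) -> None:
        if self.e_value_threshold <= 0 or self.min_coverage <= 0:
            raise ValueError("thresholds must be positive")
        object.__setattr__(
            self, "exclusion_terms", tuple(t.lower() for t in self.exclusion_terms)
        )
        object.__setattr__(
            self, "inclusion_terms", tuple(t.lower() for t in self.inclusion_terms)
        )


@dataclass(frozen=True)
class ProteinArchitecture:
    """Ordered IST-domain content of one protein and its canonical name."""

    protein_id: str
    domains: tuple[str, ...]
    type_string: str = field(default="")
    hypothetical: bool = False

    def __post_init__(self) -> None:
        if not self.domains:
            raise ValueError("a TCS/PR protein must carry at least one domain")
        if not self.type_string:
            object.__setattr__(self, "type_string", classify_architecture(self.domains))

    @property
    def n_hk(self) -> int:
        return self.domains.count("HK")

    @property
    def n_rr(self) -> int:
        return self.domains.count("RR")

    @property
    def n_hpt(self) -> int:
        return self.domains.count("HPt")


def filter_hits(
    hits: Iterable[HitRecord], config: CurationConfig | None = None
) -> list[HitRecord]:
    """Keep hits with e-value strictly below threshold and coverage ≥ minimum."""
    config = config or CurationConfig()
    return [
        h
        for h in hits
        if h.e_value < config.e_value_threshold and h.coverage >= config.min_coverage
    ]


def merge_search_results(
    *hit_sets: Iterable[HitRecord],
) -> dict[tuple[str, str], HitRecord]:
    """Merge filtered hit sets from the search sources into a non-redundant map.

    The result is keyed by (protein_id, domain); when several sources report
    the same assignment the highest-coverage record wins and the conflict is
    logged.
    """
    merged: dict[tuple[str, str], HitRecord] = {}
    for hit_set in hit_sets:
        for hit in hit_set:
            key = (hit.protein_id, hit.domain)
            incumbent = merged.get(key)
            if incumbent is None:
                merged[key] = hit
            elif hit.coverage > incumbent.coverage:
                logger.debug(
                    "conflicting assignments for %s/%s: %s (cov %.2f) supersedes "
                    "%s (cov %.2f)",
                    hit.protein_id,
                    hit.domain,
                    hit.source,
                    hit.coverage,
                    incumbent.source,
                    incumbent.coverage,
                )
                merged[key] = hit
    return merged


def curate_annotations(
    annotations: Mapping[str, str], config: CurationConfig | None = None
) -> tuple[dict[str, str], dict[str, str]]:
    """Iteratively discard proteins whose annotation flags a non-TCS/PR function.

    A protein is discarded when its annotation matches an exclusion term and
    contains no inclusion term; the loop repeats until the kept set is
    stable (a fixed point, reached in at most ``len(annotations)`` rounds).
    Returns ``(kept, discarded)`` as id → annotation maps.
    """
    config = config or CurationConfig()
    kept = dict(annotations)
    discarded: dict[str, str] = {}
    while True:
        to_drop = []
        for pid, text in kept.items():
            low = text.lower()
            excluded = any(term in low for term in config.exclusion_terms)
            included = any(term in low for term in config.inclusion_terms)
            if excluded and not included:
                to_drop.append(pid)
        if not to_drop:
            break
        for pid in to_drop:
            discarded[pid] = kept.pop(pid)
    return kept, discarded


def consensus_sequence(alignment: AlignmentBlock) -> str:
    """Most common non-gap residue per column; ties break alphabetically.

    A column that is all gaps emits 'X'.
    """
    out = []
    for i in range(alignment.length):
        residues = [c for c in alignment.column(i) if c != "-"]
        if not residues:
            out.append("X")
            continue
        counts = Counter(residues)
        best = max(counts.items(), key=lambda kv: (kv[1], -ord(kv[0])))
        out.append(best[0])
    return "".join(out)


def motif_conservation_check(
    alignment: AlignmentBlock, domain_type: str
) -> dict[str, bool]:
    """Check each sequence for the conserved phosphotransfer residue.

    The motif column is the alignment column with the highest frequency of
    the motif residue (H for HK/HPt, D for RR; earliest column on ties). A
    sequence passes iff it carries the motif residue at that column.
    """
    motif = MOTIF_RESIDUE[domain_type]
    best_col, best_count = -1, 0
    for i in range(alignment.length):
        count = alignment.column(i).count(motif)
        if count > best_count:
            best_col, best_count = i, count
    if best_count == 0:
        raise ValueError(
            f"no conserved motif column: residue {motif!r} absent from alignment"
        )
    return {
        seq_id: row[best_col] == motif
        for seq_id, row in zip(alignment.ids, alignment.rows)
    }


def classify_architecture(domains: Sequence[str]) -> str:
    """Canonical type string for an ordered N→C domain list.

    Domain types occurring k ≥ 2 times have their instances numbered 1..k
    in order of occurrence; singletons stay unnumbered: [HK, RR, HK] →
    "HK1RRHK2", [HK, RR] → "HKRR".
    """
    if not domains:
        raise ValueError("cannot classify an empty domain list")
    for d in domains:
        if d not in DOMAIN_CODES:
            raise ValueError(f"unknown domain code {d!r}")
    totals = Counter(domains)
    seen: Counter[str] = Counter()
    parts = []
    for d in domains:
        seen[d] += 1
        parts.append(f"{d}{seen[d]}" if totals[d] >= 2 else d)
    return "".join(parts)


_TOKEN_RE = re.compile(r"(HPt|HK|RR)(\d*)")


def parse_architecture(type_string: str) -> tuple[str, ...]:
    """Inverse of :func:`classify_architecture` (exact round-trip enforced)."""
    pos = 0
    domains: list[str] = []
    while pos < len(type_string):
        m = _TOKEN_RE.match(type_string, pos)
        if m is None:
            raise ValueError(f"malformed architecture string {type_string!r} at {pos}")
        domains.append(m.group(1))
        pos = m.end()
    if not domains:
        raise ValueError("empty architecture string")
    result = tuple(domains)
    if classify_architecture(result) != type_string:
        raise ValueError(
            f"architecture string {type_string!r} is not in canonical form"
        )
    return result


def architectures_from_genes(genes) -> list[ProteinArchitecture]:
    """Build ProteinArchitecture entries for every IST gene in a gene table."""
    return [
        ProteinArchitecture(protein_id=g.gene_id, domains=tuple(g.domains))
        for g in genes
        if g.is_ist
    ]
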