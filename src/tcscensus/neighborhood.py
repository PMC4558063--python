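"""Gene clusters and neighborhood statistics for TCS/PR coding genes.

Two distinct spatial rules live here, both deliberate:

* **Cluster (operon) detection** groups IST genes lying in consecutive
  positions, tolerating one intervening non-IST "gap" gene between members
  (such a gene may carry regulatory function for the operon). Isolated IST
  genes are orphans, not clusters.

* **Neighborhood patterns** use strict adjacency: an anchor gene of the
  pattern's first-named type must sit in a contiguous window with genes of
  the required types — a gap gene never satisfies a pattern.

Observed neighboring fractions are compared with closed-form expectations
under a fully random gene order. For a genome with P proteins, n_RR
single-RR proteins and n_HK single-HK proteins the expectations are::

    F(HK↔RR)            = n_RR/(P−1) + n_RR/(P−2)
    F(HK↔RR↔HK2)        = 6 · n_HK/(P−1) · n_RR/(P−2)
    F(HK↔RR↔HK2↔RR2)    = 12 · n_RR/(P−1) · (n_HK−1)/(P−2) · (n_RR−1)/(P−3)
    F(HKRR↔HK↔RR)       = 6 · n_HK/(P−1) · n_RR/(P−2)
    F(HKRRHPt↔RR)       = n_RR/(P−1) + n_RR/(P−2)
    F(HKRRHK↔RR)        = n_RR/(P−1) + n_RR/(P−2)

The pair form is the probability that a fixed interior gene has a single-RR
gene at position j−1 or j+1; the factor 6 (resp. 12) counts the distinct
spatial arrangements of the three- (four-)gene series, with the two RR
genes of the quadruple indistinguishable. These are first-order
approximations valid when IST counts are small relative to P; the
permutation Monte-Carlo null here reproduces them including edge effects
and serves as their oracle. Enrichment is reported as the odds ratio
observed/expected: planted or real operons push it into the 10–100× range.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import permutations
from typing import Iterable, Mapping, Sequence

import numpy as np

from .domain_architecture import classify_architecture
from .io_formats import GeneRecord

#: The six neighborhood patterns: anchor type, companion types required in a
#: contiguous window around the anchor, and the expectation form.
PATTERNS: dict[str, dict] = {
    "HK-RR": {"anchor": "HK", "companions": ("RR",), "form": "pair"},
    "HK-RR-HK2": {"anchor": "HK", "companions": ("RR", "HK"), "form": "triple"},
    "HK-RR-HK2-RR2": {
        "anchor": "HK",
        "companions": ("RR", "HK", "RR"),
        "form": "quadruple",
    },
    "HKRR-HK-RR": {"anchor": "HKRR", "companions": ("HK", "RR"), "form": "triple"},
    "HKRRHPt-RR": {"anchor": "HKRRHPt", "companions": ("RR",), "form": "pair"},
    "HKRRHK-RR": {"anchor": "HK1RRHK2", "companions": ("RR",), "form": "pair"},
}


@dataclass(frozen=True)
class ClusterCall:
    """A maximal run of IST genes with at most one gap gene between members."""

    organism_id: str
    replicon_id: str
    member_positions: tuple[int, ...]
    gap_positions: tuple[int, ...]
    member_types: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.member_positions) < 2:
            raise ValueError("a cluster needs at least two IST members")
        first, last = self.member_positions[0], self.member_positions[-1]
        if any(not first < g < last for g in self.gap_positions):
            raise ValueError("gap positions must lie strictly inside the cluster")

    @property
    def label(self) -> str:
        """Cluster type label: member type strings joined in genomic order."""
        return "-".join(self.member_types)


@dataclass(frozen=True)
class NeighborhoodStat:
    """Observed vs expected neighboring frequency for one pattern."""

    pattern: str
    observed: float | None
    expected: float
    odds_ratio: float | None
    anchor_count: int


def detect_clusters(
    genes: Sequence[GeneRecord], max_gap: int = 1
) -> list[ClusterCall]:
    """Find gap-tolerant runs of IST genes; per replicon, never spanning two.

    Consecutive members may be separated by at most ``max_gap`` non-IST
    genes. Every IST gene ends up in exactly one cluster or is an orphan.
    """
    by_replicon: dict[tuple[str, str], list[GeneRecord]] = {}
    for g in genes:
        by_replicon.setdefault((g.organism_id, g.replicon_id), []).append(g)
    clusters: list[ClusterCall] = []
    for (org, rep), replicon_genes in by_replicon.items():
        replicon_genes.sort(key=lambda g: g.position)
        ist = [g for g in replicon_genes if g.is_ist]
        run: list[GeneRecord] = []
        for g in ist:
            if run and g.position - run[-1].position <= max_gap + 1:
                run.append(g)
            else:
                if len(run) >= 2:
                    clusters.append(_make_cluster(org, rep, run))
                run = [g]
        if len(run) >= 2:
            clusters.append(_make_cluster(org, rep, run))
    return clusters


def _make_cluster(org: str, rep: str, members: list[GeneRecord]) -> ClusterCall:
    positions = tuple(g.position for g in members)
    member_set = set(positions)
    gaps = tuple(
        p
        for p in range(positions[0] + 1, positions[-1])
        if p not in member_set
    )
    return ClusterCall(
        organism_id=org,
        replicon_id=rep,
        member_positions=positions,
        gap_positions=gaps,
        member_types=tuple(classify_architecture(g.domains) for g in members),
    )


def cluster_type_catalog(clusters: Iterable[ClusterCall]) -> dict[str, int]:
    """Aggregate cluster labels into label → count (genomic order preserved;
    mirror orders such as HK-RR and RR-HK stay distinct)."""
    return dict(Counter(c.label for c in clusters))


def arrangement_multiplicity(pattern: Sequence[str]) -> int:
    """Distinct orderings of a multiset of gene categories, by brute force.

    Enumerate all permutations and deduplicate — deliberately not the
    n!/∏ mᵢ! formula, so the formula can be property-tested against this.
    """
    if not 2 <= len(pattern) <= 6:
        raise ValueError("pattern must contain 2–6 genes")
    return len(set(permutations(pattern)))


def expected_frequency(pattern: str, n_counts: Mapping[str, int], P: int) -> float:
    """Closed-form random-order neighboring expectation for one pattern.

    ``n_counts`` supplies ``n_HK`` and ``n_RR`` (counts of single-domain HK
    and RR proteins). Raises when the first-order approximation leaves
    [0, 1] — the formulas are only valid for sparse counts.
    """
    if pattern not in PATTERNS:
        raise ValueError(f"unknown pattern {pattern!r}")
    if P < 4:
        raise ValueError("P must be at least 4")
    n_hk = n_counts.get("n_HK", 0)
    n_rr = n_counts.get("n_RR", 0)
    if n_hk < 0 or n_rr < 0:
        raise ValueError("counts must be non-negative")
    form = PATTERNS[pattern]["form"]
    if form == "pair":
        f = n_rr / (P - 1) + n_rr / (P - 2)
    elif form == "triple":
        f = 6.0 * n_hk / (P - 1) * n_rr / (P - 2)
    else:  # quadruple
        f = (
            12.0
            * n_rr
            / (P - 1)
            * max(n_hk - 1, 0)
            / (P - 2)
            * max(n_rr - 1, 0)
            / (P - 3)
        )
    if f > 1.0:
        raise ValueError(
            f"expected frequency {f:.3f} exceeds 1: counts too large for the "
            "sparse-count approximation"
        )
    return f


def _type_positions(
    genes: Sequence[GeneRecord],
) -> dict[tuple[str, str], dict[int, str]]:
    """Per replicon: position → canonical type string for IST genes."""
    out: dict[tuple[str, str], dict[int, str]] = {}
    for g in genes:
        key = (g.organism_id, g.replicon_id)
        rep = out.setdefault(key, {})
        if g.is_ist:
            rep[g.position] = classify_architecture(g.domains)
    return out


def _replicon_lengths(genes: Sequence[GeneRecord]) -> dict[tuple[str, str], int]:
    lengths: dict[tuple[str, str], int] = {}
    for g in genes:
        key = (g.organism_id, g.replicon_id)
        lengths[key] = max(lengths.get(key, 0), g.position)
    return lengths


def observed_frequency(
    genes: Sequence[GeneRecord], pattern: str
) -> tuple[float | None, int]:
    """Fraction of anchor genes whose neighborhood realises the pattern.

    The anchor set is every gene of the pattern's first-named type. For the
    pair patterns the companion must sit at position ±1; for three- and
    four-gene patterns the anchor must lie inside a contiguous window whose
    other members are exactly the companion types, in any order. An anchor
    matching in both directions still counts once. Returns ``(None, 0)``
    when there are no anchors.
    """
    if pattern not in PATTERNS:
        raise ValueError(f"unknown pattern {pattern!r}")
    pat = PATTERNS[pattern]
    anchor_type: str = pat["anchor"]
    companions: tuple[str, ...] = pat["companions"]
    window = 1 + len(companions)
    type_maps = _type_positions(genes)
    lengths = _replicon_lengths(genes)
    n_anchor = 0
    n_hit = 0
    for key, tmap in type_maps.items():
        length = lengths[key]
        for pos, tstr in tmap.items():
            if tstr != anchor_type:
                continue
            n_anchor += 1
            if _anchor_matches(tmap, pos, companions, window, length):
                n_hit += 1
    if n_anchor == 0:
        return None, 0
    return n_hit / n_anchor, n_anchor


def _anchor_matches(
    tmap: Mapping[int, str],
    pos: int,
    companions: tuple[str, ...],
    window: int,
    length: int,
) -> bool:
    need = Counter(companions)
    for start in range(pos - window + 1, pos + 1):
        if start < 1 or start + window - 1 > length:
            continue
        got: Counter[str] = Counter()
        ok = True
        for p in range(start, start + window):
            if p == pos:
                continue
            t = tmap.get(p)
            if t is None:
                ok = False
                break
            got[t] += 1
        if ok and got == need:
            return True
    return False


def odds_ratio(observed: float | None, expected: float) -> float | None:
    """Observed/expected neighboring frequency; None when undefined."""
    if observed is None:
        return None
    if expected == 0:
        return None
    return observed / expected


def neighborhood_stat(
    genes: Sequence[GeneRecord], pattern: str, n_counts: Mapping[str, int], P: int
) -> NeighborhoodStat:
    """Convenience: observed, expected and odds ratio for one pattern."""
    obs, n_anchor = observed_frequency(genes, pattern)
    exp = expected_frequency(pattern, n_counts, P)
    return NeighborhoodStat(
        pattern=pattern,
        observed=obs,
        expected=exp,
        odds_ratio=odds_ratio(obs, exp),
        anchor_count=n_anchor,
    )


def permutation_null(
    genes: Sequence[GeneRecord],
    pattern: str,
    n_permutations: int = 1000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Empirical neighboring frequency under random gene order.

    Gene contents are preserved and positions permuted uniformly within
    each replicon; the observed frequency is recomputed per permutation.
    Returns (mean, standard error of the mean). Permutations with no
    anchors contribute nothing (cannot occur if the original has anchors,
    since shuffling preserves contents).
    """
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    if pattern not in PATTERNS:
        raise ValueError(f"unknown pattern {pattern!r}")
    pat = PATTERNS[pattern]
    anchor_type: str = pat["anchor"]
    companions: tuple[str, ...] = pat["companions"]
    window = 1 + len(companions)
    rng = np.random.default_rng(seed)
    type_maps = _type_positions(genes)
    lengths = _replicon_lengths(genes)
    # Under a uniform permutation of all genes the IST genes land on a
    # uniform random set of positions, so only they need to be re-placed.
    replicon_types = {
        key: [tmap[p] for p in sorted(tmap)] for key, tmap in type_maps.items()
    }
    fractions = []
    for _ in range(n_permutations):
        n_anchor = 0
        n_hit = 0
        for key, types in replicon_types.items():
            length = lengths[key]
            if not types:
                continue
            spots = rng.choice(length, size=len(types), replace=False) + 1
            order = rng.permutation(len(types))
            tmap = {int(spots[i]): types[order[i]] for i in range(len(types))}
            for pos, tstr in tmap.items():
                if tstr != anchor_type:
                    continue
                n_anchor += 1
                if _anchor_matches(tmap, pos, companions, window, length):
                    n_hit += 1
        if n_anchor > 0:
            fractions.append(n_hit / n_anchor)
    arr = np.asarray(fractions, dtype=float)
    if arr.size == 0:
        return 0.0, 0.0
    se = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0
    return float(arr.mean()), se
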