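"""Synthetic genomes, fusion series, and alignments with known ground truth.

Every analysis stage in this package has a parameter-recovery test built on
these generators, which emulate the features of annotated proteomes the
census pipeline consumes:

* genomes of 500–10,000 genes on a single linear replicon, with a chosen
  number of proteins of each IST architecture type placed uniformly at
  random, plus planted operons (blocks of consecutive IST genes, optionally
  containing one non-IST gap gene) at controllable enrichment;
* per-organism fusion series where the percentage of fused domains follows
  a linear trend in the total domain count, with Gaussian noise, truncated
  to the physical range [0, 100];
* toy multiple alignments with a known consensus and a controllable
  fraction of sequences lacking the conserved motif residue.

One global integer seed drives independent named RNG streams (genome,
fusion, alignment), so identical seed + config → byte-identical output.
The generators emulate gene order and domain content only — not real
protein sequences, inter-organism phylogenetic correlation, or horizontal
transfer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .domain_architecture import parse_architecture
from .io_formats import GeneRecord, AlignmentBlock

_STREAMS = {"genome": 0, "fusion": 1, "alignment": 2}


def stream_rng(seed: int, stream: str, index: int = 0) -> np.random.Generator:
    """Independent RNG for a named stage, derived from the global seed."""
    return np.random.default_rng([seed, _STREAMS[stream], index])


class ConfigError(ValueError):
    """A simulation configuration is internally inconsistent."""


@dataclass
class OperonSpec:
    """A planted gene cluster: label like "HK-RR", how many copies, and the
    probability that a copy carries one non-IST gap gene strictly inside."""

    label: str
    count: int
    gap_probability: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gap_probability <= 1.0:
            raise ConfigError("gap_probability must lie in [0, 1]")
        if self.count < 0:
            raise ConfigError("operon count must be non-negative")
        self.member_types = tuple(self.label.split("-"))
        if len(self.member_types) < 2:
            raise ConfigError("an operon needs at least two member genes")


@dataclass
class SimulationConfig:
    """Everything :func:`simulate_genome` needs.

    ``protein_type_counts`` gives the TOTAL number of proteins of each
    architecture type in the genome; operon members are drawn from those
    totals, the remainder are placed uniformly at random as background.
    """

    n_organisms: int = 1
    genes_per_organism: int = 2000
    protein_type_counts: dict[str, int] = field(default_factory=dict)
    operons: list[OperonSpec] = field(default_factory=list)
    phylogeny: int = 1  # 1 = prokaryote, 2 = eukaryote
    fusion_intercept: float = 14.0
    fusion_slope: float = 0.31
    fusion_noise_sd: float = 3.0
    fusion_totals_range: tuple[int, int] = (5, 100)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genes_per_organism < 50:
            raise ConfigError("genes_per_organism must be at least 50")
        if self.fusion_noise_sd < 0:
            raise ConfigError("noise sd must be non-negative")
        if self.phylogeny not in (1, 2):
            raise ConfigError("phylogeny must be 1 (prokaryote) or 2 (eukaryote)")
        for t, n in self.protein_type_counts.items():
            parse_architecture(t)  # validates the type string
            if n < 0:
                raise ConfigError(f"negative count for type {t!r}")


@dataclass
class PlantedCluster:
    """Ground truth for one planted operon."""

    organism_id: str
    replicon_id: str
    member_positions: tuple[int, ...]
    gap_positions: tuple[int, ...]
    label: str


@dataclass
class GroundTruth:
    planted_clusters: list[PlantedCluster]
    type_counts: dict[str, int]


def _background_counts(config: SimulationConfig) -> dict[str, int]:
    """Per-type singles left over after operon members take their share."""
    used: dict[str, int] = {}
    for op in config.operons:
        for t in op.member_types:
            used[t] = used.get(t, 0) + op.count
    background = dict(config.protein_type_counts)
    for t, n in used.items():
        background[t] = background.get(t, 0) - n
        if background[t] < 0:
            raise ConfigError(
                f"operons demand more {t!r} proteins than the configured total"
            )
    return {t: n for t, n in background.items() if n > 0}


def simulate_genome(
    config: SimulationConfig, organism_id: str = "org1", organism_index: int = 0
) -> tuple[list[GeneRecord], GroundTruth]:
    """Generate one organism's gene table plus the planted ground truth.

    Operon blocks (with gap genes already inserted) and background IST
    singles are shuffled uniformly among the non-IST filler genes, so with
    zero operons the gene order is fully random — the null the closed-form
    expectations assume.
    """
    rng = stream_rng(config.seed, "genome", organism_index)
    P = config.genes_per_organism
    background = _background_counts(config)

    # Build items: each item is a list of domain-tuples (None = filler gene).
    blocks: list[tuple[list[tuple[str, ...] | None], OperonSpec | None]] = []
    for op in config.operons:
        for _ in range(op.count):
            members: list[tuple[str, ...] | None] = [
                parse_architecture(t) for t in op.member_types
            ]
            if op.gap_probability > 0 and rng.random() < op.gap_probability:
                slot = int(rng.integers(1, len(members)))
                members.insert(slot, None)
            blocks.append((members, op))
    singles: list[tuple[str, ...]] = []
    for t, n in background.items():
        singles.extend([parse_architecture(t)] * n)

    n_block_genes = sum(len(b) for b, _ in blocks)
    n_used = n_block_genes + len(singles)
    if n_used > P:
        raise ConfigError(
            f"requested genes ({n_used}) exceed genes_per_organism ({P})"
        )

    items: list[object] = list(range(len(blocks)))  # block indices
    items += [("single", d) for d in singles]
    items += [None] * (P - n_used)  # gap genes are already inside the blocks
    rng.shuffle(items)

    genes: list[GeneRecord] = []
    planted: list[PlantedCluster] = []
    pos = 1
    replicon = "chr"
    for item in items:
        if item is None:
            genes.append(_gene(organism_id, replicon, pos, ()))
            pos += 1
        elif isinstance(item, tuple) and item[0] == "single":
            genes.append(_gene(organism_id, replicon, pos, item[1]))
            pos += 1
        else:
            members, op = blocks[item]
            member_positions = []
            gap_positions = []
            for dom in members:
                if dom is None:
                    gap_positions.append(pos)
                    genes.append(_gene(organism_id, replicon, pos, ()))
                else:
                    member_positions.append(pos)
                    genes.append(_gene(organism_id, replicon, pos, dom))
                pos += 1
            planted.append(
                PlantedCluster(
                    organism_id=organism_id,
                    replicon_id=replicon,
                    member_positions=tuple(member_positions),
                    gap_positions=tuple(gap_positions),
                    label=op.label,
                )
            )
    truth = GroundTruth(
        planted_clusters=planted, type_counts=dict(config.protein_type_counts)
    )
    return genes, truth


def _gene(
    org: str, rep: str, pos: int, domains: tuple[str, ...]
) -> GeneRecord:
    return GeneRecord(
        organism_id=org,
        replicon_id=rep,
        position=pos,
        gene_id=f"{org}_g{pos}",
        annotation="ist protein" if domains else "filler",
        domains=domains,
    )


def simulate_fusion_series(config: SimulationConfig) -> pd.DataFrame:
    """Per-organism fusion table: total domain count, % fused, phylogeny.

    ``pct_fused = intercept + slope × total + N(0, sd)``, truncated to the
    physical range [0, 100] (a known bias at extreme parameters).
    """
    rng = stream_rng(config.seed, "fusion")
    lo, hi = config.fusion_totals_range
    totals = rng.integers(lo, hi + 1, size=config.n_organisms)
    noise = (
        rng.normal(0.0, config.fusion_noise_sd, size=config.n_organisms)
        if config.fusion_noise_sd > 0
        else np.zeros(config.n_organisms)
    )
    pct = config.fusion_intercept + config.fusion_slope * totals + noise
    pct = np.clip(pct, 0.0, 100.0)
    return pd.DataFrame(
        {
            "organism_id": [f"org{i+1}" for i in range(config.n_organisms)],
            "total_domains": totals,
            "pct_fused": pct,
            "phylogeny": config.phylogeny,
        }
    )


def simulate_alignment(
    n_rows: int,
    length: int,
    consensus_string: str,
    motif_column: int,
    motif_residue: str,
    corruption_rate: float,
    seed: int = 0,
) -> AlignmentBlock:
    """Toy alignment whose majority residue per column is ``consensus_string``.

    Exactly ``round(corruption_rate × n_rows)`` rows lose the motif residue
    at ``motif_column`` (0-based), replaced by 'Y' — alphabetically after
    both H and D, so consensus recovery still holds for rates ≤ 0.5.
    """
    if not 0.0 <= corruption_rate <= 1.0:
        raise ConfigError("corruption_rate must lie in [0, 1]")
    if len(consensus_string) != length:
        raise ConfigError("consensus_string length must equal alignment length")
    if not 0 <= motif_column < length:
        raise ConfigError("motif_column must fall inside the alignment")
    if consensus_string[motif_column] != motif_residue:
        raise ConfigError("consensus must carry the motif residue at its column")
    rng = stream_rng(seed, "alignment")
    n_corrupt = int(round(corruption_rate * n_rows))
    corrupt_rows = set(rng.choice(n_rows, size=n_corrupt, replace=False).tolist())
    rows = []
    for r in range(n_rows):
        row = list(consensus_string)
        if r in corrupt_rows:
            row[motif_column] = "Y"
        rows.append("".join(row))
    return AlignmentBlock(
        ids=tuple(f"seq{r+1}" for r in range(n_rows)), rows=tuple(rows)
    )


def simulate_organism_set(
    config: SimulationConfig,
) -> tuple[list[list[GeneRecord]], list[GroundTruth]]:
    """Generate ``config.n_organisms`` genomes from independent sub-streams."""
    genomes = []
    truths = []
    for i in range(config.n_organisms):
        genes, truth = simulate_genome(config, organism_id=f"org{i+1}", organism_index=i)
        genomes.append(genes)
        truths.append(truth)
    return genomes, truths
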