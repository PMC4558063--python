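"""Fusion prevalence and the linear models of the comparative analysis.

A "fused" domain is an HK/RR/HPt instance residing in a protein that
carries two or more IST domains (so each HK inside an HKRR hybrid counts as
one fused HK instance). Two ordinary-least-squares models are fitted:

* ``pct_fused ~ total`` — percentage of fused domains of a type against the
  total count of that type in the genome; a positive slope indicates
  selection in favor of fusion events, a zero slope is the neutral
  expectation (fusion count proportional to genome size).
* ``n_ist ~ P + phylogeny`` — total IST-domain count against proteome size
  and a phylogeny covariate coded literally 1 (prokaryote) / 2 (eukaryote).
  With this coding the intercept is not at zero covariates. Per-coefficient
  significance comes from single-coefficient ANOVA F-tests (identical to
  the squared-t tests of classical OLS inference; no robust errors).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .census import OrganismCensus
from .domain_architecture import parse_architecture


@dataclass(frozen=True)
class FusionFit:
    """OLS fit of % fused domains vs total domain count for one type."""

    domain_type: str
    intercept: float
    slope: float
    slope_p_value: float
    slope_ci: tuple[float, float]
    n_organisms: int
    r_squared: float
    adj_r_squared: float


@dataclass(frozen=True)
class ISTModelFit:
    """OLS fit of IST-domain count vs proteome size and phylogeny."""

    intercept: float
    alpha1: float  # coefficient on total proteins
    alpha2: float  # coefficient on phylogeny (1 prokaryote / 2 eukaryote)
    alpha1_p_value: float
    alpha2_p_value: float
    alpha1_ci: tuple[float, float]
    alpha2_ci: tuple[float, float]
    residual_variance: float
    n_organisms: int
    r_squared: float
    adj_r_squared: float


def fused_percentage(census: OrganismCensus, domain_type: str) -> float | None:
    """% of this organism's domain instances of a type that sit in multi-domain
    proteins; None when the organism has no instances of the type."""
    total = 0
    fused = 0
    for type_string, n in census.type_counts.items():
        domains = parse_architecture(type_string)
        k = domains.count(domain_type)
        if k == 0:
            continue
        total += k * n
        if len(domains) >= 2:
            fused += k * n
    if total == 0:
        return None
    return 100.0 * fused / total


def fusion_table(
    censuses: Iterable[OrganismCensus], domain_type: str
) -> pd.DataFrame:
    """Per-organism (total instances, % fused) table for one domain type.

    Organisms with zero instances of the type are dropped (undefined %).
    """
    rows = []
    for c in censuses:
        pct = fused_percentage(c, domain_type)
        if pct is None:
            continue
        rows.append(
            {
                "organism_id": c.organism_id,
                "total_domains": c.domain_instance_counts()[domain_type],
                "pct_fused": pct,
                "phylogeny": c.phylogeny,
            }
        )
    return pd.DataFrame(
        rows, columns=["organism_id", "total_domains", "pct_fused", "phylogeny"]
    )


def fit_fusion_model(
    table: pd.DataFrame, domain_type: str = "",
    x: str = "total_domains", y: str = "pct_fused",
) -> FusionFit:
    """OLS of % fused vs total count, with a two-sided slope t-test."""
    df = table.dropna(subset=[x, y])
    if len(df) < 3:
        raise ValueError("need at least 3 organisms with a defined percentage")
    if df[x].nunique() < 2:
        raise ValueError("all x values identical: slope inestimable")
    X = sm.add_constant(np.asarray(df[x], dtype=float))
    model = sm.OLS(np.asarray(df[y], dtype=float), X).fit()
    ci = model.conf_int()
    p_slope = float(model.pvalues[1])
    if np.isnan(p_slope):
        # zero residual variance and zero slope: the t statistic is 0/0;
        # there is no evidence against the null, report p = 1
        p_slope = 1.0
    return FusionFit(
        domain_type=domain_type,
        intercept=float(model.params[0]),
        slope=float(model.params[1]),
        slope_p_value=p_slope,
        slope_ci=(float(ci[1][0]), float(ci[1][1])),
        n_organisms=len(df),
        r_squared=float(model.rsquared),
        adj_r_squared=float(model.rsquared_adj),
    )


def fit_ist_model(table: pd.DataFrame) -> ISTModelFit:
    """OLS of IST-domain count on proteome size and the 1/2 phylogeny code.

    ``table`` needs columns n_ist, total_proteins, phylogeny, with both
    phylogeny values present so the phylogeny coefficient is estimable.
    """
    df = table.dropna(subset=["n_ist", "total_proteins", "phylogeny"])
    if len(df) < 4:
        raise ValueError("need at least 4 organisms")
    if df["phylogeny"].nunique() < 2:
        raise ValueError(
            "phylogeny coefficient inestimable with a single phylogeny value; "
            "use fit_ist_model_stratified"
        )
    X = sm.add_constant(
        np.column_stack(
            [
                np.asarray(df["total_proteins"], dtype=float),
                np.asarray(df["phylogeny"], dtype=float),
            ]
        )
    )
    model = sm.OLS(np.asarray(df["n_ist"], dtype=float), X).fit()
    # Per-coefficient ANOVA: F-test of the single restriction beta_j = 0.
    p_alpha1 = float(model.f_test(np.array([[0.0, 1.0, 0.0]])).pvalue)
    p_alpha2 = float(model.f_test(np.array([[0.0, 0.0, 1.0]])).pvalue)
    ci = model.conf_int()
    return ISTModelFit(
        intercept=float(model.params[0]),
        alpha1=float(model.params[1]),
        alpha2=float(model.params[2]),
        alpha1_p_value=p_alpha1,
        alpha2_p_value=p_alpha2,
        alpha1_ci=(float(ci[1][0]), float(ci[1][1])),
        alpha2_ci=(float(ci[2][0]), float(ci[2][1])),
        residual_variance=float(model.mse_resid),
        n_organisms=len(df),
        r_squared=float(model.rsquared),
        adj_r_squared=float(model.rsquared_adj),
    )


def fit_ist_model_stratified(table: pd.DataFrame) -> dict[int, FusionFit]:
    """Separate n_ist ~ total_proteins fits per phylogeny stratum.

    Returns stratum (1 or 2) → fit; mirrors splitting the data when the
    phylogeny covariate proves significant.
    """
    out: dict[int, FusionFit] = {}
    for value, sub in table.groupby("phylogeny"):
        if len(sub) < 3 or sub["total_proteins"].nunique() < 2:
            continue
        out[int(value)] = fit_fusion_model(
            sub, domain_type=f"phylogeny={int(value)}",
            x="total_proteins", y="n_ist",
        )
    return out
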