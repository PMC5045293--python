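"""Transmitted rare-variant burden: gene-length-weighted binomial tests,
Q-Q construction, case-control Fisher comparison, and combination with the
de novo evidence.

The model: conditional on the cohort-wide total of rare damaging alleles,
each allele falls in a gene with probability equal to that gene's share of
the exome's coding length.  A gene's burden p-value is the upper-tail exact
binomial probability of its observed allele count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .denovo import BurdenResult, fishers_method
from .errors import ValidationError


@dataclass
class CohortAlleleCounts:
    """Rare allele tallies for a proband cohort: totals and per-gene counts
    of LOF and damaging (LOF + D-mis) alleles."""

    total_lof: int
    total_damaging: int
    per_gene: dict[str, dict[str, int]] = field(default_factory=dict)
    n_probands: int = 0

    def __post_init__(self):
        lof = sum(g.get("lof", 0) for g in self.per_gene.values())
        dam = sum(g.get("damaging", 0) for g in self.per_gene.values())
        if lof > self.total_lof or dam > self.total_damaging:
            raise ValidationError("per-gene counts exceed cohort totals")


def expected_gene_count(
    gene: str, lengths: Mapping[str, int], total_alleles: int
) -> float:
    """Expected allele count in ``gene``: the gene's fraction of total coding
    length times the cohort-wide allele total."""
    if total_alleles < 0:
        raise ValidationError("total_alleles must be >= 0")
    if gene not in lengths:
        raise ValidationError(f"gene {gene!r} not in length table")
    denom = sum(lengths.values())
    return total_alleles * lengths[gene] / denom


def binomial_burden_test(
    observed: int, total_alleles: int, gene_fraction: float, label: str = ""
) -> BurdenResult:
    """Upper-tail exact binomial test of a gene's rare-allele count.

    ``gene_fraction`` is the gene's share of exome coding length (the
    per-allele hit probability); expected = total_alleles * gene_fraction.
    """
    if not 0.0 <= gene_fraction <= 1.0:
        raise ValidationError("gene_fraction must be in [0,1]")
    if observed < 0 or total_alleles < 0:
        raise ValidationError("counts must be non-negative")
    if observed > total_alleles:
        raise ValidationError("observed exceeds the allele total")
    expected = total_alleles * gene_fraction
    if observed == 0:
        return BurdenResult(label, 0, expected, 0.0, 1.0, "upper")
    p = float(stats.binom.sf(observed - 1, total_alleles, gene_fraction))
    enrichment = observed / expected if expected > 0 else float("inf")
    return BurdenResult(label, observed, expected, enrichment, p, "upper")


def qq_points(per_gene_p: Mapping[str, float]) -> pd.DataFrame:
    """Observed vs expected -log10 p for a Q-Q plot.

    Observed p-values are sorted ascending; the i-th (1-based) expected
    quantile is (i - 0.5) / m.  Returns a DataFrame with columns
    ``gene, p, expected_neglog10, observed_neglog10``, strongest gene first.
    """
    if not per_gene_p:
        raise ValidationError("need at least one gene")
    items = sorted(per_gene_p.items(), key=lambda kv: kv[1])
    m = len(items)
    genes, pvals = zip(*items)
    expected = (np.arange(1, m + 1) - 0.5) / m
    return pd.DataFrame(
        {
            "gene": genes,
            "p": pvals,
            "expected_neglog10": -np.log10(expected),
            "observed_neglog10": -np.log10(np.asarray(pvals, dtype=float)),
        }
    )


def plot_qq(per_gene_p: Mapping[str, float], ax=None, label_top: int = 1):
    """Render the Q-Q plot (requires matplotlib; not imported elsewhere)."""
    import matplotlib.pyplot as plt

    df = qq_points(per_gene_p)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(df["expected_neglog10"], df["observed_neglog10"], s=12, color="k")
    lim = max(df["expected_neglog10"].max(), df["observed_neglog10"].max()) * 1.05
    ax.plot([0, lim], [0, lim], color="red", lw=1)
    for _, row in df.head(label_top).iterrows():
        ax.annotate(row["gene"], (row["expected_neglog10"], row["observed_neglog10"]))
    ax.set_xlabel(r"expected $-\log_{10} p$")
    ax.set_ylabel(r"observed $-\log_{10} p$")
    return ax


def case_control_fisher(
    case_carriers: int, case_n: int, control_carriers: int, control_n: int
) -> dict:
    """Two-sided Fisher exact comparison of carrier prevalence in cases vs
    controls.

    Returns ``{"odds_ratio", "p", "haldane"}``; the odds ratio is the sample
    cross-product, with the Haldane–Anscombe 0.5 continuity correction
    applied (and flagged) when any cell is zero.
    """
    for val, n in ((case_carriers, case_n), (control_carriers, control_n)):
        if not 0 <= val <= n:
            raise ValidationError("carriers must lie in [0, n] on each side")
    table = np.array(
        [
            [case_carriers, case_n - case_carriers],
            [control_carriers, control_n - control_carriers],
        ]
    )
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    haldane = bool((table == 0).any())
    t = table + 0.5 if haldane else table
    odds_ratio = float(t[0, 0] * t[1, 1] / (t[0, 1] * t[1, 0]))
    return {"odds_ratio": odds_ratio, "p": p, "haldane": haldane}


def combine_denovo_transmitted(p_denovo: float, p_transmitted: float) -> float:
    """Fisher's-method combination (df = 4) of the de novo and transmitted
    burden p-values for one gene."""
    return fishers_method([p_denovo, p_transmitted])
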