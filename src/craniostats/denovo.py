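"""De novo mutation burden statistics.

The number of de novo mutations of a given class observed across a trio
cohort is compared with a Poisson expectation derived from per-gene mutation
rates.  Class-level tests (all mutations, synonymous, missense, D-mis, LOF...)
use cohort-wide expected counts; gene-level tests use per-gene lambdas;
independent per-class p-values are combined by Fisher's method; and a
permutation test asks how often any single gene would be hit more than once
when a fixed number of de novo events is thrown at the genome in proportion
to each gene's mutability.

Tail convention.  For enriched classes the p-value is the inclusive upper
tail P(X >= observed).  For depleted classes the reported lower tail is the
complement of that upper tail, P(X < observed) = P(X <= observed - 1) — so
the two tails of any test partition unit probability and never double-count
the observed point mass.  Pass ``lower_includes_observed=True`` for the
inclusive lower tail P(X <= observed) instead.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError
from .variants import MutationRateRow


@dataclass(frozen=True)
class BurdenResult:
    """Observed/expected comparison for one mutation class or gene."""

    label: str
    observed: int
    expected: float
    enrichment: float
    p: float
    tail: str  # "upper" or "lower"

    def __post_init__(self):
        if self.tail not in ("upper", "lower"):
            raise ValidationError(f"tail must be 'upper' or 'lower', got {self.tail!r}")


def class_poisson_test(
    observed: int,
    expected: float,
    label: str = "",
    lower_includes_observed: bool = False,
) -> BurdenResult:
    """Poisson test of an observed de novo count against its expectation.

    Enriched (observed > expected): p = P(X >= observed).
    Depleted: p = P(X < observed) by default (the complement of the upper
    tail), or P(X <= observed) with ``lower_includes_observed=True``.
    """
    if observed < 0 or expected < 0:
        raise ValidationError("observed and expected must be non-negative")
    if expected == 0:
        if observed == 0:
            return BurdenResult(label, 0, 0.0, 1.0, 1.0, "lower")
        raise ValidationError("expected = 0 with observed > 0: enrichment undefined")
    enrichment = observed / expected
    if observed > expected:
        p = float(stats.poisson.sf(observed - 1, expected))
        tail = "upper"
    else:
        k = observed if lower_includes_observed else observed - 1
        p = float(stats.poisson.cdf(k, expected))
        if observed == 0:
            # the most extreme attainable depletion still has its point mass:
            # never report p = 0 for a possible outcome
            p = float(stats.poisson.pmf(0, expected))
        tail = "lower"
    return BurdenResult(label, observed, expected, enrichment, p, tail)


def gene_poisson_test(
    rate: MutationRateRow,
    observed_lof: int = 0,
    observed_mis: int = 0,
    observed_syn: int | None = None,
) -> dict[str, BurdenResult]:
    """Per-class upper-tail Poisson tests for one gene (or gene set).

    Returns a dict keyed by class ("LOF", "missense", optionally
    "synonymous").  A class observed > 0 with lambda = 0 is reported with
    infinite enrichment and p = 0.0 (boundary), with a warning.
    """
    observed = {"LOF": (observed_lof, rate.lambda_lof), "missense": (observed_mis, rate.lambda_mis)}
    if observed_syn is not None:
        observed["synonymous"] = (observed_syn, rate.lambda_syn)
    out: dict[str, BurdenResult] = {}
    for cls, (obs, lam) in observed.items():
        if obs < 0 or lam < 0:
            raise ValidationError("counts and rates must be non-negative")
        label = f"{rate.gene}:{cls}"
        if lam == 0 and obs > 0:
            warnings.warn(
                f"{label}: observed {obs} with zero expected rate; "
                "enrichment is unbounded",
                stacklevel=2,
            )
            out[cls] = BurdenResult(label, obs, 0.0, math.inf, 0.0, "upper")
            continue
        if obs == 0:
            out[cls] = BurdenResult(label, 0, lam, 0.0, 1.0, "upper")
            continue
        p = float(stats.poisson.sf(obs - 1, lam))
        out[cls] = BurdenResult(label, obs, lam, obs / lam, p, "upper")
    return out


def fishers_method(pvals: Sequence[float]) -> float:
    """Combine independent p-values: chi2 = -2 sum(ln p) on 2k df."""
    if len(pvals) == 0:
        raise ValidationError("need at least one p-value")
    for p in pvals:
        if not 0 < p <= 1:
            raise ValidationError(
                f"p-values must lie in (0,1]; got {p!r} (use boundary-safe tails)"
            )
    chi2 = -2.0 * sum(math.log(p) for p in pvals)
    return float(stats.chi2.sf(chi2, 2 * len(pvals)))


def multihit_permutation(
    n_hits: int,
    gene_probs: Mapping[str, float],
    n_iter: int = 1_000_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Probability that any gene receives >= 2 of ``n_hits`` de novo events.

    ``n_hits`` events are thrown at genes in proportion to ``gene_probs``
    (normalized internally), ``n_iter`` times; the returned p is the fraction
    of iterations in which some gene is hit at least twice.  Deterministic
    for a fixed ``seed``.
    """
    if n_iter < 1:
        raise ValidationError("n_iter must be >= 1")
    if n_hits < 0:
        raise ValidationError("n_hits must be >= 0")
    if n_hits < 2:
        warnings.warn("fewer than 2 hits: no gene can be multiply hit", stacklevel=2)
        return 0.0
    probs = np.asarray(list(gene_probs.values()), dtype=float)
    if np.any(probs < 0) or probs.sum() <= 0:
        raise ValidationError("gene probabilities must be non-negative with positive sum")
    probs = probs / probs.sum()
    if rng is None:
        rng = np.random.default_rng(seed)
    n_genes = probs.size
    hits_with_multi = 0
    chunk = max(1, min(n_iter, 200_000 // max(n_hits, 1) * 10))
    done = 0
    while done < n_iter:
        b = min(chunk, n_iter - done)
        draws = rng.choice(n_genes, size=(b, n_hits), p=probs)
        draws.sort(axis=1)
        multi = (np.diff(draws, axis=1) == 0).any(axis=1)
        hits_with_multi += int(multi.sum())
        done += b
    return hits_with_multi / n_iter


def attributable_fraction(observed_pa: int, expected_pa: float, n_trios: int) -> float:
    """Fraction of probands whose disease is attributed to de novo mutation:
    the excess of probands with protein-altering de novo mutations over
    chance expectation, divided by the cohort size.  Clipped below at 0."""
    if n_trios <= 0:
        raise ValidationError("n_trios must be positive")
    if observed_pa < 0 or expected_pa < 0:
        raise ValidationError("counts must be non-negative")
    return max(0.0, (observed_pa - expected_pa) / n_trios)


def per_offspring_rate(
    n_mutations: int, n_trios: int, callable_bp: int | None = None
) -> dict[str, float | None]:
    """Mean de novo mutations per offspring, and per base pair per haploid
    genome copy when the callable target size is given."""
    if n_trios <= 0:
        raise ValidationError("n_trios must be positive")
    if n_mutations < 0:
        raise ValidationError("n_mutations must be non-negative")
    per_offspring = n_mutations / n_trios
    per_bp = None
    if callable_bp is not None:
        if callable_bp <= 0:
            raise ValidationError("callable_bp must be positive")
        per_bp = n_mutations / (n_trios * 2 * callable_bp)
    return {"per_offspring": per_offspring, "per_bp": per_bp}
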