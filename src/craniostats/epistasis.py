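"""Exact statistics for rare-variant x common-SNP epistasis.

Members of kindreds segregating a rare damaging SMAD6 variant are classed by
two-locus genotype — carrier with risk allele (S+B+), carrier without
(S+B-), risk allele only (S-B+) — and cross-tabulated against affection.
Departure from independence is assessed with the Freeman–Halton extension of
Fisher's exact test (full enumeration of tables with the observed margins);
transmission distortion of the SNP to affected offspring with a 1-df
chi-square TDT; and carrier penetrance estimated with and without the
ascertained probands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy.special import gammaln

from scipy import stats

from .errors import EnumerationBoundError, ValidationError
from .pedigree import PedigreeGraph, Smad6Genotype

#: probability-ordering tie tolerance for "as or more extreme" (log scale)
_TIE_EPS = 1e-12

#: full-enumeration bounds; larger problems use the Monte-Carlo fallback
ENUMERATION_MAX_N = 60
ENUMERATION_MAX_CELLS = 8


CLASS_LABELS = ("S+B+", "S+B-", "S-B+")


@dataclass
class TwoLocusClassTable:
    """Affected/unaffected counts for the three informative two-locus
    classes.  Individuals carrying neither allele are outside the table (as
    is conventional for carrier-class layouts); skipped individuals are
    tallied, never silently dropped."""

    counts: np.ndarray  # shape (3, 2): rows CLASS_LABELS, cols (affected, unaffected)
    n_missing_genotype: int = 0
    n_neither_allele: int = 0
    n_unknown_phenotype: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (3, 2):
            raise ValidationError("class table must be 3x2")
        if (self.counts < 0).any():
            raise ValidationError("counts must be non-negative")

    @classmethod
    def from_counts(
        cls,
        both: tuple[int, int],
        smad6_only: tuple[int, int],
        bmp2_only: tuple[int, int],
    ) -> "TwoLocusClassTable":
        return cls(np.array([both, smad6_only, bmp2_only]))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.counts, index=list(CLASS_LABELS), columns=["affected", "unaffected"]
        )


# ---------------------------------------------------------------------------
# Freeman–Halton exact test


def _log_table_prob(table: np.ndarray, logZ: float) -> float:
    """log multivariate hypergeometric probability of a margin-fixed table;
    ``logZ`` = log(prod R_i! prod C_j! / N!)."""
    return logZ - gammaln(table + 1).sum()


def _margin_tables(rows: Sequence[int], cols: Sequence[int]) -> Iterator[np.ndarray]:
    """Yield every non-negative integer table with the given margins."""
    r, c = len(rows), len(cols)
    table = np.zeros((r, c), dtype=int)

    def fill_row(i: int, remaining_cols: list[int]) -> Iterator[np.ndarray]:
        if i == r - 1:
            # last row is forced
            last = remaining_cols
            if all(v >= 0 for v in last) and sum(last) == rows[i]:
                table[i] = last
                yield table
            return
        # enumerate compositions of rows[i] bounded by remaining_cols
        def comp(j: int, left: int) -> Iterator[None]:
            if j == c - 1:
                if left <= remaining_cols[j]:
                    table[i, j] = left
                    yield None
                return
            for v in range(min(left, remaining_cols[j]) + 1):
                table[i, j] = v
                yield from comp(j + 1, left - v)

        for _ in comp(0, rows[i]):
            nxt = [remaining_cols[j] - table[i, j] for j in range(c)]
            yield from fill_row(i + 1, nxt)

    yield from fill_row(0, list(cols))


def _validate_contingency(table) -> np.ndarray:
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValidationError("need an r x c table with r, c >= 2")
    if (t < 0).any():
        raise ValidationError("counts must be non-negative")
    if t.sum() == 0:
        raise ValidationError("table total must be positive")
    return t


def freeman_halton_exact(table) -> float:
    """Two-sided exact p for an r x c contingency table (Freeman–Halton).

    Enumerates every table with the observed margins and sums the
    multivariate-hypergeometric probabilities of those no more probable than
    the observed table (probability ordering, with a 1e-12 relative tie
    tolerance).  On a 2x2 table this reduces to Fisher's exact test.

    Tables with total > 60 or more than 8 cells raise
    :class:`EnumerationBoundError`; use :func:`freeman_halton_mc`.
    """
    t = _validate_contingency(table)
    n = int(t.sum())
    if n > ENUMERATION_MAX_N or t.size > ENUMERATION_MAX_CELLS:
        raise EnumerationBoundError(
            f"table total {n} / {t.size} cells exceeds the exact enumeration "
            f"bound (N <= {ENUMERATION_MAX_N}, cells <= {ENUMERATION_MAX_CELLS}); "
            "use freeman_halton_mc for a seeded Monte-Carlo estimate"
        )
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    logZ = float(gammaln(rows + 1).sum() + gammaln(cols + 1).sum() - gammaln(n + 1))
    lp_obs = _log_table_prob(t, logZ)
    total = 0.0
    for cand in _margin_tables(rows.tolist(), cols.tolist()):
        lp = _log_table_prob(cand, logZ)
        if lp <= lp_obs + _TIE_EPS:
            total += math.exp(lp)
    return min(total, 1.0)


def freeman_halton_mc(
    table, n_iter: int = 100_000, seed: int | None = None
) -> float:
    """Seeded Monte-Carlo estimate of the Freeman–Halton p-value for tables
    beyond the exact enumeration bound.

    Random margin-fixed tables are generated by permutation (shuffling the
    column labels of the N underlying observations); p is estimated with the
    standard +1 correction so it is never exactly 0.
    """
    t = _validate_contingency(table)
    n = int(t.sum())
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    logZ = float(gammaln(rows + 1).sum() + gammaln(cols + 1).sum() - gammaln(n + 1))
    lp_obs = _log_table_prob(t, logZ)
    rng = np.random.default_rng(seed)
    row_of = np.repeat(np.arange(len(rows)), rows)
    col_of = np.repeat(np.arange(len(cols)), cols)
    hits = 0
    for _ in range(n_iter):
        perm = rng.permutation(col_of)
        cand = np.zeros_like(t)
        np.add.at(cand, (row_of, perm), 1)
        if _log_table_prob(cand, logZ) <= lp_obs + _TIE_EPS:
            hits += 1
    return (hits + 1) / (n_iter + 1)


# ---------------------------------------------------------------------------
# Transmission disequilibrium


@dataclass(frozen=True)
class TransmissionCounts:
    """Risk-allele transmissions from heterozygous parents to affected
    offspring."""

    transmitted: int
    untransmitted: int

    def __post_init__(self):
        if self.transmitted < 0 or self.untransmitted < 0:
            raise ValidationError("transmission counts must be non-negative")


def count_transmissions(pedigrees: Iterable[PedigreeGraph]) -> TransmissionCounts:
    """Tally risk-allele transmissions from heterozygous parents to affected
    offspring across kindreds.

    For each affected, genotyped child and each heterozygous parent, the
    transmitted allele is inferred when the other parent's contribution is
    determinate (other parent homozygous, or the child's dose pins both
    alleles).  Ambiguous het x het / dose-1 configurations are skipped, as
    is standard.
    """
    t = u = 0
    for ped in pedigrees:
        index = ped.by_id
        for child in ped.members:
            if child.affected is not True or child.is_founder or child.bmp2_dose is None:
                continue
            father = index[child.father_id]
            mother = index[child.mother_id]
            for parent, other in ((father, mother), (mother, father)):
                if parent.bmp2_dose != 1 or other.bmp2_dose is None:
                    continue
                if other.bmp2_dose == 1 and child.bmp2_dose == 1:
                    continue  # ambiguous: cannot assign the risk allele
                other_allele = (
                    other.bmp2_dose // 2
                    if other.bmp2_dose != 1
                    else child.bmp2_dose // 2  # child 0 or 2 pins both
                )
                transmitted = child.bmp2_dose - other_allele
                if transmitted == 1:
                    t += 1
                else:
                    u += 1
    return TransmissionCounts(t, u)


def tdt(tc: TransmissionCounts) -> dict[str, float]:
    """Transmission disequilibrium test: chi2 = (T - U)^2 / (T + U), 1 df.

    Tests departure from the Mendelian 50% transmission expectation of the
    risk allele from heterozygous parents to affected offspring.
    """
    total = tc.transmitted + tc.untransmitted
    if total < 1:
        raise ValidationError("need at least one transmission")
    chi2 = (tc.transmitted - tc.untransmitted) ** 2 / total
    return {"chi2": float(chi2), "p": float(stats.chi2.sf(chi2, 1))}


# ---------------------------------------------------------------------------
# Penetrance


def penetrance_estimate(
    n_carriers: int,
    n_affected_carriers: int,
    n_probands: int,
    exclude_probands: bool,
) -> float:
    """Carrier penetrance, optionally correcting for ascertainment by
    dropping the probands (who were selected for being affected) from both
    numerator and denominator."""
    if not 0 <= n_affected_carriers <= n_carriers:
        raise ValidationError("affected carriers must lie in [0, carriers]")
    if not 0 <= n_probands <= n_affected_carriers:
        raise ValidationError("probands must be a subset of affected carriers")
    if not exclude_probands:
        if n_carriers == 0:
            raise ValidationError("no carriers: penetrance undefined")
        return n_affected_carriers / n_carriers
    if n_carriers == n_probands:
        raise ValidationError(
            "all carriers are probands: ascertainment-corrected penetrance undefined"
        )
    return (n_affected_carriers - n_probands) / (n_carriers - n_probands)


# ---------------------------------------------------------------------------
# Tabulation from pedigrees


def class_risk_table(pedigrees: Iterable[PedigreeGraph]) -> TwoLocusClassTable:
    """Cross-tabulate every member of carrier kindreds by two-locus class
    and affection.

    Only kindreds containing at least one rare-variant carrier contribute.
    "Risk allele present" collapses dose 1 and 2.  Members with a missing
    genotype or unknown phenotype, and members carrying neither allele, are
    counted in the result's metadata fields rather than silently dropped.
    """
    counts = np.zeros((3, 2), dtype=int)
    n_missing = n_neither = n_unknown = 0
    for ped in pedigrees:
        if not ped.has_smad6_carrier():
            continue
        for m in ped.members:
            if m.smad6 is Smad6Genotype.MISSING or m.bmp2_dose is None:
                n_missing += 1
                continue
            if m.affected is None:
                n_unknown += 1
                continue
            s = m.smad6 is Smad6Genotype.CARRIER
            b = m.bmp2_dose >= 1
            if s and b:
                row = 0
            elif s:
                row = 1
            elif b:
                row = 2
            else:
                n_neither += 1
                continue
            counts[row, 0 if m.affected else 1] += 1
    return TwoLocusClassTable(
        counts,
        n_missing_genotype=n_missing,
        n_neither_allele=n_neither,
        n_unknown_phenotype=n_unknown,
    )


def carrier_only_fisher(table: TwoLocusClassTable) -> dict:
    """2x2 Fisher exact test among carriers only: risk-allele presence vs
    affection (rows S+B+ and S+B- of the class table)."""
    t = table.counts[:2]
    p = float(stats.fisher_exact(t, alternative="two-sided")[1])
    haldane = bool((t == 0).any())
    tt = t + 0.5 if haldane else t
    orr = float(tt[0, 0] * tt[1, 1] / (tt[0, 1] * tt[1, 0]))
    return {"odds_ratio": orr, "p": p, "haldane": haldane}
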