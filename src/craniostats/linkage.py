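"""Parametric two-locus pedigree linkage.

Each individual's two-locus genotype — rare damaging SMAD6 carrier status
and risk-allele dose at the common BMP2 SNP — falls in one of five
penetrance classes:

====================  ==========  =====================================
class                 parameter    default (maximum-likelihood model)
====================  ==========  =====================================
carrier + risk allele  f_both      1.00
carrier only           f_S         0.09
one risk allele only   f_B1        0.0008
two risk alleles only  f_B2        0.0032
neither                f_0         0.0002  (phenocopy rate)
====================  ==========  =====================================

Marker and trait loci are modelled with zero recombination, so the
penetrance class is read directly off the observed marker genotypes.  A
kindred's likelihood, conditional on observed genotypes, is the product over
members of f(g) for affected and 1 - f(g) for unaffected individuals; the
null is phenotypes independent of genotype at the population prevalence.
The log10 likelihood ratio is the kindred's lod score; lods add across
independent kindreds.

Missing genotypes (typically ungenotyped founders) are marginalized: the
likelihood is summed over every Mendelian-consistent completion, each
weighted by its probability given the observed genotypes — Hardy–Weinberg
SNP genotype frequencies (allele frequency ``q_B``) and the rare-variant
carrier frequency ``q_S`` for founders, Mendelian transmission elsewhere.
The weights involve only genotype frequencies, never penetrances, so they
are computed once per pedigree and reused across the maximum-likelihood
penetrance grid search.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import logsumexp

from .errors import NoConsistentCompletionError, ValidationError
from .pedigree import Individual, PedigreeGraph, Smad6Genotype

#: penetrance-class order used throughout: (both, S only, B1 only, B2 only, neither)
CLASS_NAMES = ("f_both", "f_S", "f_B1", "f_B2", "f_0")

#: very negative stand-in for log(0) that keeps 0 * log(0) = 0 in count
#: products while still driving any impossible model's likelihood to zero
_LOG_ZERO = -1e30

#: default population prevalence for the chance null (configurable everywhere)
DEFAULT_PREVALENCE = 5e-4

#: marginalization bound: 6 genotype states per missing member
MAX_MISSING_MEMBERS = 6


@dataclass(frozen=True)
class TwoLocusPenetranceModel:
    """Five-class penetrance vector plus locus allele frequencies.

    Defaults are the maximum-likelihood digenic model: full penetrance with
    risk alleles at both loci, 9% for the rare variant alone, 0.08%/0.32%
    for one/two SNP risk alleles alone, 0.02% phenocopy rate, SNP risk-allele
    frequency 0.34, and zero recombination between markers and trait loci.
    """

    f_both: float = 1.0
    f_S: float = 0.09
    f_B1: float = 0.0008
    f_B2: float = 0.0032
    f_0: float = 0.0002
    q_B: float = 0.34
    q_S: float = 1e-4
    theta: float = 0.0  # fixed by the model; kept explicit for transparency

    def __post_init__(self):
        for name in CLASS_NAMES:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0,1], got {v}")
        if not 0.0 < self.q_B < 1.0:
            raise ValidationError(f"q_B must be in (0,1), got {self.q_B}")
        if not 0.0 < self.q_S < 1.0:
            raise ValidationError(f"q_S must be in (0,1), got {self.q_S}")
        if self.theta != 0.0:
            raise ValidationError("theta is fixed at 0 in this model")

    @property
    def f_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in CLASS_NAMES])


@dataclass
class LinkageResult:
    per_family_lod: dict[str, float]
    total_lod: float
    model: TwoLocusPenetranceModel
    null_spec: str

    def __post_init__(self):
        finite = [v for v in self.per_family_lod.values()]
        if not math.isclose(
            self.total_lod, sum(finite), rel_tol=1e-9, abs_tol=1e-9
        ) and not math.isinf(self.total_lod):
            raise ValidationError("total lod must equal the sum of per-family lods")


def class_index(smad6_carrier: bool, bmp2_dose: int) -> int:
    """Map a two-locus genotype to its penetrance-class index."""
    if bmp2_dose not in (0, 1, 2):
        raise ValidationError(f"bmp2_dose must be 0/1/2, got {bmp2_dose}")
    if smad6_carrier:
        return 0 if bmp2_dose >= 1 else 1
    return {0: 4, 1: 2, 2: 3}[bmp2_dose]


def penetrance_of(
    smad6_carrier: bool, bmp2_dose: int, m: TwoLocusPenetranceModel
) -> float:
    """Penetrance of a two-locus genotype under the model."""
    return float(m.f_vector[class_index(smad6_carrier, bmp2_dose)])


def lod_to_odds(lod: float) -> float:
    """Convert a lod score to the odds in favour of linkage (10**lod)."""
    return 10.0**lod


# ---------------------------------------------------------------------------
# Genotype-completion machinery

#: all (carrier, dose) states a missing genotype can take
_STATES = [(c, d) for c in (False, True) for d in (0, 1, 2)]


def _founder_prob(carrier: bool, dose: int, m: TwoLocusPenetranceModel) -> float:
    p_carrier = m.q_S if carrier else 1.0 - m.q_S
    hwe = {
        0: (1 - m.q_B) ** 2,
        1: 2 * m.q_B * (1 - m.q_B),
        2: m.q_B**2,
    }[dose]
    return p_carrier * hwe


def _transmit_dose_prob(child_dose: int, father_dose: int, mother_dose: int) -> float:
    pf, pm = father_dose / 2.0, mother_dose / 2.0  # P(transmit risk allele)
    probs = {
        0: (1 - pf) * (1 - pm),
        1: pf * (1 - pm) + (1 - pf) * pm,
        2: pf * pm,
    }
    return probs[child_dose]


def _transmit_carrier_prob(
    child_carrier: bool, father_carrier: bool, mother_carrier: bool, de_novo: bool
) -> float:
    if de_novo:
        # the child's carrier state arose by new mutation: its probability is
        # a constant (the de novo rate) independent of parental genotypes, so
        # it cancels in the normalized completion weights and is dropped
        return 1.0
    pf = 0.5 if father_carrier else 0.0  # carrier parents modelled heterozygous
    pm = 0.5 if mother_carrier else 0.0
    p_noncarrier = (1 - pf) * (1 - pm)
    return p_noncarrier if not child_carrier else 1.0 - p_noncarrier


@dataclass
class _FamilyCounts:
    """Penetrance-class tallies for each Mendelian-consistent completion of a
    pedigree's missing genotypes.

    ``weights[k]`` is P(completion k | observed genotypes); ``affected`` and
    ``unaffected`` are (K, 5) per-class count matrices.  Only members with a
    known phenotype contribute counts.
    """

    family_id: str
    weights: np.ndarray
    affected: np.ndarray
    unaffected: np.ndarray
    n_known_affected: int
    n_known_unaffected: int


def _family_counts(ped: PedigreeGraph, m: TwoLocusPenetranceModel) -> _FamilyCounts:
    members = ped.members
    index = {mem.iid: i for i, mem in enumerate(members)}
    missing = [
        mem
        for mem in members
        if mem.smad6 is Smad6Genotype.MISSING or mem.bmp2_dose is None
    ]
    if len(missing) > MAX_MISSING_MEMBERS:
        raise ValidationError(
            f"{ped.family_id}: {len(missing)} ungenotyped members exceeds the "
            f"marginalization bound ({MAX_MISSING_MEMBERS})"
        )

    def states_for(mem: Individual) -> list[tuple[bool, int]]:
        carriers = (
            (False, True)
            if mem.smad6 is Smad6Genotype.MISSING
            else (mem.smad6 is Smad6Genotype.CARRIER,)
        )
        doses = (0, 1, 2) if mem.bmp2_dose is None else (mem.bmp2_dose,)
        return [(c, d) for c in carriers for d in doses]

    missing_pos = {mem.iid: k for k, mem in enumerate(missing)}
    weights, aff_rows, unaff_rows = [], [], []
    n_aff = sum(1 for mem in members if mem.affected is True)
    n_unaff = sum(1 for mem in members if mem.affected is False)
    for combo in itertools.product(*(states_for(mem) for mem in missing)):
        geno: dict[str, tuple[bool, int]] = {}
        for mem in members:
            if mem.iid in missing_pos:
                geno[mem.iid] = combo[missing_pos[mem.iid]]
            else:
                geno[mem.iid] = (mem.smad6 is Smad6Genotype.CARRIER, mem.bmp2_dose)
        w = 1.0
        for mem in members:
            c, d = geno[mem.iid]
            if mem.is_founder:
                w *= _founder_prob(c, d, m)
            else:
                fc, fd = geno[mem.father_id]
                mc, md = geno[mem.mother_id]
                w *= _transmit_dose_prob(d, fd, md)
                w *= _transmit_carrier_prob(c, fc, mc, mem.smad6_de_novo)
            if w == 0.0:
                break
        if w == 0.0:
            continue
        a = np.zeros(5, dtype=np.int64)
        u = np.zeros(5, dtype=np.int64)
        for mem in members:
            if mem.affected is None:
                continue
            ci = class_index(*geno[mem.iid])
            (a if mem.affected else u)[ci] += 1
        weights.append(w)
        aff_rows.append(a)
        unaff_rows.append(u)
    if not weights:
        raise NoConsistentCompletionError(
            f"{ped.family_id}: no Mendelian-consistent completion of missing genotypes"
        )
    w = np.asarray(weights)
    return _FamilyCounts(
        ped.family_id,
        w / w.sum(),
        np.vstack(aff_rows),
        np.vstack(unaff_rows),
        n_aff,
        n_unaff,
    )


def _log_f(f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(log f, log(1-f)) with log(0) replaced by a large negative constant."""
    with np.errstate(divide="ignore"):
        lf = np.where(f > 0, np.log(np.maximum(f, 1e-300)), _LOG_ZERO)
        l1mf = np.where(f < 1, np.log(np.maximum(1 - f, 1e-300)), _LOG_ZERO)
    return lf, l1mf


def _counts_loglik(fc: _FamilyCounts, f: np.ndarray) -> float:
    lf, l1mf = _log_f(f)
    per_completion = fc.affected @ lf + fc.unaffected @ l1mf
    return float(logsumexp(per_completion, b=fc.weights))


# ---------------------------------------------------------------------------
# Likelihoods and lods


def family_likelihood(
    ped: PedigreeGraph,
    m: TwoLocusPenetranceModel,
    validate: bool = True,
    condition_on_proband: bool = False,
) -> float:
    """Likelihood of the kindred's phenotypes given its genotypes.

    Fully observed genotypes give the plain product of f(g) over affected
    and 1 - f(g) over unaffected members; missing genotypes are marginalized
    over Mendelian-consistent completions weighted by genotype frequencies
    (see module docstring).  With ``condition_on_proband`` the likelihood is
    divided by the probability that each proband is affected, correcting for
    ascertainment.
    """
    if validate:
        ped.validate()
    fc = _family_counts(ped, m)
    ll = _counts_loglik(fc, m.f_vector)
    if condition_on_proband:
        ll -= _proband_logprob(ped, m)
    return math.exp(ll) if ll > _LOG_ZERO / 2 else 0.0


def _proband_logprob(ped: PedigreeGraph, m: TwoLocusPenetranceModel) -> float:
    total = 0.0
    for p in ped.probands:
        if p.smad6 is Smad6Genotype.MISSING or p.bmp2_dose is None:
            raise ValidationError(
                f"{ped.family_id}/{p.iid}: proband genotype must be observed "
                "for ascertainment conditioning"
            )
        f = penetrance_of(p.smad6 is Smad6Genotype.CARRIER, p.bmp2_dose, m)
        if f == 0:
            raise ValidationError(
                f"{ped.family_id}/{p.iid}: proband has zero penetrance under the model"
            )
        total += math.log(f)
    return total


def marginalize_missing_parent(
    ped: PedigreeGraph, m: TwoLocusPenetranceModel, validate: bool = True
) -> float:
    """Family likelihood with missing founders summed out (explicit name for
    the marginalization path of :func:`family_likelihood`)."""
    return family_likelihood(ped, m, validate=validate)


def null_likelihood(ped: PedigreeGraph, prevalence: float = DEFAULT_PREVALENCE) -> float:
    """Chance model: phenotypes independent of genotype at the population
    prevalence."""
    if not 0.0 < prevalence < 1.0:
        raise ValidationError("prevalence must be in (0,1)")
    n_aff = sum(1 for mem in ped.members if mem.affected is True)
    n_unaff = sum(1 for mem in ped.members if mem.affected is False)
    return prevalence**n_aff * (1 - prevalence) ** n_unaff


def family_lod(
    ped: PedigreeGraph,
    m: TwoLocusPenetranceModel,
    prevalence: float = DEFAULT_PREVALENCE,
    validate: bool = True,
    condition_on_proband: bool = False,
) -> float:
    """log10 likelihood ratio of the two-locus model vs chance for one
    kindred.  A zero numerator (an unaffected obligate-penetrant member)
    yields -inf, surfaced rather than clamped."""
    if validate:
        ped.validate()
    fc = _family_counts(ped, m)
    log_num = _counts_loglik(fc, m.f_vector)  # natural log, underflow-safe
    if condition_on_proband:
        log_num -= _proband_logprob(ped, m)
    if log_num <= _LOG_ZERO / 2:
        return float("-inf")
    log_den = math.log(null_likelihood(ped, prevalence))
    if condition_on_proband:
        log_den -= len(ped.probands) * math.log(prevalence)
    return (log_num - log_den) / math.log(10)


def total_lod(
    peds: Sequence[PedigreeGraph],
    m: TwoLocusPenetranceModel,
    prevalence: float = DEFAULT_PREVALENCE,
    validate: bool = True,
    condition_on_proband: bool = False,
) -> LinkageResult:
    """Per-family and summed lod scores across independent kindreds."""
    ids = [ped.family_id for ped in peds]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate family ids: lods would silently collapse")
    per_family = {
        ped.family_id: family_lod(
            ped, m, prevalence, validate=validate, condition_on_proband=condition_on_proband
        )
        for ped in peds
    }
    return LinkageResult(
        per_family_lod=per_family,
        total_lod=sum(per_family.values()),
        model=m,
        null_spec=f"phenotypes independent of genotype, prevalence={prevalence}",
    )


# ---------------------------------------------------------------------------
# Maximum-likelihood grid search


def default_penetrance_grid(include_one: bool = False) -> list[float]:
    """log2-spaced penetrance grid 1e-4 ... 0.4096 plus 0.5 (and 1.0 for the
    fully penetrant class)."""
    vals = [1e-4 * 2**k for k in range(12)] + [0.5]
    if include_one:
        vals.append(1.0)
    return vals


def default_grid_spec() -> dict[str, list[float]]:
    return {
        "f_both": default_penetrance_grid(include_one=True),
        "f_S": default_penetrance_grid(),
        "f_B1": default_penetrance_grid(),
        "f_B2": default_penetrance_grid(),
        "f_0": default_penetrance_grid(),
    }


def _grid_matrix(grid_spec: Mapping[str, Sequence[float]]) -> np.ndarray:
    axes = []
    for name in CLASS_NAMES:
        vals = list(grid_spec.get(name, default_grid_spec()[name]))
        if not vals:
            raise ValidationError(f"empty grid for {name}")
        axes.append(np.asarray(vals, dtype=float))
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.stack([g.ravel() for g in mesh], axis=1)  # (G, 5)


def _grid_logliks(
    family_counts: Sequence[_FamilyCounts], F: np.ndarray
) -> np.ndarray:
    """Total log-likelihood of every candidate penetrance vector (rows of F)."""
    lf, l1mf = _log_f(F)  # (G, 5) each
    total = np.zeros(F.shape[0])
    # families without missing genotypes (a single completion) share one
    # summed count vector; marginalized families need a logsumexp each
    a_obs = np.zeros(5)
    u_obs = np.zeros(5)
    for fc in family_counts:
        if fc.weights.size == 1:
            a_obs += fc.affected[0]
            u_obs += fc.unaffected[0]
        else:
            per = fc.affected @ lf.T + fc.unaffected @ l1mf.T  # (K, G)
            total += logsumexp(per, axis=0, b=fc.weights[:, None])
    total += lf @ a_obs + l1mf @ u_obs
    return total


def ml_search(
    peds: Sequence[PedigreeGraph],
    grid_spec: Mapping[str, Sequence[float]] | None = None,
    prevalence: float = DEFAULT_PREVALENCE,
    base_model: TwoLocusPenetranceModel | None = None,
    validate: bool = True,
) -> LinkageResult:
    """Exhaustive grid maximization of the total lod over the five penetrance
    parameters.  Deterministic; ties resolve to the first grid point in
    lexicographic grid order.  Allele frequencies (and hence completion
    weights for missing genotypes) come from ``base_model``.
    """
    base = base_model or TwoLocusPenetranceModel()
    if validate:
        for ped in peds:
            ped.validate()
    counts = [_family_counts(ped, base) for ped in peds]
    F = _grid_matrix(grid_spec or default_grid_spec())
    logliks = _grid_logliks(counts, F)
    best = int(np.argmax(logliks))
    f = F[best]
    model = replace(
        base, **{name: float(f[i]) for i, name in enumerate(CLASS_NAMES)}
    )
    return total_lod(peds, model, prevalence, validate=False)


def single_locus_comparison(
    peds: Sequence[PedigreeGraph],
    m2: TwoLocusPenetranceModel,
    m1_grid: Mapping[str, Sequence[float]] | None = None,
    prevalence: float = DEFAULT_PREVALENCE,
) -> dict:
    """Likelihood ratio of the two-locus model against the best single-locus
    model, in which penetrance depends only on rare-variant carrier status
    (``f_carrier`` for carriers, ``f_noncarrier`` otherwise, each maximized
    over its grid).

    Returns the ratio 10**(lod2 - lod1) plus both lods and the best
    single-locus parameters.
    """
    grids = {
        "f_carrier": list(
            (m1_grid or {}).get("f_carrier", default_penetrance_grid(include_one=True))
        ),
        "f_noncarrier": list(
            (m1_grid or {}).get("f_noncarrier", default_penetrance_grid())
        ),
    }
    counts = [_family_counts(ped, m2) for ped in peds]
    fc_vals = np.asarray(grids["f_carrier"])
    fn_vals = np.asarray(grids["f_noncarrier"])
    mesh_c, mesh_n = np.meshgrid(fc_vals, fn_vals, indexing="ij")
    # map the single-locus model onto the five-class vector:
    # carrier classes (both, S-only) share f_carrier; the rest f_noncarrier
    F = np.stack(
        [mesh_c.ravel(), mesh_c.ravel(), mesh_n.ravel(), mesh_n.ravel(), mesh_n.ravel()],
        axis=1,
    )
    logliks = _grid_logliks(counts, F)
    best = int(np.argmax(logliks))
    null_ll = sum(math.log(null_likelihood(ped, prevalence)) for ped in peds)
    lod1 = (logliks[best] - null_ll) / math.log(10)
    lod2 = total_lod(peds, m2, prevalence, validate=False).total_lod
    return {
        "likelihood_ratio": 10.0 ** (lod2 - lod1),
        "lod_two_locus": lod2,
        "lod_single_locus": float(lod1),
        "best_single_locus": {
            "f_carrier": float(F[best, 0]),
            "f_noncarrier": float(F[best, 4]),
        },
    }
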