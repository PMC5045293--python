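"""Shared fixtures and the independent pedigree-likelihood oracle."""

from __future__ import annotations

import itertools

import pytest

from craniostats import TwoLocusPenetranceModel, penetrance_of
from craniostats.pedigree import Individual, PedigreeGraph, Smad6Genotype


@pytest.fixture
def ml_model() -> TwoLocusPenetranceModel:
    return TwoLocusPenetranceModel()


def make_ind(
    iid,
    father=None,
    mother=None,
    sex=0,
    affected=None,
    proband=False,
    carrier=None,
    dose=None,
    de_novo=False,
) -> Individual:
    smad6 = (
        Smad6Genotype.MISSING
        if carrier is None
        else (Smad6Genotype.CARRIER if carrier else Smad6Genotype.NONCARRIER)
    )
    return Individual(
        iid=iid,
        father_id=father,
        mother_id=mother,
        sex=sex,
        affected=affected,
        is_proband=proband,
        smad6=smad6,
        smad6_de_novo=de_novo,
        bmp2_dose=dose,
    )


@pytest.fixture
def oracle_trio() -> PedigreeGraph:
    """Mendelian-consistent trio whose likelihood under the default model is
    the hand product 0.91 * 0.9992 * 1.0 = 0.909272."""
    return PedigreeGraph(
        "T1",
        [
            make_ind("F", sex=1, affected=False, carrier=True, dose=0),
            make_ind("M", sex=2, affected=False, carrier=False, dose=1),
            make_ind("C", "F", "M", 1, True, True, True, 1),
        ],
    )


# ---------------------------------------------------------------------------
# Independent brute-force pedigree likelihood (the oracle the marginalization
# code is checked against).  It enumerates the JOINT genotype space of every
# member, scores each assignment by founder priors and Mendelian transmission,
# conditions on the observed genotypes, and averages the penetrance product —
# sharing no code with craniostats.linkage beyond penetrance_of.

_STATES = [(c, d) for c in (False, True) for d in (0, 1, 2)]


def _prior(carrier: bool, dose: int, m: TwoLocusPenetranceModel) -> float:
    hwe = {0: (1 - m.q_B) ** 2, 1: 2 * m.q_B * (1 - m.q_B), 2: m.q_B**2}[dose]
    return (m.q_S if carrier else 1 - m.q_S) * hwe


def _trans(child, father, mother, de_novo: bool) -> float:
    (cc, cd), (fc, fd), (mc, md) = child, father, mother
    pf, pm = fd / 2, md / 2
    pdose = {0: (1 - pf) * (1 - pm), 1: pf * (1 - pm) + (1 - pf) * pm, 2: pf * pm}[cd]
    if de_novo:
        pcar = 1.0  # constant de novo factor, cancels after conditioning
    else:
        qf = 0.5 if fc else 0.0
        qm = 0.5 if mc else 0.0
        pcar = (1 - qf) * (1 - qm) if not cc else 1 - (1 - qf) * (1 - qm)
    return pdose * pcar


def brute_force_likelihood(ped: PedigreeGraph, m: TwoLocusPenetranceModel) -> float:
    members = ped.members
    num = den = 0.0
    for assignment in itertools.product(_STATES, repeat=len(members)):
        geno = dict(zip((x.iid for x in members), assignment))
        ok = True
        for mem, g in zip(members, assignment):
            if mem.smad6 is not Smad6Genotype.MISSING and g[0] != (
                mem.smad6 is Smad6Genotype.CARRIER
            ):
                ok = False
                break
            if mem.bmp2_dose is not None and g[1] != mem.bmp2_dose:
                ok = False
                break
        if not ok:
            continue
        w = 1.0
        for mem in members:
            if mem.is_founder:
                w *= _prior(*geno[mem.iid], m)
            else:
                w *= _trans(
                    geno[mem.iid], geno[mem.father_id], geno[mem.mother_id], mem.smad6_de_novo
                )
        if w == 0.0:
            continue
        pen = 1.0
        for mem in members:
            if mem.affected is None:
                continue
            f = penetrance_of(*geno[mem.iid], m)
            pen *= f if mem.affected else 1 - f
        den += w
        num += w * pen
    if den == 0.0:
        raise ValueError("no consistent genotype assignment")
    return num / den
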