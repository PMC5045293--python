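"""Synthetic cohorts with the statistical structure the analyses assume.

Three generators stand in for study data so every pipeline stage runs and is
validated without any download:

* a trio-cohort de novo generator: per-offspring mutation counts are Poisson
  with class mix (synonymous / tolerated missense / damaging missense / LOF)
  set by cohort-wide expected counts, genes hit in proportion to per-gene
  mutability, plus a disease-gene "spike" contributing extra damaging events;
* a kindred generator: founders draw SNP genotypes from Hardy–Weinberg
  equilibrium and rare-variant carrier status from the carrier frequency (or
  a seeded carrier founder), alleles drop by Mendelian transmission,
  affection is sampled from the two-locus penetrance vector, and kindreds
  are ascertained through an affected (carrier) proband by rejection
  sampling;
* a null transmission generator for TDT type-I calibration (fair-coin
  transmissions).

Defaults mirror the study conditions: 132 trios with 142.8 expected coding
de novo mutations (40.4 synonymous, 75.2 T-mis, 14.5 D-mis, 12.7 LOF), 191
probands with 3156 rare damaging alleles (1135 LOF), SNP risk-allele
frequency 0.34, and the maximum-likelihood penetrance vector.

One root seed fans out to named substreams, so each generator is
independently reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace as dc_replace
from typing import Iterable, Sequence

import numpy as np

from .errors import ValidationError
from .epistasis import TransmissionCounts
from .linkage import TwoLocusPenetranceModel, penetrance_of
from .pedigree import Individual, PedigreeGraph, Smad6Genotype
from .transmitted import CohortAlleleCounts
from .variants import (
    Consequence,
    DamagingCall,
    MutationRateRow,
    Origin,
    VariantRecord,
)


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible child stream of a root seed."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(zlib.crc32(name.encode()),))
    )


@dataclass(frozen=True)
class SpikeSpec:
    """Extra burden injected into one disease gene: expected de novo counts
    per cohort and the per-proband transmitted damaging carrier rate."""

    gene: str = "SMAD6"
    denovo_lof: float = 2.0
    denovo_dmis: float = 1.0
    transmitted_carrier_rate: float = 10 / 191

    def __post_init__(self):
        if min(self.denovo_lof, self.denovo_dmis, self.transmitted_carrier_rate) < 0:
            raise ValidationError("spike rates must be non-negative")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-scale simulation parameters; every stochastic call derives its
    generator from ``seed`` via a named substream."""

    seed: int
    n_trios: int = 132
    n_probands: int = 191
    n_genes: int = 500
    # cohort-wide expected de novo counts per class
    expected_synonymous: float = 40.4
    expected_tmis: float = 75.2
    expected_dmis: float = 14.5
    expected_lof: float = 12.7
    spike: SpikeSpec = field(default_factory=SpikeSpec)
    total_damaging_alleles: int = 3156
    total_lof_alleles: int = 1135
    q_B: float = 0.34
    q_S: float = 1e-4
    penetrance: TwoLocusPenetranceModel = field(default_factory=TwoLocusPenetranceModel)
    n_kindreds: int = 13
    kindred_templates: tuple[str, ...] = (
        "trio",
        "trio",
        "trio",
        "trio",
        "trio",
        "quartet",
        "quartet",
        "quartet",
        "quartet",
        "three_gen",
        "three_gen",
        "three_gen",
        "three_gen",
    )
    seed_carrier_founder: bool = True
    #: when False, families are returned as drawn (raw population sample);
    #: ascertainment and the purifying-selection condition are skipped
    ascertain: bool = True
    require_carrier_proband: bool = True
    #: purifying selection: individuals with the phenotype rarely reproduce,
    #: so kindreds are conditioned on no parent being affected (matches the
    #: absence of affected transmitting parents in real midline-synostosis
    #: kindreds).  Disable for unconditioned population draws.
    condition_parents_unaffected: bool = True
    max_rejection_iter: int = 100_000

    def __post_init__(self):
        for name in ("q_B", "q_S"):
            if not 0 < getattr(self, name) < 1:
                raise ValidationError(f"{name} must be in (0,1)")
        if self.n_trios <= 0 or self.n_genes <= 0:
            raise ValidationError("n_trios and n_genes must be positive")

    @property
    def expected_total(self) -> float:
        return (
            self.expected_synonymous
            + self.expected_tmis
            + self.expected_dmis
            + self.expected_lof
        )


# ---------------------------------------------------------------------------
# Gene universe


def synthetic_gene_lengths(cfg: SimulationConfig) -> dict[str, int]:
    """Log-normal coding lengths (median ~1.5 kb) for a synthetic gene set;
    the spike gene is included with a realistic mid-size length."""
    rng = substream(cfg.seed, "genes")
    lengths = np.exp(rng.normal(np.log(1500), 0.6, size=cfg.n_genes)).astype(int) + 150
    names = [f"G{i:04d}" for i in range(cfg.n_genes)]
    out = dict(zip(names, (int(v) for v in lengths)))
    out[cfg.spike.gene] = 1500
    return out


def synthetic_rate_table(cfg: SimulationConfig) -> list[MutationRateRow]:
    """Per-gene de novo expectations: cohort-wide class totals split across
    genes in proportion to coding length."""
    lengths = synthetic_gene_lengths(cfg)
    total_bp = sum(lengths.values())
    rows = []
    for gene, bp in lengths.items():
        frac = bp / total_bp
        rows.append(
            MutationRateRow(
                gene=gene,
                lambda_lof=cfg.expected_lof * frac,
                lambda_mis=(cfg.expected_tmis + cfg.expected_dmis) * frac,
                lambda_syn=cfg.expected_synonymous * frac,
                cohort_size=cfg.n_trios,
            )
        )
    return rows


# ---------------------------------------------------------------------------
# De novo cohort

_CLASS_CONSEQUENCE = {
    "synonymous": Consequence.SYNONYMOUS,
    "tmis": Consequence.MISSENSE,
    "dmis": Consequence.MISSENSE,
    "lof": Consequence.NONSENSE,
}


def simulate_denovo_cohort(
    cfg: SimulationConfig,
) -> tuple[list[VariantRecord], list[MutationRateRow], dict[str, int]]:
    """Draw a trio cohort's de novo variants.

    Returns (variant records, per-gene rate table, gene lengths).  Per trio
    the total count is Poisson with the cohort mean / n_trios; classes are
    multinomial in the configured class mix; genes are chosen with
    probability proportional to their per-class lambda; the spike gene
    receives additional Poisson damaging events.
    """
    rng = substream(cfg.seed, "denovo")
    rates = synthetic_rate_table(cfg)
    lengths = synthetic_gene_lengths(cfg)
    genes = [r.gene for r in rates]
    gene_weights = np.array([lengths[g] for g in genes], dtype=float)
    gene_probs = gene_weights / gene_weights.sum()
    class_means = {
        "synonymous": cfg.expected_synonymous,
        "tmis": cfg.expected_tmis,
        "dmis": cfg.expected_dmis,
        "lof": cfg.expected_lof,
    }
    class_names = list(class_means)
    class_p = np.array([class_means[c] for c in class_names])
    class_p = class_p / class_p.sum()
    per_trio_mean = cfg.expected_total / cfg.n_trios
    records: list[VariantRecord] = []
    for t in range(cfg.n_trios):
        sample = f"T{t:04d}"
        n = rng.poisson(per_trio_mean)
        for _ in range(n):
            cls = class_names[rng.choice(len(class_names), p=class_p)]
            gene = genes[rng.choice(len(genes), p=gene_probs)]
            records.append(_denovo_record(sample, gene, cls))
        # spike gene: extra damaging events at the configured cohort rates
        for cls, rate in (("lof", cfg.spike.denovo_lof), ("dmis", cfg.spike.denovo_dmis)):
            for _ in range(rng.poisson(rate / cfg.n_trios)):
                records.append(_denovo_record(sample, cfg.spike.gene, cls))
    return records, rates, lengths


def _denovo_record(sample: str, gene: str, cls: str) -> VariantRecord:
    return VariantRecord(
        sample_id=sample,
        gene=gene,
        consequence=_CLASS_CONSEQUENCE[cls],
        damaging_call=(
            DamagingCall.D
            if cls == "dmis"
            else DamagingCall.T
            if cls == "tmis"
            else DamagingCall.NA
        ),
        pop_af=0.0,
        origin=Origin.DE_NOVO,
    )


def simulate_transmitted_counts(cfg: SimulationConfig) -> CohortAlleleCounts:
    """Throw the cohort's rare damaging alleles at genes in proportion to
    coding length, plus spike-gene carriers at the configured rate."""
    rng = substream(cfg.seed, "transmitted")
    lengths = synthetic_gene_lengths(cfg)
    genes = list(lengths)
    w = np.array([lengths[g] for g in genes], dtype=float)
    probs = w / w.sum()
    lof_hits = rng.multinomial(cfg.total_lof_alleles, probs)
    dam_hits = rng.multinomial(cfg.total_damaging_alleles - cfg.total_lof_alleles, probs)
    per_gene = {
        g: {"lof": int(lof_hits[i]), "damaging": int(lof_hits[i] + dam_hits[i])}
        for i, g in enumerate(genes)
    }
    spike_extra = int(rng.binomial(cfg.n_probands, cfg.spike.transmitted_carrier_rate))
    sg = per_gene.setdefault(cfg.spike.gene, {"lof": 0, "damaging": 0})
    sg["lof"] += spike_extra
    sg["damaging"] += spike_extra
    return CohortAlleleCounts(
        total_lof=cfg.total_lof_alleles + spike_extra,
        total_damaging=cfg.total_damaging_alleles + spike_extra,
        per_gene=per_gene,
        n_probands=cfg.n_probands,
    )


# ---------------------------------------------------------------------------
# Kindreds

#: structure templates: (iid, father, mother, sex); probands marked separately
_TEMPLATES: dict[str, list[tuple[str, str | None, str | None, int]]] = {
    "trio": [
        ("F", None, None, 1),
        ("M", None, None, 2),
        ("C1", "F", "M", 1),
    ],
    "quartet": [
        ("F", None, None, 1),
        ("M", None, None, 2),
        ("C1", "F", "M", 1),
        ("C2", "F", "M", 2),
    ],
    "three_gen": [
        ("GF", None, None, 1),
        ("GM", None, None, 2),
        ("F", "GF", "GM", 1),
        ("M", None, None, 2),
        ("C1", "F", "M", 1),
        ("C2", "F", "M", 2),
    ],
}

#: the ascertained individual in each template
_PROBAND = {"trio": "C1", "quartet": "C1", "three_gen": "C1"}


def _draw_family(
    template: str, fid: str, cfg: SimulationConfig, rng: np.random.Generator
) -> PedigreeGraph:
    spec = _TEMPLATES[template]
    founders = [iid for iid, f, m, _ in spec if f is None]
    seeded = founders[0] if cfg.seed_carrier_founder else None
    geno: dict[str, tuple[bool, int]] = {}
    members = []
    for iid, f, m, sex in spec:
        if f is None:
            dose = int(rng.choice(3, p=_hwe(cfg.q_B)))
            carrier = iid == seeded or (iid != seeded and rng.random() < cfg.q_S)
        else:
            fc, fd = geno[f]
            mc, md = geno[m]
            dose = int(rng.random() < fd / 2) + int(rng.random() < md / 2)
            carrier = (fc and rng.random() < 0.5) or (mc and rng.random() < 0.5)
        geno[iid] = (carrier, dose)
        affected = rng.random() < penetrance_of(carrier, dose, cfg.penetrance)
        members.append(
            Individual(
                iid=iid,
                father_id=f,
                mother_id=m,
                sex=sex,
                affected=affected,
                is_proband=iid == _PROBAND[template],
                smad6=Smad6Genotype.CARRIER if carrier else Smad6Genotype.NONCARRIER,
                bmp2_dose=dose,
            )
        )
    return PedigreeGraph(fid, members)


def _hwe(q: float) -> np.ndarray:
    return np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])


def _ascertained(ped: PedigreeGraph, cfg: SimulationConfig) -> bool:
    if not cfg.ascertain:
        return True
    pro = ped.probands[0]
    if pro.affected is not True:
        return False
    if cfg.require_carrier_proband and pro.smad6 is not Smad6Genotype.CARRIER:
        return False
    if cfg.condition_parents_unaffected:
        parent_ids = {m.father_id for m in ped.members} | {
            m.mother_id for m in ped.members
        }
        parent_ids.discard(None)
        if any(ped.by_id[pid].affected for pid in parent_ids):
            return False
    return True


def simulate_pedigrees(cfg: SimulationConfig) -> list[PedigreeGraph]:
    """Generate ``n_kindreds`` ascertained kindreds by rejection sampling.

    Raises ``RuntimeError`` if the ascertainment rule cannot be met within
    ``cfg.max_rejection_iter`` draws (e.g. penetrances too low for the
    requested rule).
    """
    rng = substream(cfg.seed, "pedigrees")
    peds = []
    attempts = 0
    for k in range(cfg.n_kindreds):
        template = cfg.kindred_templates[k % len(cfg.kindred_templates)]
        while True:
            attempts += 1
            if attempts > cfg.max_rejection_iter:
                raise RuntimeError(
                    f"ascertainment failed: {attempts} draws produced only "
                    f"{len(peds)} of {cfg.n_kindreds} acceptable kindreds"
                )
            ped = _draw_family(template, f"K{k:03d}", cfg, rng)
            if _ascertained(ped, cfg):
                peds.append(ped)
                break
    return peds


# ---------------------------------------------------------------------------
# Null transmissions


def simulate_null_tdt(
    cfg: SimulationConfig, n_replicates: int, n_transmissions: int
) -> list[TransmissionCounts]:
    """Fair-coin transmission replicates for TDT type-I calibration.

    Zero informative (heterozygous-parent) transmissions yields an empty
    stream.
    """
    if n_transmissions == 0:
        return []
    rng = substream(cfg.seed, "transmissions")
    t = rng.binomial(n_transmissions, 0.5, size=n_replicates)
    return [TransmissionCounts(int(x), n_transmissions - int(x)) for x in t]
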