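"""Annotated-variant domain model: classification into mutation classes and
allele-frequency rarity filtering.

A cohort's coding variants arrive as a flat table, one row per variant per
individual, already annotated upstream with a functional consequence, a
population allele frequency (ExAC-style; absent-from-database is coded 0) and,
for missense variants, an ensemble deleteriousness call or score.  This module
turns those annotations into the four mutation classes used throughout the
burden analyses:

* ``LOF`` — premature termination (nonsense), frameshift, or canonical
  splice-site variants, pooled as loss-of-function;
* ``D_mis`` / ``T_mis`` — missense predicted damaging / tolerated, using the
  ensemble call when present or a rank-score threshold (default 0.83357)
  when only a score is given;
* ``synonymous`` — silent variants, the negative-control class.

Rarity is a strict "<" cutoff on population allele frequency: 2e-5 for the
dominant (heterozygous damaging) analyses, 1e-3 for recessive screens.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .errors import UnclassifiableVariantError, ValidationError


class Consequence(str, enum.Enum):
    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    SPLICE_SITE = "splice_site"


#: consequences pooled as loss-of-function
LOF_CONSEQUENCES = frozenset(
    {Consequence.NONSENSE, Consequence.FRAMESHIFT, Consequence.SPLICE_SITE}
)


class DamagingCall(str, enum.Enum):
    D = "D"
    T = "T"
    NA = "NA"


class Origin(str, enum.Enum):
    DE_NOVO = "de_novo"
    TRANSMITTED = "transmitted"
    UNKNOWN = "unknown"


class Zygosity(str, enum.Enum):
    HET = "het"
    HOM = "hom"


class VariantClass(str, enum.Enum):
    LOF = "LOF"
    D_MIS = "D_mis"
    T_MIS = "T_mis"
    SYNONYMOUS = "synonymous"


@dataclass(frozen=True)
class VariantRecord:
    """One annotated coding variant in one individual."""

    sample_id: str
    gene: str
    consequence: Consequence
    pop_af: float
    origin: Origin = Origin.UNKNOWN
    zygosity: Zygosity = Zygosity.HET
    damaging_call: DamagingCall = DamagingCall.NA
    damaging_score: float | None = None

    def __post_init__(self):
        if not 0.0 <= self.pop_af <= 1.0:
            raise ValidationError(
                f"pop_af must be in [0,1], got {self.pop_af!r} for {self.gene}"
            )
        if self.damaging_score is not None and not 0.0 <= self.damaging_score <= 1.0:
            raise ValidationError(
                f"damaging_score must be in [0,1], got {self.damaging_score!r}"
            )
        if (
            self.consequence is not Consequence.MISSENSE
            and self.damaging_call is not DamagingCall.NA
        ):
            raise ValidationError(
                "damaging_call is defined only for missense variants "
                f"(got {self.damaging_call} on {self.consequence})"
            )


@dataclass(frozen=True)
class MutationRateRow:
    """Expected de novo counts per mutation class for one gene (or gene set)
    in a cohort of ``cohort_size`` trios.  The lambdas are the Poisson means
    of the gene-level burden tests; they scale linearly with cohort size."""

    gene: str
    lambda_lof: float
    lambda_mis: float
    lambda_syn: float = 0.0
    cohort_size: int = 0

    def __post_init__(self):
        for name in ("lambda_lof", "lambda_mis", "lambda_syn"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    def scaled_to(self, n_trios: int) -> "MutationRateRow":
        """Rescale the expectations to a different cohort size."""
        if self.cohort_size <= 0:
            raise ValidationError("cannot rescale a row with unknown cohort_size")
        k = n_trios / self.cohort_size
        return MutationRateRow(
            self.gene, self.lambda_lof * k, self.lambda_mis * k, self.lambda_syn * k, n_trios
        )


@dataclass(frozen=True)
class GeneLengthRow:
    gene: str
    coding_bp: int

    def __post_init__(self):
        if self.coding_bp <= 0:
            raise ValidationError(f"coding_bp must be > 0, got {self.coding_bp}")


@dataclass(frozen=True)
class RarityPolicy:
    """Allele-frequency cutoffs and the missense deleteriousness threshold.

    Comparisons are strict: a variant is rare when pop_af < the cutoff.
    """

    dominant_af_max: float = 2e-5
    recessive_af_max: float = 1e-3
    damaging_score_min: float = 0.83357

    def __post_init__(self):
        if not 0 < self.dominant_af_max <= self.recessive_af_max:
            raise ValidationError(
                "require 0 < dominant_af_max <= recessive_af_max, got "
                f"{self.dominant_af_max} / {self.recessive_af_max}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RarityPolicy":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "dominant_af_max": self.dominant_af_max,
                    "recessive_af_max": self.recessive_af_max,
                    "damaging_score_min": self.damaging_score_min,
                },
                fh,
            )


def classify_variant(
    v: VariantRecord, policy: RarityPolicy | None = None
) -> VariantClass:
    """Bin a variant into {LOF, D_mis, T_mis, synonymous}.

    Missense variants use the explicit damaging call when present; otherwise
    a score strictly above ``policy.damaging_score_min`` is damaging.  A
    missense variant with neither call nor score raises
    :class:`UnclassifiableVariantError` — it is never silently tolerated.
    """
    policy = policy or RarityPolicy()
    if v.consequence in LOF_CONSEQUENCES:
        return VariantClass.LOF
    if v.consequence is Consequence.SYNONYMOUS:
        return VariantClass.SYNONYMOUS
    # missense
    if v.damaging_call is DamagingCall.D:
        return VariantClass.D_MIS
    if v.damaging_call is DamagingCall.T:
        return VariantClass.T_MIS
    if v.damaging_score is not None:
        return (
            VariantClass.D_MIS
            if v.damaging_score > policy.damaging_score_min
            else VariantClass.T_MIS
        )
    raise UnclassifiableVariantError(
        f"missense variant in {v.gene} ({v.sample_id}) has neither a damaging "
        "call nor a score"
    )


def filter_rare(
    records: Iterable[VariantRecord],
    policy: RarityPolicy | None = None,
    mode: str = "dominant",
) -> list[VariantRecord]:
    """Keep variants strictly below the policy's allele-frequency cutoff.

    ``mode`` is ``"dominant"`` (default, af < dominant_af_max) or
    ``"recessive"`` (af < recessive_af_max).  Input order is preserved.
    """
    policy = policy or RarityPolicy()
    if mode == "dominant":
        cutoff = policy.dominant_af_max
    elif mode == "recessive":
        cutoff = policy.recessive_af_max
    else:
        raise ValidationError(f"mode must be 'dominant' or 'recessive', got {mode!r}")
    out = []
    for r in records:
        if r.pop_af < 0:  # defensive; VariantRecord already validates
            raise ValidationError(f"negative allele frequency on {r.gene}")
        if r.pop_af < cutoff:
            out.append(r)
    return out


# ---------------------------------------------------------------------------
# Tab-separated table IO

VARIANT_COLUMNS = [
    "sample",
    "gene",
    "consequence",
    "damaging_call",
    "damaging_score",
    "pop_af",
    "origin",
    "zygosity",
]


def read_variant_table(path: str | Path) -> list[VariantRecord]:
    """Read a variant TSV (header = :data:`VARIANT_COLUMNS`; '.' = missing)."""
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["."], keep_default_na=False)
    missing = set(VARIANT_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"variant table missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        score = getattr(row, "damaging_score")
        call = getattr(row, "damaging_call")
        records.append(
            VariantRecord(
                sample_id=row.sample,
                gene=row.gene,
                consequence=Consequence(row.consequence),
                damaging_call=DamagingCall(call) if pd.notna(call) else DamagingCall.NA,
                damaging_score=float(score) if pd.notna(score) else None,
                pop_af=float(row.pop_af) if pd.notna(row.pop_af) else 0.0,
                origin=Origin(row.origin) if pd.notna(row.origin) else Origin.UNKNOWN,
                zygosity=Zygosity(row.zygosity) if pd.notna(row.zygosity) else Zygosity.HET,
            )
        )
    return records


def write_variant_table(records: Sequence[VariantRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "sample": r.sample_id,
                "gene": r.gene,
                "consequence": r.consequence.value,
                "damaging_call": r.damaging_call.value
                if r.damaging_call is not DamagingCall.NA
                else ".",
                "damaging_score": r.damaging_score if r.damaging_score is not None else ".",
                "pop_af": r.pop_af,
                "origin": r.origin.value,
                "zygosity": r.zygosity.value,
            }
        )
    pd.DataFrame(rows, columns=VARIANT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_rate_table(path: str | Path) -> list[MutationRateRow]:
    """Read a per-gene mutation-rate TSV: gene, lambda_lof, lambda_mis
    [, lambda_syn, cohort_size]."""
    df = pd.read_csv(path, sep="\t")
    rows = []
    for r in df.itertuples(index=False):
        rows.append(
            MutationRateRow(
                gene=str(r.gene),
                lambda_lof=float(r.lambda_lof),
                lambda_mis=float(r.lambda_mis),
                lambda_syn=float(getattr(r, "lambda_syn", 0.0) or 0.0),
                cohort_size=int(getattr(r, "cohort_size", 0) or 0),
            )
        )
    return rows


def write_rate_table(rows: Sequence[MutationRateRow], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "gene": r.gene,
                "lambda_lof": r.lambda_lof,
                "lambda_mis": r.lambda_mis,
                "lambda_syn": r.lambda_syn,
                "cohort_size": r.cohort_size,
            }
            for r in rows
        ]
    ).to_csv(path, sep="\t", index=False)


def read_gene_lengths(path: str | Path) -> dict[str, int]:
    """Read a 2-column gene/coding_bp TSV into a dict."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, int] = {}
    for r in df.itertuples(index=False):
        row = GeneLengthRow(str(r.gene), int(r.coding_bp))
        out[row.gene] = row.coding_bp
    return out


def write_gene_lengths(lengths: dict[str, int], path: str | Path) -> None:
    pd.DataFrame(
        [{"gene": g, "coding_bp": bp} for g, bp in lengths.items()]
    ).to_csv(path, sep="\t", index=False)
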