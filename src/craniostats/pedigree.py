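"""Pedigrees genotyped at two loci: a rare damaging-variant carrier flag at
SMAD6 and a common biallelic risk SNP (modelled on rs1884302 downstream of
BMP2, risk allele 'C') stored as risk-allele dose 0/1/2.

File format is PED-like, whitespace-delimited, one individual per line::

    fid iid father mother sex aff proband smad6 bmp2

* ``father``/``mother`` — ``0`` for founders;
* ``sex`` — 1 male, 2 female, 0 unknown;
* ``aff`` — 2 affected, 1 unaffected, 0/-9 unknown;
* ``proband`` — 1 for the ascertained individual, else 0 (explicit, never
  inferred: ascertainment corrections need it);
* ``smad6`` — ``D`` carrier, ``D*`` de novo carrier, ``N`` non-carrier,
  ``.`` missing;
* ``bmp2`` — risk-allele dose ``0``/``1``/``2`` or ``.`` missing.

Reading validates structure (parent links present and acyclic) and Mendelian
consistency at both loci; violations are reported with file line numbers.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from .errors import MendelianError, PedigreeFormatError, ValidationError


class Smad6Genotype(str, enum.Enum):
    CARRIER = "D"
    NONCARRIER = "N"
    MISSING = "."


@dataclass
class Individual:
    iid: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: int = 0
    affected: bool | None = None
    is_proband: bool = False
    smad6: Smad6Genotype = Smad6Genotype.MISSING
    smad6_de_novo: bool = False
    bmp2_dose: int | None = None

    def __post_init__(self):
        if self.bmp2_dose is not None and self.bmp2_dose not in (0, 1, 2):
            raise ValidationError(f"bmp2_dose must be 0/1/2 or None, got {self.bmp2_dose}")
        if self.smad6_de_novo and self.smad6 is not Smad6Genotype.CARRIER:
            raise ValidationError("smad6_de_novo set on a non-carrier")

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None

    @property
    def smad6_carrier(self) -> bool | None:
        if self.smad6 is Smad6Genotype.MISSING:
            return None
        return self.smad6 is Smad6Genotype.CARRIER


@dataclass
class PedigreeGraph:
    """One kindred: individuals, parent links, affection and two-locus
    genotypes.  Construction checks link integrity and acyclicity; call
    :meth:`mendelian_violations` (or construct via :func:`read_pedigree`)
    for genotype-level checks."""

    family_id: str
    members: list[Individual] = field(default_factory=list)

    def __post_init__(self):
        self._check_structure()

    def _check_structure(self) -> None:
        ids = [m.iid for m in self.members]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate individual ids in family {self.family_id}")
        index = self.by_id
        for m in self.members:
            if (m.father_id is None) != (m.mother_id is None):
                raise ValidationError(
                    f"{self.family_id}/{m.iid}: both parents or neither must be given"
                )
            for pid in (m.father_id, m.mother_id):
                if pid is not None and pid not in index:
                    raise ValidationError(
                        f"{self.family_id}/{m.iid}: missing parent id {pid!r}"
                    )
        # acyclicity via iterative DFS over child->parent edges
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(start: str) -> None:
            stack = [(start, iter(self._parent_ids(start)))]
            state[start] = 0
            while stack:
                node, it = stack[-1]
                advanced = False
                for pid in it:
                    if state.get(pid) == 0:
                        raise ValidationError(
                            f"cycle in pedigree {self.family_id} involving {pid}"
                        )
                    if pid not in state:
                        state[pid] = 0
                        stack.append((pid, iter(self._parent_ids(pid))))
                        advanced = True
                        break
                if not advanced:
                    state[node] = 1
                    stack.pop()

        for m in self.members:
            if m.iid not in state:
                visit(m.iid)

    def _parent_ids(self, iid: str) -> list[str]:
        m = self.by_id[iid]
        return [p for p in (m.father_id, m.mother_id) if p is not None]

    @property
    def by_id(self) -> dict[str, Individual]:
        return {m.iid: m for m in self.members}

    @property
    def founders(self) -> list[Individual]:
        return [m for m in self.members if m.is_founder]

    @property
    def probands(self) -> list[Individual]:
        return [m for m in self.members if m.is_proband]

    def children_of(self, iid: str) -> list[Individual]:
        return [m for m in self.members if iid in (m.father_id, m.mother_id)]

    def has_smad6_carrier(self) -> bool:
        return any(m.smad6 is Smad6Genotype.CARRIER for m in self.members)

    # -- Mendelian consistency ------------------------------------------------

    def mendelian_violations(self) -> list[str]:
        """Human-readable descriptions of every Mendelian inconsistency at
        either locus; empty list when the pedigree is consistent."""
        out = []
        index = self.by_id
        for child in self.members:
            if child.is_founder:
                continue
            father = index[child.father_id]
            mother = index[child.mother_id]
            # SNP dose: child dose must be attainable as one allele from each parent
            if child.bmp2_dose is not None:
                if not _dose_transmissible(child.bmp2_dose, father.bmp2_dose, mother.bmp2_dose):
                    out.append(
                        f"{self.family_id}: child {child.iid} dose {child.bmp2_dose} "
                        f"impossible from parents {father.iid}/{mother.iid} "
                        f"(doses {father.bmp2_dose}/{mother.bmp2_dose})"
                    )
            # rare-variant carrier flag: a carrier child needs a carrier parent
            # unless the variant is flagged de novo
            if (
                child.smad6 is Smad6Genotype.CARRIER
                and not child.smad6_de_novo
                and father.smad6 is Smad6Genotype.NONCARRIER
                and mother.smad6 is Smad6Genotype.NONCARRIER
            ):
                out.append(
                    f"{self.family_id}: carrier child {child.iid} has two "
                    "non-carrier parents and no de novo flag"
                )
        return out

    def validate(self) -> None:
        """Raise :class:`MendelianError` if any genotype is inconsistent."""
        violations = self.mendelian_violations()
        if violations:
            raise MendelianError(
                "; ".join(violations),
                trios=[v.split(":")[0] for v in violations],
            )


def _possible_transmitted(dose: int | None) -> set[int]:
    """Alleles (0 = non-risk, 1 = risk) a parent of the given dose can pass."""
    if dose is None:
        return {0, 1}
    return {0: {0}, 1: {0, 1}, 2: {1}}[dose]


def _dose_transmissible(child: int, father: int | None, mother: int | None) -> bool:
    return any(
        a + b == child
        for a in _possible_transmitted(father)
        for b in _possible_transmitted(mother)
    )


# ---------------------------------------------------------------------------
# IO

_AFF_CODES = {"2": True, "1": False, "0": None, "-9": None}


def _parse_line(parts: list[str], lineno: int) -> tuple[str, Individual]:
    if len(parts) != 9:
        raise PedigreeFormatError(
            f"expected 9 whitespace-delimited fields, got {len(parts)}", lineno
        )
    fid, iid, father, mother, sex, aff, proband, smad6, bmp2 = parts
    if aff not in _AFF_CODES:
        raise PedigreeFormatError(f"bad affection code {aff!r}", lineno)
    if smad6 not in ("D", "D*", "N", "."):
        raise PedigreeFormatError(f"bad smad6 genotype {smad6!r}", lineno)
    if bmp2 not in ("0", "1", "2", "."):
        raise PedigreeFormatError(f"bad bmp2 dose {bmp2!r}", lineno)
    try:
        ind = Individual(
            iid=iid,
            father_id=None if father == "0" else father,
            mother_id=None if mother == "0" else mother,
            sex=int(sex),
            affected=_AFF_CODES[aff],
            is_proband=proband == "1",
            smad6=Smad6Genotype.MISSING
            if smad6 == "."
            else (Smad6Genotype.CARRIER if smad6.startswith("D") else Smad6Genotype.NONCARRIER),
            smad6_de_novo=smad6 == "D*",
            bmp2_dose=None if bmp2 == "." else int(bmp2),
        )
    except (ValueError, ValidationError) as exc:
        raise PedigreeFormatError(str(exc), lineno) from exc
    return fid, ind


def read_pedigree(path: str | Path, validate: bool = True) -> list[PedigreeGraph]:
    """Parse a pedigree file into one :class:`PedigreeGraph` per family id.

    With ``validate`` (default) Mendelian inconsistencies raise
    :class:`MendelianError` listing the offending trios and file lines.
    """
    families: dict[str, list[Individual]] = {}
    lines_by_family: dict[str, list[int]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fid, ind = _parse_line(line.split(), lineno)
            families.setdefault(fid, []).append(ind)
            lines_by_family.setdefault(fid, []).append(lineno)
    peds = []
    for fid, members in families.items():
        try:
            ped = PedigreeGraph(fid, members)
        except ValidationError as exc:
            raise PedigreeFormatError(
                f"family {fid}: {exc}", lines_by_family[fid][0]
            ) from exc
        if validate:
            violations = ped.mendelian_violations()
            if violations:
                raise MendelianError(
                    f"(lines {lines_by_family[fid]}) " + "; ".join(violations),
                    lines=lines_by_family[fid],
                )
        peds.append(ped)
    return peds


def write_pedigree(peds: Iterable[PedigreeGraph], path: str | Path) -> None:
    """Inverse of :func:`read_pedigree`; write(read(f)) round-trips."""
    with open(path, "w") as fh:
        fh.write("# fid iid father mother sex aff proband smad6 bmp2\n")
        for ped in peds:
            for m in ped.members:
                if m.smad6 is Smad6Genotype.MISSING:
                    smad6 = "."
                elif m.smad6 is Smad6Genotype.CARRIER:
                    smad6 = "D*" if m.smad6_de_novo else "D"
                else:
                    smad6 = "N"
                aff = {True: "2", False: "1", None: "0"}[m.affected]
                fh.write(
                    " ".join(
                        [
                            ped.family_id,
                            m.iid,
                            m.father_id or "0",
                            m.mother_id or "0",
                            str(m.sex),
                            aff,
                            "1" if m.is_proband else "0",
                            smad6,
                            "." if m.bmp2_dose is None else str(m.bmp2_dose),
                        ]
                    )
                    + "\n"
                )
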