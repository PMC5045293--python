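"""Exception hierarchy shared across the package."""

from __future__ import annotations


class CranioStatsError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(CranioStatsError, ValueError):
    """Invalid numeric or categorical input (negative counts, out-of-range frequencies...)."""


class UnclassifiableVariantError(CranioStatsError):
    """A missense variant carries neither a damaging call nor a score; it cannot
    be binned into D-mis/T-mis and must never be silently treated as tolerated."""


class MendelianError(CranioStatsError):
    """A child genotype is impossible given its parents' genotypes.

    ``trios`` lists the offending (family_id, child_id, father_id, mother_id)
    tuples; ``lines`` the 1-based file lines when parsed from disk.
    """

    def __init__(self, message: str, trios: list | None = None, lines: list | None = None):
        super().__init__(message)
        self.trios = trios or []
        self.lines = lines or []


class PedigreeFormatError(CranioStatsError):
    """Malformed pedigree file; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message if line is None else f"line {line}: {message}")
        self.line = line


class EnumerationBoundError(CranioStatsError):
    """An exact contingency enumeration would be too large; use the seeded
    Monte-Carlo fallback instead."""


class NoConsistentCompletionError(CranioStatsError):
    """No assignment of missing genotypes is Mendelian-consistent with the
    observed ones."""
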