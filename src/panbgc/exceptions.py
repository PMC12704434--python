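"""Exception hierarchy for panbgc.

All user-facing errors derive from :class:`PanbgcError` so callers (and the
CLI) can catch one base class. Input-validation failures subclass
``ValueError`` as well, matching the convention of most scientific Python
packages.
"""

from __future__ import annotations


class PanbgcError(Exception):
    """Base class for all panbgc errors."""


class FormatError(PanbgcError, ValueError):
    """A file could not be parsed in its declared format."""


class EmptyRecordError(PanbgcError, ValueError):
    """A BGC record contains no CDS features (a cluster must contain genes)."""


class UnknownGeneError(PanbgcError, KeyError):
    """An ortholog table references a gene absent from the family."""


class IncompleteAssignmentError(PanbgcError, ValueError):
    """Ortholog assignment does not cover every gene of the family."""

    def __init__(self, missing: list[str]):
        self.missing = list(missing)
        super().__init__(
            f"ortholog assignment missing for {len(self.missing)} gene(s): "
            + ", ".join(self.missing[:10])
            + ("..." if len(self.missing) > 10 else "")
        )


class ConflictError(PanbgcError, ValueError):
    """A gene is assigned to more than one ortholog group."""


class UngroupableGeneError(PanbgcError, ValueError):
    """A gene has no protein or recoverable sequence to group by."""


class TooFewMembersError(PanbgcError, ValueError):
    """Openness analysis requires at least three member BGCs."""

    def __init__(self, n: int):
        self.n = n
        super().__init__(f"openness analysis requires >= 3 BGCs, got {n}")


class EmptyFamilyError(PanbgcError, ValueError):
    """A synthetic-family spec that can generate no genes at all."""


class NoSharedLeavesError(PanbgcError, ValueError):
    """Two leaf orders share no labels; no tanglegram can be drawn."""
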