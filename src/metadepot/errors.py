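"""Exception hierarchy shared by all modules.

Every error raised on purpose derives from :class:`MetadepotError` and carries a
stable ``code`` (the class name) so CLI output and validation reports can refer
to findings uniformly.
"""

from __future__ import annotations


class MetadepotError(Exception):
    """Base class for all errors raised by metadepot."""

    @property
    def code(self) -> str:
        return type(self).__name__


# --- file-format layer -------------------------------------------------------

class MissingColumn(MetadepotError):
    pass


class DuplicateSample(MetadepotError):
    pass


class MalformedRow(MetadepotError):
    pass


class MalformedCoordinate(MetadepotError):
    pass


class NegativeContribution(MetadepotError):
    pass


class DuplicateSequenceRow(MetadepotError):
    pass


class NonNumericCell(MetadepotError):
    pass


class DuplicateId(MetadepotError):
    pass


class EmptySequence(MetadepotError):
    pass


class NoTarget(MetadepotError):
    pass


class MalformedBestHit(MetadepotError):
    pass


class MalformedDate(MetadepotError):
    pass


class IOFailure(MetadepotError):
    pass


# --- taxonomy layer ----------------------------------------------------------

class OrphanNode(MetadepotError):
    pass


class CycleDetected(MetadepotError):
    pass


class UnknownTaxon(MetadepotError):
    pass


class EmptyInput(MetadepotError):
    pass


class MalformedMapping(MetadepotError):
    pass


class NoTaxonomy(MetadepotError):
    pass


# --- store layer -------------------------------------------------------------

class DuplicateProject(MetadepotError):
    pass


class UnknownProject(MetadepotError):
    pass


class DuplicateSequence(MetadepotError):
    pass


class ConflictingFieldType(MetadepotError):
    pass


class ConflictingSampleMetadata(MetadepotError):
    pass


class UnknownSequence(MetadepotError):
    pass


class BestHitConflict(MetadepotError):
    pass


# --- query / export layer ----------------------------------------------------

class UnknownField(MetadepotError):
    pass


class TypeMismatch(MetadepotError):
    pass


class AmbiguousMethod(MetadepotError):
    pass


class EmptySelection(MetadepotError):
    pass
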