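"""Exception hierarchy for plastsurvey.

Errors are structured (they carry the offending object where useful) so that
pipeline stages can report which genome, marker or tree caused an abort.
"""

from __future__ import annotations


class PlastsurveyError(Exception):
    """Base class for all package errors."""


class GenomeParseError(PlastsurveyError):
    """A GenBank record could not be parsed into a CircularGenome."""


class AlignmentError(PlastsurveyError):
    """Ragged rows, duplicate labels, or an empty alignment."""


class FrameError(AlignmentError):
    """A CDS alignment whose length is not a multiple of three."""


class NoInvertedRepeatError(PlastsurveyError):
    """No inverted repeat of at least ``min_ir`` bases exists."""

    def __init__(self, min_ir: int) -> None:
        super().__init__(f"no exact inverted repeat of length >= {min_ir} found")
        self.min_ir = min_ir


class InvertedRepeatTieError(PlastsurveyError):
    """Two or more maximal inverted-repeat pairs of equal length."""

    def __init__(self, candidates) -> None:
        self.candidates = list(candidates)
        super().__init__(
            "ambiguous inverted repeat: multiple maximal candidates "
            + ", ".join(str(c) for c in self.candidates)
        )


class UndefinedGCError(PlastsurveyError):
    """GC content requested for a sequence without unambiguous bases."""


class SaturationError(PlastsurveyError):
    """K80 distance undefined: log argument non-positive (saturated pair)."""


class ExtractionError(PlastsurveyError):
    """A gene's exon parts overlap or are otherwise inconsistent."""


class TooFewTaxaError(PlastsurveyError):
    """A marker is present in fewer than four genomes; no tree possible."""


class TreeError(PlastsurveyError):
    """Invalid distance matrix, taxon-set mismatch, or malformed Newick."""


class DegenerateSurveyError(PlastsurveyError):
    """Every marker is invariant; relative values are undefined."""


class PipelineError(PlastsurveyError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
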