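"""Exception hierarchy for nat2kit.

Every error raised on a bad input or an unsupported analysis path derives
from :class:`Nat2kitError`, so callers can catch one base class at a
pipeline boundary while tests can assert on the specific subtype.
"""


class Nat2kitError(Exception):
    """Base class for all nat2kit errors."""


class DefinitionError(Nat2kitError):
    """Invalid star-allele definition table (duplicate rsID, empty set, ...)."""


class UnknownSiteError(Nat2kitError):
    """A genotype carries a dosage at an rsID outside the definition set."""


class CompoundHaplotypeError(Nat2kitError):
    """The most likely phase puts two signature variants on one chromosome.

    The supported allele universe is {*4, *5, *6, *7}; a compound haplotype
    has no name in it, and silently renaming it would corrupt every
    downstream activity score, so this is a hard error.
    """


class UnsupportedAlleleError(Nat2kitError):
    """An allele with no kinetic characterization (e.g. *14) reached scoring."""


class MissingReferenceError(Nat2kitError):
    """No *4 reference value available where a ratio to *4 is required."""


class InsufficientDataError(Nat2kitError):
    """Too few usable observations for a fit (e.g. <3 positive concentrations)."""


class NonConvergentFitError(Nat2kitError):
    """A kinetic fit produced a non-physical parameter (e.g. intercept <= 0)."""


class UnlabelledGenotypeError(Nat2kitError):
    """A cohort genotype has no phenotype label in the assignment."""


class VCFFormatError(Nat2kitError):
    """Malformed or unsupported VCF content (e.g. multi-allelic signature site)."""


class ConfigError(Nat2kitError):
    """Invalid pipeline configuration (unknown keys, missing inputs)."""


class PipelineStageError(Nat2kitError):
    """A pipeline stage failed; carries the stage name and offending record."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
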