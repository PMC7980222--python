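"""Exception hierarchy.

Every error raised on purpose by this package derives from
:class:`MethylbindError`, so callers can catch one type at a pipeline
boundary.  Subclasses map one-to-one onto the failure modes of the
operations that raise them.
"""


class MethylbindError(Exception):
    """Base class for all methylbind errors."""


class InvalidConfigurationError(MethylbindError, ValueError):
    """A parameter is outside its admissible range."""


class BoundaryError(MethylbindError):
    """A cytosine too close to a chromosome edge to classify; callers skip it."""


class InputIntegrityError(MethylbindError, ValueError):
    """Input table violates a structural contract (duplicates, bad subset)."""


class MalformedIntervalError(MethylbindError, ValueError):
    """A genomic interval with end <= start."""


class EmptyCatalogError(MethylbindError, ValueError):
    """A site catalog with no members where at least one is required."""


class DegenerateProfileError(MethylbindError, ValueError):
    """Footprint profile cannot be normalized or ratioed (zero flank/bin)."""


class IncompatibleProfilesError(MethylbindError, ValueError):
    """Profiles with mixed stages or catalogs cannot be combined."""


class UndefinedEstimateError(MethylbindError, ValueError):
    """Genome scaling undefined: no covered motifs to scale from."""


class EmptyJoinError(MethylbindError, ValueError):
    """Expression/methylation join produced no genes."""


class UndefinedCorrelationError(MethylbindError, ValueError):
    """Correlation undefined because a covariate has zero variance."""


class InsufficientGenesError(MethylbindError, ValueError):
    """Too few genes to form interior bins after edge dropping."""


class DegenerateBinError(MethylbindError, ValueError):
    """A gene bin without enough members or x-variance to fit a slope."""


class EmptyInputError(MethylbindError, ValueError):
    """An operation received an empty collection it cannot act on."""


class DegenerateTraceError(MethylbindError, ValueError):
    """FRAP trace with nonpositive denominators or too few usable points."""


class NoRecoveryError(MethylbindError):
    """FRAP log-fit slope is not positive: no recovery to time."""
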