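"""Error hierarchy shared across the package.

All errors derive from :class:`BioregionsError` so callers can catch the
package's failures in one clause; most also derive from the matching
builtin (``ValueError``/``KeyError``) so generic handling keeps working.
"""


class BioregionsError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(BioregionsError, ValueError):
    """An argument violates a documented precondition."""


class OutOfRangeError(BioregionsError, IndexError):
    """A cell id does not exist on the grid."""


class UnknownSpeciesError(BioregionsError, KeyError):
    """A species label is absent from the declared species universe."""


class EmptyCommunityError(BioregionsError, ValueError):
    """Every cell of a community matrix is empty."""


class UnmatchedTaxonError(BioregionsError, ValueError):
    """Community species missing from the phylogeny."""

    def __init__(self, offenders):
        self.offenders = sorted(offenders)
        super().__init__(
            f"{len(self.offenders)} species not found in tree: "
            + ", ".join(self.offenders[:10])
            + ("..." if len(self.offenders) > 10 else "")
        )


class UndefinedPairError(BioregionsError, ValueError):
    """Dissimilarity requested for a pair of empty assemblages (a=b=c=0)."""


class AlignmentError(BioregionsError, ValueError):
    """Inputs that must share a cell index / grid do not."""


class UndefinedCorrelationError(BioregionsError, ValueError):
    """A correlation is undefined because one input has zero variance."""


class DegenerateInputError(BioregionsError, ValueError):
    """Input carries no signal (e.g. total dissimilarity of zero)."""


class DegenerateScenarioError(BioregionsError, ValueError):
    """A scenario transformation emptied every species range."""


class DegenerateResponseError(BioregionsError, ValueError):
    """Binary response has only one class (e.g. boundary fills its buffer)."""
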