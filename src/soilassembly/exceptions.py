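"""Exception hierarchy shared across the package."""


class SoilAssemblyError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(SoilAssemblyError, ValueError):
    """An argument violates a documented precondition."""


class LabelMismatchError(SoilAssemblyError, KeyError):
    """Sample or taxon labels of two objects do not line up."""


class DegenerateInputError(SoilAssemblyError, ValueError):
    """Input has no variance (or is otherwise statistically degenerate)."""


class CollinearityError(SoilAssemblyError, ValueError):
    """Predictor matrix is rank deficient."""

    def __init__(self, columns, message=None):
        self.columns = list(columns)
        super().__init__(message or f"collinear predictor columns: {self.columns}")


class EmptyResultError(SoilAssemblyError, ValueError):
    """An operation would return an empty object (e.g. all samples dropped)."""


class InvalidTreeError(SoilAssemblyError, ValueError):
    """Phylogeny is unusable (e.g. missing branch lengths)."""
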