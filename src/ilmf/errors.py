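"""Exception hierarchy for ilmf.

All exceptions raised on bad user input derive from :class:`IlmfError`, so
callers (and the CLI) can catch one base class.
"""


class IlmfError(Exception):
    """Base class for all ilmf errors."""


class IdentifierError(IlmfError):
    """Duplicate, missing, or inconsistent row/column identifiers."""


class MatrixParseError(IlmfError):
    """A labeled matrix file could not be parsed (ragged rows, non-numeric cells)."""


class ShapeError(IlmfError):
    """A matrix has the wrong shape (e.g. expected square)."""


class DomainError(IlmfError):
    """Matrix entries violate a domain constraint (e.g. non-binary associations)."""


class AlignmentError(IlmfError):
    """Identifier sets of related matrices do not overlap."""


class DegenerateBandwidthError(IlmfError):
    """Gaussian interaction-profile kernel bandwidth is undefined (all-zero profiles)."""


class DegenerateRowError(IlmfError):
    """An all-zero feature row makes cosine similarity undefined."""


class DimensionError(IlmfError):
    """Requested embedding dimension exceeds the number of entities."""


class ConfigError(IlmfError):
    """A run configuration field violates its constraint."""


class TrainingError(IlmfError):
    """Optimization diverged (non-finite objective or parameters)."""


class SmoothingError(IlmfError):
    """Neighborhood smoothing is impossible (no observed entity at all)."""


class FoldError(IlmfError):
    """Cross-validation folds cannot be constructed (too few positives/negatives)."""


class MetricError(IlmfError):
    """Evaluation metrics are undefined (single-class labels)."""


class GenerationError(IlmfError):
    """Synthetic data generation failed (unreachable density target)."""
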