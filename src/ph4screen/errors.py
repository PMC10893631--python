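"""Exception hierarchy shared across the package."""


class Ph4Error(Exception):
    """Base class for all ph4screen errors."""


class MalformedFileError(Ph4Error):
    """The file could not be parsed at all (bad JSON, bad SDF record, ...)."""


class SchemaViolationError(Ph4Error):
    """Parsed content does not conform to the expected schema or types."""


class DanglingParentError(SchemaViolationError):
    """A projected feature references a parent feature id that does not exist."""


class InvariantError(Ph4Error):
    """A domain-type invariant is violated (radius <= 0, duplicate ids, ...)."""


class PerceptionError(Ph4Error):
    """Feature perception failed (no coordinates, unparsable SMARTS, bad molecule)."""


class AlignmentError(Ph4Error):
    """Rigid alignment is impossible (too few pairs, degenerate geometry)."""


class LabelError(Ph4Error):
    """Test-set label table is invalid (duplicates, unknown labels, empty)."""


class MetricsError(Ph4Error):
    """Metric computation is undefined for the given confusion counts."""


class NoConsistentCountsError(Ph4Error):
    """No integer confusion matrix reproduces the printed rounded metrics."""


class GenerationError(Ph4Error):
    """Synthetic-data generation cannot honour the requested guarantees."""
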