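"""Exception hierarchy.

Everything raised on purpose derives from :class:`WingmorphError`, so CLI
entry points can catch one type and turn it into a diagnostic + nonzero exit.
"""


class WingmorphError(Exception):
    """Base class for all wingmorph errors."""


class InputError(WingmorphError):
    """Bad user input: unreadable file, ROI out of bounds, invalid polygon."""


class ComputationError(WingmorphError):
    """A computation cannot proceed (e.g. zero denominator density)."""


class EmptyResultError(ComputationError):
    """An operation that needs at least one detection found none."""


class TrainingError(WingmorphError):
    """Classifier training precondition or sanity floor violated."""


class SegmentationError(WingmorphError):
    """Segmentation produced no usable intervein regions."""


class GeneratorError(WingmorphError):
    """Synthetic wing parameters are infeasible."""
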