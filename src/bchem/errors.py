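"""Named exceptions raised by the library.

Each error corresponds to a distinct data-integrity or contract violation so
callers can react to (or test for) the specific failure mode.
"""


class BchemError(Exception):
    """Base class for all library errors."""


class EmptyAssociationFileError(BchemError):
    """The association table contains a header but no records (or nothing)."""


class UnknownLabelError(BchemError):
    """A response label is neither 'resistance' nor 'sensitivity'."""


class ConflictingLabelError(BchemError):
    """The same (disease, drug) pair appears with both labels."""


class UnknownNodeError(BchemError):
    """A record or query references a node id absent from the network."""


class MissingAttributeError(BchemError):
    """A registered node has no attribute vector."""


class FoldCountError(BchemError):
    """Requested fold count exceeds the size of one of the label classes."""


class SingleClassError(BchemError):
    """An operation requiring both labels received only one."""
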