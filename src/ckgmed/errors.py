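"""Package-wide exception types."""


class CKGError(Exception):
    """Base class for package errors."""


class FormatError(CKGError):
    """Malformed input table or unknown relation label."""


class StructuralError(CKGError):
    """Graph violates a structural invariant (e.g. a cycle where a DAG is required)."""


class UntestableHypothesis(CKGError):
    """A hypothesis cannot be tested on the available data.

    Mirrors the N/A category of the results summary: raised on missing
    vocabulary, absent support, degenerate or separated analysis tables, or
    failure to find a valid adjustment set.
    """

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason
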