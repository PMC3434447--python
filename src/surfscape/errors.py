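"""Exception hierarchy for the surfscape pipeline.

Stage code raises the most specific class available so the CLI can report
which pipeline stage rejected an input and why.
"""


class SurfscapeError(Exception):
    """Base class for all surfscape errors."""


class ContractError(SurfscapeError, ValueError):
    """An argument violates a documented precondition."""


class ParseError(SurfscapeError, ValueError):
    """A file could not be parsed; message names the offending location."""


class UnsupportedDialectError(ParseError):
    """A file is syntactically valid but uses an unsupported dialect."""


class FragmentLookupError(SurfscapeError, KeyError):
    """No lipophilic fragment value could be resolved for an atom."""

    def __str__(self) -> str:  # KeyError quotes its payload; keep it readable
        return self.args[0] if self.args else ""


class OutOfBoundsError(SurfscapeError, ValueError):
    """A query point lies outside the grid's bounding box."""


class ResolutionError(SurfscapeError, ValueError):
    """Grid/voxel resolution too coarse for the requested geometry."""
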