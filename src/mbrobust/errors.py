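"""Toolkit exception hierarchy.

Two error classes map onto the CLI exit codes: malformed input files raise
:class:`FormatError` (exit 2), violated operation contracts raise
:class:`ContractError` (exit 3).
"""


class MbrobustError(Exception):
    """Base class for all toolkit errors."""


class FormatError(MbrobustError):
    """An input file or sequence does not conform to its declared format."""

    exit_code = 2


class ContractError(MbrobustError):
    """An operation precondition or internal invariant was violated."""

    exit_code = 3
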