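"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: input/format problems exit with 2,
violated data invariants with 3.
"""


class PhylocascadeError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InputFormatError(PhylocascadeError):
    """A file or argument could not be parsed or is inconsistent with other inputs."""

    exit_code = 2


class InvariantViolation(PhylocascadeError):
    """A data structure violates one of its declared invariants."""

    exit_code = 3
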