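"""Exception hierarchy; the CLI maps these onto stable exit codes."""


class NacselError(Exception):
    """Base class for all package errors."""

    exit_code = 4


class ValidationError(NacselError):
    """Bad configuration or invalid parameter values (exit 2)."""

    exit_code = 2


class InputError(NacselError):
    """Unreadable or unparsable input file (exit 3)."""

    exit_code = 3


class TopologyError(NacselError):
    """Inconsistent atom topology across models, or a malformed bond graph."""

    exit_code = 3


class GeometryError(NacselError):
    """Degenerate or infeasible geometry (exit 4)."""

    exit_code = 4
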