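"""Exception hierarchy shared by all pipeline stages.

Each class carries the process exit code the command-line layer maps it to:
2 for configuration problems, 3 for malformed or impossible input data,
4 for analysis/fit failures.
"""


class RLTError(Exception):
    """Base class for all rltkit errors."""

    exit_code = 1


class ConfigError(RLTError):
    """Missing files, malformed run configuration, bad option combinations."""

    exit_code = 2


class InputError(RLTError, ValueError):
    """Input values that violate a stage's preconditions."""

    exit_code = 3


class DataError(InputError):
    """Structurally invalid data files (unparseable worksheets, tables)."""

    exit_code = 3


class AnalysisError(RLTError):
    """A computation that cannot be carried out on otherwise valid input."""

    exit_code = 4


class FitError(AnalysisError):
    """Nonlinear regression failed to converge or the model is unidentifiable."""

    exit_code = 4
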