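"""Exception types shared across the package."""


class SterolOrderError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SterolOrderError):
    """Invalid species map or run configuration."""


class FormatError(SterolOrderError):
    """Malformed coordinate file."""

    def __init__(self, message: str, path=None, line: int | None = None):
        prefix = ""
        if path is not None:
            prefix += f"{path}"
        if line is not None:
            prefix += f":{line}"
        super().__init__(f"{prefix}: {message}" if prefix else message)
        self.path = path
        self.line = line


class DegenerateGeometryError(SterolOrderError):
    """Geometric construction is undefined for the given points."""


class PackingError(SterolOrderError):
    """Dart-throwing placement failed to reach the requested density."""

    def __init__(self, message: str, achieved: int | None = None):
        super().__init__(message)
        self.achieved = achieved


class AnalysisError(SterolOrderError):
    """An analysis precondition is violated (empty selections etc.)."""
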