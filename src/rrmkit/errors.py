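"""Exception hierarchy shared by all rrmkit modules."""


class RRMError(Exception):
    """Base class for all rrmkit errors."""


class ValidationError(RRMError, ValueError):
    """Input violates a documented precondition or contract."""


class DomainError(RRMError, ValueError):
    """Numeric argument lies outside its mathematical domain."""


class NotFoundError(RRMError, KeyError):
    """A named resource (scale, super family, preset) does not exist."""

    def __str__(self) -> str:  # KeyError quotes its message; undo that
        return self.args[0] if self.args else ""


class IntegrityError(RRMError):
    """A bundled data file failed its checksum verification."""
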