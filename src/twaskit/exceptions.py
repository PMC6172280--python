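"""Exception types shared across the pipeline."""


class ConfigError(ValueError):
    """A configuration problem: missing column, bad mapping, invalid option."""


class ValidationError(ValueError):
    """Input data violates an invariant (e.g. duplicated SNP identifiers)."""


class EmptyResultError(RuntimeError):
    """An operation removed or matched every record; carries a breakdown."""

    def __init__(self, message: str, breakdown: dict | None = None):
        super().__init__(message)
        self.breakdown = dict(breakdown or {})


class EmptyRegionError(ValueError):
    """A genomic region query returned no SNPs."""


class DegenerateModelError(ValueError):
    """A gene model has (numerically) zero predicted-expression variance."""
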