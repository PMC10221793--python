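"""Exception hierarchy.

All package errors derive from :class:`CpgSigError` so callers can catch
one base class; subclasses distinguish config, data-format, and numeric
failure modes (the CLI maps them to distinct exit codes).
"""


class CpgSigError(Exception):
    """Base class for all errors raised by cpgsig."""


class FormatError(CpgSigError):
    """A table could not be parsed: duplicate ids, bad header, non-numeric cell."""


class BetaRangeError(CpgSigError):
    """A methylation value lies outside the closed interval [0, 1]."""

    def __init__(self, cpg_id: str, sample_id: str, value: float):
        self.cpg_id = cpg_id
        self.sample_id = sample_id
        self.value = value
        super().__init__(
            f"beta value {value!r} for CpG {cpg_id!r}, sample {sample_id!r} "
            f"is outside [0, 1]"
        )


class QCError(CpgSigError):
    """Quality control removed everything, or its inputs were degenerate."""


class ImputationError(CpgSigError):
    """A CpG has no non-missing value among the reference samples."""

    def __init__(self, cpg_ids):
        self.cpg_ids = list(cpg_ids)
        super().__init__(
            f"{len(self.cpg_ids)} CpG(s) entirely missing in reference columns: "
            f"{self.cpg_ids[:10]}"
        )


class ConfigError(CpgSigError):
    """An invalid or infeasible configuration value."""


class SelectionError(CpgSigError):
    """A feature-selection request that cannot be satisfied."""


class EvaluationError(CpgSigError):
    """Model training or evaluation failed on degenerate inputs."""
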