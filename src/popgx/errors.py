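"""Exception hierarchy for popgx."""


class PopgxError(Exception):
    """Base class for all popgx errors."""


class TableError(PopgxError, ValueError):
    """Malformed or inconsistent haplotype translation table."""


class PanelError(PopgxError, ValueError):
    """Malformed sample panel (population map) file."""


class GenotypeError(PopgxError, ValueError):
    """Genotype extraction failure (no resolvable variants, unreadable VCF)."""


class SimulationError(PopgxError, ValueError):
    """Invalid synthetic-cohort configuration."""


class PipelineError(PopgxError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
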