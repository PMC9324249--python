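"""Exception types shared across the pipeline stages."""


class InvalidArgumentError(ValueError):
    """An operation received arguments violating its contract."""


class SimulationError(RuntimeError):
    """The synthetic cohort generator could not produce a valid simulation."""


class DegenerateSampleError(ValueError):
    """A statistical routine received a sample it cannot handle (e.g. zero variance)."""


class MissingStageInputError(FileNotFoundError):
    """A pipeline stage is missing a cached input from an earlier stage."""

    def __init__(self, stage: str, missing: str):
        self.stage = stage
        self.missing = missing
        super().__init__(f"stage '{stage}' requires missing input: {missing}")
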