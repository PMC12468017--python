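"""Package-specific exceptions."""


class LnsimError(Exception):
    """Base class for all lnsim errors."""


class PlacementError(LnsimError):
    """The grid is too small to place the requested disjoint node regions."""


class MatchingInfeasibleError(LnsimError):
    """The control pool cannot supply k distinct controls per patient."""


class UndefinedMotionError(LnsimError):
    """Motion summaries need at least two timepoints."""


class DegenerateTemplateError(LnsimError):
    """The lesion-network template is constant over the profile support."""


class StageError(LnsimError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
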