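"""Exception hierarchy shared by all optoxr modules."""


class OptoxrError(Exception):
    """Base class for all package-specific errors."""


class AlphabetError(OptoxrError, ValueError):
    """Sequence contains a symbol outside the declared alphabet."""


class LengthError(OptoxrError, ValueError):
    """Sequence too short for the requested operation."""


class ParseError(OptoxrError, ValueError):
    """Malformed input file; message names the offending line when known."""


class BoundsError(OptoxrError, IndexError):
    """Row or position outside an alignment's coordinate range."""


class ParameterError(OptoxrError, ValueError):
    """Tunable parameter outside its documented range."""


class TopologyError(OptoxrError, ValueError):
    """Topology call failed or a topology map violates its invariants.

    Carries the candidate TM intervals (when available) so the caller can
    adjust the calling threshold and retry.
    """

    def __init__(self, message, candidates=None):
        super().__init__(message)
        self.candidates = candidates


class AssemblyError(OptoxrError, ValueError):
    """Chimera assembly failed (e.g. a swapped segment is empty)."""


class TableError(OptoxrError, ValueError):
    """Codon-usage table invalid or missing an amino acid."""


class UnresolvableSiteError(OptoxrError, ValueError):
    """A restriction site cannot be removed by synonymous substitution."""

    def __init__(self, message, position=None):
        super().__init__(message)
        self.position = position


class FrameError(OptoxrError, ValueError):
    """Reading-frame violation (e.g. linker length not divisible by 3)."""


class InputError(OptoxrError, ValueError):
    """Semantically invalid input to an operation."""


class CassetteError(OptoxrError, ValueError):
    """Expression-cassette invariant violated; message lists positions."""

    def __init__(self, message, positions=None):
        super().__init__(message)
        self.positions = positions or []


class DesignFailureError(OptoxrError, RuntimeError):
    """No primer candidate passed the specificity screen.

    ``diagnostics`` holds the best rejected candidates with the reason each
    was discarded.
    """

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class ConfigError(OptoxrError, ValueError):
    """Unknown configuration key or type mismatch."""


class StageError(OptoxrError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage, message):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
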