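"""Exception hierarchy for the analysis pipeline.

Each CLI stage maps these onto documented exit codes: parse errors -> 2,
non-bilayer states -> 3, any other stage failure -> 4.
"""


class CGMemError(Exception):
    """Base class for all package errors."""


class FrameParseError(CGMemError):
    """A coordinate file could not be parsed under its declared format."""


class ClassificationError(CGMemError):
    """A (residue, bead) pair has no entry in the bead classification table."""

    def __init__(self, pairs):
        self.pairs = sorted(set(pairs))
        listing = ", ".join(f"({r!r}, {b!r})" for r, b in self.pairs[:10])
        more = "" if len(self.pairs) <= 10 else f" (+{len(self.pairs) - 10} more)"
        super().__init__(f"unclassifiable (residue, bead) pairs: {listing}{more}")


class NonBilayerError(CGMemError):
    """The phosphate proximity graph does not resolve into two leaflets."""

    def __init__(self, n_components):
        self.n_components = n_components
        super().__init__(
            f"phosphate proximity graph has {n_components} large component(s); "
            "expected exactly 2 (upper and lower leaflet)"
        )


class StageError(CGMemError):
    """An analysis stage failed; carries the stage name for the run manifest."""

    def __init__(self, stage, cause):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")
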