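"""Exception types shared across modules."""


class AlignmentError(ValueError):
    """Sample or taxon identifiers disagree between two inputs."""


class TableParseError(ValueError):
    """A tabular input file is malformed (non-numeric cell, bad header...)."""


class ConfoundingError(ValueError):
    """Two model factors are perfectly confounded (1:1 level mapping)."""


class NoTransitionError(RuntimeError):
    """The random-matrix threshold scan found no Poisson-consistent window."""
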