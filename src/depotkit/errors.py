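"""Exception types shared across the toolkit."""


class DepotKitError(Exception):
    """Base class for all depotkit errors."""


class InvalidSpec(DepotKitError):
    """A generator or analysis specification violates its invariants."""


class NoDepotFound(DepotKitError):
    """Segmentation or a metric was requested on an empty region."""


class EmptyReconstruction(DepotKitError):
    """No tracked frame intersected the requested output grid."""


class NoDecayPhase(DepotKitError):
    """A log-linear window contains no decaying concentration segment."""


class UndefinedPK(DepotKitError):
    """Pharmacokinetic summary requested on degenerate data (e.g. all-zero)."""
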