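"""Exception hierarchy shared across the toolkit."""


class ArgSwitchError(Exception):
    """Base class for all toolkit errors."""


class PDBParseError(ArgSwitchError):
    """A structure file could not be parsed (carries the offending line number)."""


class EmptyInputError(ArgSwitchError):
    """An operation received zero atoms, frames or observations."""


class ShapeError(ArgSwitchError):
    """Coordinate/topology dimensions disagree."""


class SelectionError(ArgSwitchError):
    """An atom selection could not be resolved against a topology."""


class SelectionSyntaxError(SelectionError):
    """The selection expression violates the grammar (carries the position)."""


class DegenerateSelectionError(ArgSwitchError):
    """A superposition selection is collinear or otherwise rank-deficient."""


class DataCompletenessError(ArgSwitchError):
    """A comparison is missing a required state, timepoint or replicate."""
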