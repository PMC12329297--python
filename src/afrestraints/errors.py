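"""Exception hierarchy for afrestraints."""


class AFRestraintsError(Exception):
    """Base class for all afrestraints errors."""


class StructureParseError(AFRestraintsError):
    """A coordinate file could not be parsed under the named standard."""


class EmptyStructureError(AFRestraintsError):
    """A parsed structure contains no atoms."""


class FormatError(AFRestraintsError):
    """The coordinate-file format could not be determined or is unsupported."""


class UnknownChainError(AFRestraintsError):
    """A requested chain identifier is absent from the structure."""


class RenumberCollisionError(AFRestraintsError):
    """Residue renumbering would produce duplicate atom keys."""


class ConfigError(AFRestraintsError):
    """A restraint configuration violates its invariants."""


class WriterError(AFRestraintsError):
    """An output file cannot be produced (bad records or residue numbering)."""
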