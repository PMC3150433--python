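class DegenkitError(Exception):
    """Base class for all toolkit errors."""


class AlignmentError(DegenkitError):
    """Malformed alignment: ragged rows, duplicate taxa, bad symbols."""


class CharsetError(DegenkitError):
    """Character-set metadata problem: out-of-bounds or unknown set."""


class FrameError(DegenkitError):
    """Reading-frame violation: a fragment is not a whole number of codons."""
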