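class YplexError(Exception):
    """Base class for all package errors."""


class PanelError(YplexError):
    """Malformed or inconsistent panel definition."""


class TreeError(YplexError):
    """Phylogeny construction or lookup failure."""


class EncodingError(YplexError):
    """A raw allele that matches neither the ancestral nor the derived state."""


class CallingError(YplexError):
    """Fluorescence plate or assay that cannot be called."""


class QCError(YplexError):
    """Quality-control computation on a degenerate input."""


class SimulationError(YplexError):
    """Invalid simulation configuration."""
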