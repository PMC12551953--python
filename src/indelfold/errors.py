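"""Exception hierarchy for indelfold.

All library errors derive from :class:`IndelfoldError` so callers can catch
one base class; the subclasses mirror the distinct failure modes of the
pipeline (bad sequence alphabet, out-of-bounds coordinates, a binding site
overlapping the deleted interval, engine configuration, degenerate affinity
input, unparseable variant files).
"""


class IndelfoldError(Exception):
    """Base class for all indelfold errors."""


class AlphabetError(IndelfoldError, ValueError):
    """Sequence contains characters outside the RNA alphabet A/C/G/U."""


class BoundsError(IndelfoldError, IndexError):
    """A coordinate or interval lies outside the sequence it refers to."""


class OverlapError(IndelfoldError, ValueError):
    """A binding site overlaps the deleted interval of an indel."""


class ConfigError(IndelfoldError, ValueError):
    """Unknown engine, scenario, or otherwise invalid configuration."""


class EngineUnavailableError(ConfigError):
    """The requested folding engine cannot be loaded in this environment."""


class DegenerateAffinityError(IndelfoldError, ValueError):
    """No 7-mer in the sequence has nonzero affinity-weighted accessibility."""


class NoSharedSiteError(IndelfoldError, ValueError):
    """Every candidate 7-mer in a binding region is destroyed by the indel;
    site identification has no shared 7-mer left to rank."""


class GuardError(IndelfoldError, ValueError):
    """An exponential-cost oracle was invoked above its size guard."""


class ParseError(IndelfoldError, ValueError):
    """A variant/region file could not be parsed; message carries context."""


class SkipRegion(IndelfoldError):
    """Signal: a region cannot be used (e.g. too close to the 5' end) and
    should be dropped with a logged reason rather than aborting a run."""
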