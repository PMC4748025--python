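"""Exception hierarchy shared across proxsoc modules."""


class ProxsocError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(ProxsocError):
    """A delimited-text file does not match its documented schema."""


class RecordLinkError(ProxsocError):
    """A record references an id that does not resolve against the roster."""


class InvariantError(ProxsocError):
    """An in-memory record violates a structural invariant."""


class ConfigurationError(ProxsocError):
    """A configuration value is out of range or infeasible."""


class EmptyNetworkError(ProxsocError):
    """No scans fall inside the requested window."""


class UndefinedMetricError(ProxsocError):
    """A network metric is undefined for the given graph (e.g. < 2 nodes)."""


class PartitionError(ProxsocError):
    """A partition does not cover every node of the network."""
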