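"""Exception hierarchy shared by all pipeline stages.

The CLI maps these onto distinct exit codes so callers can tell a
malformed input file from a mis-used API from internally inconsistent
data without parsing stderr.
"""


class NcceError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(NcceError):
    """An on-disk file violates its format contract (bad column, bad
    residue, arithmetic mismatch...). Messages cite the offending line
    or record where possible."""


class UsageError(NcceError):
    """The API was called against its preconditions (mismatched lengths,
    wrong stage order, unknown role...)."""


class DataConsistencyError(NcceError):
    """Two inputs that must describe the same genome disagree (e.g. a
    chain names a chromosome absent from the target FASTA)."""


class ConfigError(NcceError):
    """A simulation or run configuration is infeasible or contradictory."""
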