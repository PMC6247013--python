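"""Exception types shared across the package."""


class KmernetError(Exception):
    """Base class for all package-specific errors."""


class ConfigMismatch(KmernetError):
    """Two objects built under different k / strand policy / mode settings."""


class AnnotationMissing(KmernetError):
    """A genome view requiring annotation was requested for an unannotated genome."""


class EmptyViewError(KmernetError):
    """A genome view contains no sequence (e.g. plasmid_only without plasmids)."""


class DomainError(KmernetError, ValueError):
    """A numeric argument lies outside its mathematical domain."""


class FastaParseError(KmernetError):
    """Malformed or inconsistent FASTA input."""


class TaxonomyError(KmernetError):
    """Missing or inconsistent taxonomy information."""
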