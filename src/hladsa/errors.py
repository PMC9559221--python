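"""Exception hierarchy shared across the package."""


class HlaError(Exception):
    """Base class for all hladsa errors."""


class AlleleParseError(HlaError, ValueError):
    """An allele string does not follow LOCUS*F1[:F2] nomenclature."""


class ResolutionError(HlaError, ValueError):
    """An operation required two-field resolution but got one-field input."""


class MissingLocusError(HlaError, ValueError):
    """A required locus is untyped/unavailable; the message names the locus."""


class RegistryLookupError(HlaError, KeyError):
    """An allele has no entry in the eplet registry."""


class ImputationError(HlaError, ValueError):
    """The observed genotype is inconsistent with the haplotype panel."""


class AssayError(HlaError, ValueError):
    """Malformed or insufficient single-antigen bead input."""


class FixtureError(HlaError, ValueError):
    """A bundled fixture table violates its schema."""
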