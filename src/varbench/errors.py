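"""Exception types shared across the package."""


class VarbenchError(Exception):
    """Base class for all package-specific errors."""


class FormatError(VarbenchError, ValueError):
    """An input file violates its format contract (bad BED bounds,
    inconsistent refFlat exon counts, malformed VCF line, ...)."""


class ConsistencyError(VarbenchError, ValueError):
    """Inputs disagree with each other, e.g. a variant's REF allele does
    not match the reference sequence at its position."""


class DomainError(VarbenchError, ValueError):
    """An operation was asked outside its domain (empty target set,
    variant outside the gene span, n = 0 trials, ...)."""


class GenerationError(VarbenchError, RuntimeError):
    """The synthetic-data generator could not satisfy its configuration
    (e.g. more features than fit on the chromosomes)."""


class ClusterTooComplexError(VarbenchError, RuntimeError):
    """A variant cluster exceeds the heterozygous-site cap of the
    exhaustive haplotype matcher."""
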