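"""Exception hierarchy shared by all genomekit modules."""


class GenomekitError(Exception):
    """Base class for all errors raised by genomekit."""


class ContractError(GenomekitError):
    """A documented precondition of an operation was violated by the caller."""


class ParseError(GenomekitError):
    """Malformed input data (bad SAM field, inconsistent FASTQ record, ...)."""


class UsageError(GenomekitError):
    """Bad command-line usage: unknown/untypable argument, missing input file,
    or an output collision without --force."""
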