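"""Exception hierarchy shared across the toolkit."""


class LeakguardError(Exception):
    """Base class for all toolkit errors."""


class VcfParseError(LeakguardError):
    """A VCF data line could not be parsed; message names the 1-based line number."""


class InvalidKeyError(LeakguardError, ValueError):
    """A variant key violates its invariants (bad position, allele or chromosome)."""


class ConfigurationError(LeakguardError):
    """An unsupported protocol, cipher or parameter combination was requested."""


class StoreError(LeakguardError):
    """Base class for encrypted-store failures."""


class StoreFormatError(StoreError):
    """The file is not a recognizable store (bad magic, version or layout)."""


class BadPassphraseError(StoreError):
    """The passphrase does not match the store; no digests are returned."""


class StoreIntegrityError(StoreError):
    """The store is truncated or its ciphertext fails authentication."""


class SessionClosedError(LeakguardError):
    """A filtering session was used after close()."""


class UnknownTumourError(LeakguardError, KeyError):
    """A session request named a tumour label with no loaded store."""


class ConstantInputError(LeakguardError, ValueError):
    """Rank correlation is undefined because one input vector is constant."""


class CapacityError(LeakguardError, ValueError):
    """A simulation requested more variant sites than the genome can hold."""
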