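"""Exception hierarchy for pbwtkit."""


class PbwtError(Exception):
    """Base class for all pbwtkit errors."""


class PanelError(PbwtError):
    """Invalid haplotype panel or panel input (non-binary alleles, ragged rows, ...)."""


class CodecError(PbwtError):
    """Run-length codec violation (reserved unit code, zero count, length mismatch)."""


class ContainerError(PbwtError):
    """Malformed .pbwt container (bad magic, version, checksum, truncation)."""


class IntegrityError(PbwtError):
    """Internal inconsistency in a PBWT index (corrupted column payload, bad counts)."""
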