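"""Exception hierarchy. Input/format problems exit the CLI with code 2."""


class DisconsError(Exception):
    """Base class for all package errors."""


class FormatError(DisconsError):
    """A file or record violates the expected format."""


class InputError(DisconsError):
    """Missing or inconsistent user input (files, chain ids, specs)."""
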