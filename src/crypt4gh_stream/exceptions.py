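"""Exception taxonomy.

Parsing problems (bad magic, truncated structures) are kept distinct from
cryptographic failures (bad MAC, wrong passphrase), which are again distinct
from "the file is fine but none of its header packets are addressed to this
key" — callers and the CLI map these to different exit codes.
"""


class Crypt4GHError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(Crypt4GHError):
    """Malformed container, key file, or header structure."""


class TruncationError(FormatError):
    """The byte stream ended in the middle of a structure."""


class AuthenticationError(Crypt4GHError):
    """A MAC failed to verify (tampered data or wrong passphrase)."""


class NoAccessError(Crypt4GHError):
    """No header packet could be decrypted with the supplied key."""
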