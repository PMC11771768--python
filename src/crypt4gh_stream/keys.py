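"""X25519 key pairs and the armored key-file format.

Public keys are 32 raw bytes, base64-armored between
``-----BEGIN CRYPT4GH PUBLIC KEY-----`` banner lines. Private keys use the
``c4gh-v1`` layout: the magic word followed by 2-byte big-endian
length-prefixed strings — KDF name, KDF options (4-byte big-endian rounds ‖
salt), cipher name, key blob, optional comment. A passphrase-protected blob
is 12-byte nonce ‖ ChaCha20-IETF-Poly1305 ciphertext of the 32-byte secret
scalar under the KDF-derived key, so a wrong passphrase is always detected
by MAC failure rather than yielding garbage.

Writing supports the scrypt KDF (interactive-strength fixed cost:
N=2^14, r=8, p=1) and unprotected ``none``; reading additionally accepts
bcrypt (OpenBSD bcrypt_pbkdf). KDF parameters are always taken from the
file on read, never assumed. Passphrases are encoded as UTF-8 with no
normalization. The secret scalar is stored exactly as produced; X25519
clamping happens at use time.
"""

from __future__ import annotations

import base64
import hashlib
import os
import re
from dataclasses import dataclass
from collections.abc import Callable

from ._crypto.aead import open_, seal
from ._crypto.bcrypt_kdf import bcrypt_pbkdf
from ._crypto.x25519 import scalarmult_base
from .exceptions import AuthenticationError, FormatError

__all__ = [
    "KeyPair",
    "generate_keypair",
    "derive_public",
    "write_private_key",
    "read_private_key",
    "write_public_key",
    "read_public_key",
    "save_key_file",
]

_MAGIC = b"c4gh-v1"
_PRIVATE_BEGIN = "-----BEGIN CRYPT4GH PRIVATE KEY-----"
_PRIVATE_END = "-----END CRYPT4GH PRIVATE KEY-----"
_PUBLIC_BEGIN = "-----BEGIN CRYPT4GH PUBLIC KEY-----"
_PUBLIC_END = "-----END CRYPT4GH PUBLIC KEY-----"

_SCRYPT_N = 1 << 14
_SCRYPT_R = 8
_SCRYPT_P = 1
_SALT_LEN = 16
_NONCE_LEN = 12

Rng = Callable[[int], bytes]


@dataclass(frozen=True)
class KeyPair:
    """X25519 key pair for the envelope's outer (asymmetric) layer."""

    public_key: bytes
    secret_key: bytes

    def __post_init__(self) -> None:
        if len(self.public_key) != 32 or len(self.secret_key) != 32:
            raise ValueError("X25519 keys must be exactly 32 bytes")


def derive_public(secret_key: bytes) -> bytes:
    """Public key for a 32-byte secret scalar (clamped at use)."""
    if len(secret_key) != 32:
        raise FormatError("secret key must be exactly 32 bytes")
    return scalarmult_base(secret_key)


def generate_keypair(rng: Rng = os.urandom) -> KeyPair:
    """Fresh X25519 key pair from 32 bytes of entropy.

    A short read from the entropy source is a hard error; there is no
    fallback source.
    """
    secret = rng(32)
    if not isinstance(secret, bytes) or len(secret) != 32:
        raise RuntimeError("entropy source failed to deliver 32 bytes")
    return KeyPair(public_key=derive_public(secret), secret_key=secret)


def _pack_string(value: bytes) -> bytes:
    if len(value) >= 1 << 16:
        raise ValueError("string too long for key-file encoding")
    return len(value).to_bytes(2, "big") + value


class _Unpacker:
    def __init__(self, data: bytes):
        self.data = data
        self.pos = 0

    def string(self, what: str) -> bytes:
        if self.pos + 2 > len(self.data):
            raise FormatError(f"key file truncated while reading {what}")
        n = int.from_bytes(self.data[self.pos : self.pos + 2], "big")
        self.pos += 2
        if self.pos + n > len(self.data):
            raise FormatError(f"key file truncated while reading {what}")
        out = self.data[self.pos : self.pos + n]
        self.pos += n
        return out

    @property
    def exhausted(self) -> bool:
        return self.pos >= len(self.data)


def _armor(begin: str, payload: bytes, end: str) -> bytes:
    return (begin + "\n" + base64.b64encode(payload).decode() + "\n" + end + "\n").encode()


def _dearmor(data: bytes, begin: str, end: str) -> bytes:
    try:
        text = data.decode("ascii")
    except UnicodeDecodeError as exc:
        raise FormatError("key file is not ASCII armored text") from exc
    match = re.search(re.escape(begin) + r"(.*?)" + re.escape(end), text, re.DOTALL)
    if match is None:
        raise FormatError(f"missing {begin.strip('-').strip()} armor")
    body = re.sub(r"\s+", "", match.group(1))
    try:
        return base64.b64decode(body, validate=True)
    except ValueError as exc:
        raise FormatError("invalid base64 in armored key") from exc


def _kdf(kdf_name: bytes, passphrase: bytes, salt: bytes, rounds: int) -> bytes:
    if kdf_name == b"scrypt":
        # rounds field is present in the file but carries no meaning for scrypt
        return hashlib.scrypt(
            passphrase, salt=salt, n=_SCRYPT_N, r=_SCRYPT_R, p=_SCRYPT_P, dklen=32
        )
    if kdf_name == b"bcrypt":
        return bcrypt_pbkdf(passphrase, salt, 32, rounds)
    raise FormatError(f"unsupported KDF {kdf_name!r}")


def write_private_key(
    pair: KeyPair,
    passphrase: str | bytes | None,
    kdf_name: str = "scrypt",
    kdf_rounds: int | None = None,
    comment: str | bytes | None = None,
    rng: Rng = os.urandom,
) -> bytes:
    """Armored private-key file contents.

    With a passphrase the secret is locked under the named KDF (write side
    supports scrypt); without one ``kdf_name`` must be "none".
    """
    kdf = kdf_name.encode() if isinstance(kdf_name, str) else kdf_name
    if passphrase is None:
        if kdf != b"none":
            raise ValueError("a passphrase is required unless kdf_name is 'none'")
        body = (
            _MAGIC
            + _pack_string(b"none")
            + _pack_string(b"")
            + _pack_string(b"none")
            + _pack_string(pair.secret_key)
        )
    else:
        if kdf == b"none":
            raise ValueError("kdf_name 'none' conflicts with a supplied passphrase")
        if kdf != b"scrypt":
            raise ValueError(f"writing supports the scrypt KDF only, not {kdf.decode()!r}")
        if isinstance(passphrase, str):
            passphrase = passphrase.encode("utf-8")
        rounds = 0 if kdf_rounds is None else kdf_rounds
        salt = rng(_SALT_LEN)
        key = _kdf(kdf, passphrase, salt, rounds)
        nonce = rng(_NONCE_LEN)
        blob = nonce + seal(key, nonce, pair.secret_key)
        body = (
            _MAGIC
            + _pack_string(kdf)
            + _pack_string(rounds.to_bytes(4, "big") + salt)
            + _pack_string(b"chacha20_poly1305")
            + _pack_string(blob)
        )
    if comment is not None:
        body += _pack_string(comment.encode() if isinstance(comment, str) else comment)
    return _armor(_PRIVATE_BEGIN, body, _PRIVATE_END)


def read_private_key(data: bytes, passphrase: str | bytes | None = None) -> bytes:
    """Recover the 32-byte secret scalar from an armored private-key file."""
    payload = _dearmor(data, _PRIVATE_BEGIN, _PRIVATE_END)
    if not payload.startswith(_MAGIC):
        raise FormatError("bad private-key magic (expected c4gh-v1)")
    unpacker = _Unpacker(payload[len(_MAGIC) :])
    kdf_name = unpacker.string("KDF name")
    kdf_options = unpacker.string("KDF options")
    cipher_name = unpacker.string("cipher name")
    blob = unpacker.string("key blob")

    if cipher_name == b"none":
        if len(blob) != 32:
            raise FormatError(f"unprotected secret key must be 32 bytes, got {len(blob)}")
        return blob
    if cipher_name != b"chacha20_poly1305":
        raise FormatError(f"unsupported private-key cipher {cipher_name!r}")
    if kdf_name == b"none":
        raise FormatError("encrypted key blob with no KDF")
    if passphrase is None:
        raise AuthenticationError("private key is passphrase-protected; none supplied")
    if isinstance(passphrase, str):
        passphrase = passphrase.encode("utf-8")
    if len(kdf_options) < 4 + 1:
        raise FormatError("KDF options field too short for rounds and salt")
    rounds = int.from_bytes(kdf_options[:4], "big")
    salt = kdf_options[4:]
    key = _kdf(kdf_name, passphrase, salt, rounds)
    if len(blob) < _NONCE_LEN + 16:
        raise FormatError("encrypted key blob too short")
    secret = open_(key, blob[:_NONCE_LEN], blob[_NONCE_LEN:])
    if secret is None:
        raise AuthenticationError("wrong passphrase for private key")
    if len(secret) != 32:
        raise FormatError(f"decrypted secret key must be 32 bytes, got {len(secret)}")
    return secret


def write_public_key(public_key: bytes) -> bytes:
    if len(public_key) != 32:
        raise ValueError("public key must be exactly 32 bytes")
    return _armor(_PUBLIC_BEGIN, public_key, _PUBLIC_END)


def read_public_key(data: bytes) -> bytes:
    payload = _dearmor(data, _PUBLIC_BEGIN, _PUBLIC_END)
    if len(payload) != 32:
        raise FormatError(f"public key payload must be 32 bytes, got {len(payload)}")
    return payload


def save_key_file(path: str | os.PathLike, content: bytes, private: bool = False) -> None:
    """Write a key file; private keys get 0600 permissions where supported."""
    with open(path, "wb") as handle:
        handle.write(content)
    if private:
        try:
            os.chmod(path, 0o600)
        except OSError:  # pragma: no cover - platform dependent
            pass
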