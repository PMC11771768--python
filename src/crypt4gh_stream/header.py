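"""Container header: per-recipient encrypted packets.

Wire layout (all integers little-endian):

    magic ``crypt4gh`` (8 bytes) ‖ uint32 version=1 ‖ uint32 packet count ‖
    packets, each:
        uint32 packet length (self-inclusive) ‖
        uint32 header-encryption method (0 = X25519-ChaCha20-IETF-Poly1305) ‖
        32-byte writer public key ‖ 12-byte nonce ‖ ciphertext ‖ 16-byte MAC

A decrypted packet payload starts with a uint32 packet type:
type 0 carries the data-encryption parameters (uint32 method=0 ‖ 32-byte
symmetric data key), type 1 an edit list (uint32 count ‖ count × uint64).

The per-packet key comes from an X25519 exchange between the writer and one
recipient: with q the shared point, both sides compute
BLAKE2b-512(q ‖ reader_pk ‖ writer_pk) and use its second 32 bytes — the
writer's server-role receive key equals the reader's client-role transmit
key, so writer-encrypt / reader-decrypt round-trips. A recipient recognises
"their" packets purely by MAC success; packets for other recipients are a
normal non-error case.
"""

from __future__ import annotations

import io
import logging
import os
import struct
from dataclasses import dataclass
from hashlib import blake2b
from collections.abc import Callable, Sequence

from ._crypto.aead import TAG_LEN, open_, seal
from ._crypto.x25519 import x25519
from .editlist import validate_edit_list
from .exceptions import FormatError, NoAccessError, TruncationError
from .keys import KeyPair

logger = logging.getLogger(__name__)

__all__ = [
    "MAGIC",
    "VERSION",
    "HEADER_ENCRYPTION_X25519_CHACHA20_POLY1305",
    "DATA_ENCRYPTION_CHACHA20_POLY1305",
    "PACKET_TYPE_DATA_ENCRYPTION",
    "PACKET_TYPE_EDIT_LIST",
    "HeaderPacket",
    "ParsedHeader",
    "derive_packet_key",
    "encrypt_packet",
    "decrypt_packet",
    "build_header",
    "parse_header",
    "read_header_bytes",
    "reencrypt_header",
]

MAGIC = b"crypt4gh"
VERSION = 1
HEADER_ENCRYPTION_X25519_CHACHA20_POLY1305 = 0
DATA_ENCRYPTION_CHACHA20_POLY1305 = 0
PACKET_TYPE_DATA_ENCRYPTION = 0
PACKET_TYPE_EDIT_LIST = 1

_NONCE_LEN = 12
_PACKET_FIXED = 4 + 4 + 32 + _NONCE_LEN  # before ciphertext+MAC

Rng = Callable[[int], bytes]


@dataclass(frozen=True)
class HeaderPacket:
    """One encrypted header packet as it appears on the wire."""

    method: int
    writer_public_key: bytes
    nonce: bytes
    encrypted_payload: bytes  # ciphertext ‖ 16-byte MAC

    @property
    def packet_length(self) -> int:
        return _PACKET_FIXED + len(self.encrypted_payload)

    def serialize(self) -> bytes:
        return b"".join(
            (
                struct.pack("<II", self.packet_length, self.method),
                self.writer_public_key,
                self.nonce,
                self.encrypted_payload,
            )
        )


@dataclass(frozen=True)
class ParsedHeader:
    """Everything a recipient recovers from a container header."""

    data_keys: tuple[bytes, ...]
    edit_list: tuple[int, ...] | None
    header_length: int


def derive_packet_key(
    own_secret: bytes, own_public: bytes, peer_public: bytes, role: str
) -> bytes:
    """Symmetric key protecting one header packet.

    ``role`` is "writer" when own_* belongs to the container writer and
    peer is the recipient, "reader" for the converse; both evaluate to the
    same 32 bytes.
    """
    if role == "writer":
        writer_pk, reader_pk = own_public, peer_public
    elif role == "reader":
        writer_pk, reader_pk = peer_public, own_public
    else:
        raise ValueError(f"role must be 'writer' or 'reader', got {role!r}")
    shared = x25519(own_secret, peer_public)
    if shared == bytes(32):
        raise ValueError("X25519 produced an all-zero shared secret (low-order peer key)")
    digest = blake2b(shared + reader_pk + writer_pk, digest_size=64).digest()
    return digest[32:]


def encrypt_packet(
    payload: bytes, writer: KeyPair, reader_public: bytes, nonce: bytes
) -> HeaderPacket:
    if len(nonce) != _NONCE_LEN:
        raise ValueError("packet nonce must be 12 bytes")
    key = derive_packet_key(writer.secret_key, writer.public_key, reader_public, "writer")
    return HeaderPacket(
        method=HEADER_ENCRYPTION_X25519_CHACHA20_POLY1305,
        writer_public_key=writer.public_key,
        nonce=nonce,
        encrypted_payload=seal(key, nonce, payload),
    )


def decrypt_packet(packet: HeaderPacket, reader: KeyPair) -> bytes | None:
    """Decrypted payload, or None when the packet is not for this key."""
    if packet.method != HEADER_ENCRYPTION_X25519_CHACHA20_POLY1305:
        return None
    key = derive_packet_key(
        reader.secret_key, reader.public_key, packet.writer_public_key, "reader"
    )
    return open_(key, packet.nonce, packet.encrypted_payload)


def _data_key_payload(data_key: bytes) -> bytes:
    if len(data_key) != 32:
        raise ValueError("data key must be 32 bytes")
    return struct.pack(
        "<II", PACKET_TYPE_DATA_ENCRYPTION, DATA_ENCRYPTION_CHACHA20_POLY1305
    ) + data_key


def _edit_list_payload(lengths: Sequence[int]) -> bytes:
    validate_edit_list(lengths)
    return struct.pack("<II", PACKET_TYPE_EDIT_LIST, len(lengths)) + b"".join(
        struct.pack("<Q", n) for n in lengths
    )


def build_header(
    data_keys: Sequence[bytes],
    writer: KeyPair,
    recipients: Sequence[bytes],
    edit_list: Sequence[int] | None = None,
    rng: Rng = os.urandom,
) -> bytes:
    """Serialize a header carrying the data key(s), and optionally an edit
    list, for every recipient."""
    if not data_keys:
        raise ValueError("at least one data key is required")
    if not recipients:
        raise ValueError("at least one recipient is required")
    payloads = [_data_key_payload(k) for k in data_keys]
    if edit_list is not None:
        payloads.append(_edit_list_payload(edit_list))
    packets = [
        encrypt_packet(payload, writer, recipient, rng(_NONCE_LEN))
        for recipient in recipients
        for payload in payloads
    ]
    out = [MAGIC, struct.pack("<II", VERSION, len(packets))]
    out.extend(p.serialize() for p in packets)
    return b"".join(out)


def _read_exact(source: io.RawIOBase, n: int, what: str) -> bytes:
    data = source.read(n)
    while data is not None and 0 < len(data) < n:
        more = source.read(n - len(data))
        if not more:
            break
        data += more
    if data is None or len(data) < n:
        raise TruncationError(f"stream ended while reading {what}")
    return data


def _read_packets(source) -> tuple[list[HeaderPacket], int]:
    preamble = _read_exact(source, 16, "header preamble")
    if preamble[:8] != MAGIC:
        raise FormatError("not a crypt4gh container (bad magic bytes)")
    version, count = struct.unpack("<II", preamble[8:16])
    if version != VERSION:
        raise FormatError(f"unsupported container version {version}")
    packets: list[HeaderPacket] = []
    total = 16
    for i in range(count):
        raw_len = _read_exact(source, 4, f"length of header packet {i}")
        (packet_length,) = struct.unpack("<I", raw_len)
        if packet_length < _PACKET_FIXED + TAG_LEN:
            raise FormatError(f"header packet {i} impossibly short ({packet_length} bytes)")
        body = _read_exact(source, packet_length - 4, f"header packet {i}")
        (method,) = struct.unpack("<I", body[:4])
        packets.append(
            HeaderPacket(
                method=method,
                writer_public_key=body[4:36],
                nonce=body[36:48],
                encrypted_payload=body[48:],
            )
        )
        total += packet_length
    return packets, total


def read_header_bytes(source) -> bytes:
    """Consume and return the raw serialized header from a container stream."""
    packets, _total = _read_packets(source)
    out = [MAGIC, struct.pack("<II", VERSION, len(packets))]
    out.extend(p.serialize() for p in packets)
    return b"".join(out)


def _decode_payload(
    payload: bytes, index: int
) -> tuple[bytes | None, tuple[int, ...] | None]:
    """(data_key, edit_list) from one decrypted packet payload."""
    if len(payload) < 4:
        raise FormatError(f"decrypted header packet {index} shorter than its type tag")
    (packet_type,) = struct.unpack("<I", payload[:4])
    if packet_type == PACKET_TYPE_DATA_ENCRYPTION:
        if len(payload) != 40:
            raise FormatError(f"data-encryption packet {index} has length {len(payload)}, expected 40")
        (method,) = struct.unpack("<I", payload[4:8])
        if method != DATA_ENCRYPTION_CHACHA20_POLY1305:
            raise FormatError(f"unsupported data-encryption method {method}")
        return payload[8:40], None
    if packet_type == PACKET_TYPE_EDIT_LIST:
        if len(payload) < 8:
            raise FormatError(f"edit-list packet {index} truncated")
        (count,) = struct.unpack("<I", payload[4:8])
        if len(payload) != 8 + 8 * count:
            raise FormatError(
                f"edit-list packet {index} declares {count} lengths but carries "
                f"{len(payload) - 8} bytes"
            )
        lengths = struct.unpack(f"<{count}Q", payload[8:]) if count else ()
        return None, lengths
    logger.warning("skipping decrypted header packet %d of unknown type %d", index, packet_type)
    return None, None


def parse_header(
    source, reader: KeyPair, expected_writer: bytes | None = None
) -> ParsedHeader:
    """Parse a container header with a recipient key.

    Every packet is tried; MAC failures mean "not addressed to this key"
    and are silently fine. Zero recoverable data keys is a NoAccessError.
    When ``expected_writer`` is given, packets written by any other public
    key are ignored (opt-in sender authenticity check).
    """
    packets, total = _read_packets(source)
    data_keys: list[bytes] = []
    edit_list: tuple[int, ...] | None = None
    for i, packet in enumerate(packets):
        if expected_writer is not None and packet.writer_public_key != expected_writer:
            logger.warning("ignoring header packet %d from unexpected writer key", i)
            continue
        payload = decrypt_packet(packet, reader)
        if payload is None:
            continue
        key, lengths = _decode_payload(payload, i)
        if key is not None:
            data_keys.append(key)
        if lengths is not None:
            if edit_list is None:
                edit_list = lengths
            else:
                logger.warning("ignoring extra edit-list packet %d (honoring the first)", i)
    if not data_keys:
        raise NoAccessError(
            "no header packet carrying a data key could be decrypted with this key"
        )
    return ParsedHeader(
        data_keys=tuple(data_keys), edit_list=edit_list, header_length=total
    )


def reencrypt_header(
    header: bytes,
    reader: KeyPair,
    new_recipients: Sequence[bytes],
    keep_existing: bool = False,
    rng: Rng = os.urandom,
) -> bytes:
    """Re-package every payload `reader` can recover for new recipients.

    The data portion of the container is untouched by construction — only
    header packets are produced. New packets are written with the reader's
    own key pair as the writer. With ``keep_existing`` the original packets
    are retained in front of the new ones.
    """
    if not new_recipients:
        raise ValueError("at least one new recipient is required")
    packets, _total = _read_packets(io.BytesIO(header))
    recovered: list[bytes] = []
    got_data_key = False
    for packet in packets:
        payload = decrypt_packet(packet, reader)
        if payload is None:
            continue
        recovered.append(payload)
        if len(payload) >= 4 and struct.unpack("<I", payload[:4])[0] == PACKET_TYPE_DATA_ENCRYPTION:
            got_data_key = True
    if not got_data_key:
        raise NoAccessError(
            "no header packet carrying a data key could be decrypted with this key"
        )
    new_packets: list[HeaderPacket] = []
    if keep_existing:
        new_packets.extend(packets)
    new_packets.extend(
        encrypt_packet(payload, reader, recipient, rng(_NONCE_LEN))
        for recipient in new_recipients
        for payload in recovered
    )
    out = [MAGIC, struct.pack("<II", VERSION, len(new_packets))]
    out.extend(p.serialize() for p in new_packets)
    return b"".join(out)
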