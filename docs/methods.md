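# Methods

## Container model

A container is `header ‖ segment stream`. The header starts with the
8-byte magic `crypt4gh`, a little-endian uint32 version (always 1) and a
packet count, followed by that many self-length-prefixed packets. Each
packet is encrypted for exactly one recipient with
ChaCha20-IETF-Poly1305 under a key derived from an X25519 exchange; its
decrypted payload is type-tagged: type 0 carries the data-encryption
method code (0 = ChaCha20-IETF-Poly1305, the only code accepted) and the
32-byte data key, type 1 an edit list as a uint32 count of uint64 lengths.
A recipient identifies "their" packets purely by MAC success, which makes
multi-recipient headers possible without any recipient identifier on the
wire. Unknown packet types decrypt fine and are skipped with a warning
(forward compatibility); unknown data-encryption methods are a hard error
(the data would be unreadable); at most one edit list is honored per
recipient — the first, extras logged.

The data portion is a sequence of independently encrypted segments of at
most 65 536 plaintext bytes, each `12-byte nonce ‖ ciphertext ‖ 16-byte
MAC` (28 bytes overhead, 65 564 bytes for a full segment). The final
segment is not padded, so total plaintext length is implied by wire
length. Segment boundaries carry no framing: readers re-chunk the byte
stream at 65 564 and rely on the only-the-last-may-be-short invariant.

### Header key derivation

Both sides compute the X25519 shared point `q` and then
`BLAKE2b-512(q ‖ pk_reader ‖ pk_writer)`; the packet key is the second
32 bytes of that digest (the writer's server-role receive key equals the
reader's client-role transmit key in the libsodium key-exchange
construction the standard adopts). An all-zero `q` — a low-order peer
key — is rejected outright. Writer and reader roles are therefore
complementary by construction; an internal round trip cannot distinguish
the two 32-byte halves, which is why the choice is pinned here explicitly.

## Edit lists and their per-segment transformation

An edit list is a flat list of non-negative counts alternating
skip/keep, starting with skip, addressed to plaintext positions (0-based,
half-open ranges). Tail rule, encoded once in `editlist.tail_kind` and
shared by every consumer: odd entry count (ends on a skip) keeps the
remainder of the file; even count discards it; the empty list keeps
everything, being the degenerate "no restriction" case equivalent to
carrying no edit-list packet at all. Lists may over-run the plaintext;
trailing operations truncate at EOF. Zero-length entries are legal no-ops
(a leading `0, k` means keep-from-start).

Streamed decryption cannot apply a global list directly, so it is
re-expressed per segment: an `EditCursor` (list index, bytes consumed
within the current entry, global offset) is folded over the segment
lengths, splitting every span at segment boundaries while preserving
order. The whole-file form `transform_edit_list` is defined as exactly
this fold, so the two are extensionally equal by construction, and the
substantive correctness claim is pushed onto one law: streamed
per-segment recovery must be byte-identical to naive application of the
global list on the materialized plaintext. The test suite enforces that
law with an independent naive oracle over 500 randomized cases at the
module level and another 500 through real encrypt/decrypt, with list
entries up to 200 000 bytes and payloads up to 300 000 bytes — spans
chosen to straddle 0, 1, 2 and 3 segment boundaries, while keeping a full
suite run comfortably fast. Local operation lists are emitted in
canonical form (same-kind runs merged, zero lengths dropped, nothing after
the last keep), so a fully skipped segment has the empty plan.

Edit lists gate decryption only; encryption always encrypts everything.
Segments whose plan keeps nothing are still decrypted and authenticated —
simpler, and tampering anywhere is detected even when skipped.

## Streaming engine

A single chunker underlies both directions: it buffers at most one
outgoing chunk plus one incoming read, and re-segments regardless of the
granularity the source delivers (1-byte dribbles to megabyte reads), so
output is a pure function of stream content. Peak buffered data is
asserted in tests to stay under 4 segments with instrumented
sources/sinks. Encryption draws one fresh random 32-byte data key per run
and a fresh random 12-byte nonce per segment (independent values, not a
counter — matching common practice for this format; segment reordering is
not protected either way, see Limitations). Decryption accepts a trailing
28-byte segment decrypting to empty (some writers emit one after a
size-multiple payload) but treats any trailing fragment shorter than 28
bytes as a loud truncation error. Authentication failures name the
segment ordinal and propagate before any byte of that segment is emitted.

Re-encryption (`reencrypt_container`) re-packages every payload the
holder can decrypt — data keys, edit list, even unknown-type payloads —
into fresh packets for the new recipients, written under the holder's own
key pair, and copies the data portion through untouched. `keep_existing`
retains the original packets; without it the original recipients lose
access to the *new* copy (they of course still hold the old file).

## Key files

Armored base64 between `BEGIN/END CRYPT4GH PRIVATE KEY` banners; payload
is the magic `c4gh-v1` followed by 2-byte big-endian length-prefixed
fields: KDF name, KDF options (4-byte big-endian rounds ‖ salt), cipher
name, key blob, optional comment. Readers tolerate CRLF and wrapped
base64. The write side emits scrypt (fixed interactive-strength cost
N=2^14, r=8, p=1, 16-byte salt, rounds field written 0 and ignored, as is
conventional for scrypt in this format) or an unprotected `none` blob;
the read side additionally accepts bcrypt (OpenBSD bcrypt_pbkdf with the
stored rounds). Parameters are always read from the file, never assumed.
The protected blob is `nonce ‖ AEAD(secret)`, so a wrong passphrase is an
authentication failure, never 32 garbage bytes. Passphrases are UTF-8, no
Unicode normalization — documented contract, simplest deterministic
behavior. The secret scalar is stored exactly as produced and clamped at
use time, preserving byte-level compatibility with files from other
tools. Private key files are written with 0600 permissions where the
platform supports it.

## Cryptographic primitives

No crypto library is a dependency: X25519 (RFC 7748 Montgomery ladder on
Python integers), ChaCha20 (RFC 8439, block function vectorized over the
counter dimension with numpy — one call yields a whole segment's
keystream, which is what makes pure-Python streaming practical, on the
order of 10 MB/s per direction), Poly1305 (Horner evaluation with
Python's arbitrary-precision integers) and the combined IETF AEAD are
implemented in `crypt4gh_stream._crypto` and pinned to the RFC vectors in
the test suite. BLAKE2b and scrypt come from stdlib `hashlib` (OpenSSL
backed). For bcrypt key files, Blowfish and OpenBSD's bcrypt_pbkdf are
implemented likewise; the Blowfish P/S-boxes are, per the cipher's
definition, the first 8 336 fractional hex digits of π and are computed
at import with a Machin-formula series rather than inlined as opaque
tables, then spot-checked against the published constants and the classic
ECB vector set.

Numerical/tie-break choices worth noting: AEAD tag comparison is
constant-time (`hmac.compare_digest`); the ChaCha20 counter is 32-bit
wrapping per the IETF variant (a segment uses at most 1 025 blocks, far
from wrap-around); multi-key segment decryption tries keys in header
order and the first verifying MAC wins.

## Synthetic data

Test and example payloads are seeded pseudorandom bytes
(`generate_payload`), plus an injectable deterministic byte source
(`seeded_rng`) standing in for `os.urandom` so containers are
reproducible in tests. This emulates the one property of real FASTQ/BAM
payloads the cipher layer can see — arbitrary, incompressible bytes at
boundary-straddling sizes — and nothing else: no real-format structure,
no network transport, no disk I/O patterns. Passing tests therefore
certify the container transformation (byte-for-byte round trips, edit-list
extraction, error detection), not end-to-end behavior of any particular
genomics toolchain on top of it. Round-trip suites run sizes
{0, 1, 65 535, 65 536, 65 537, 131 072, 131 073, 1 000 000} — every
chunking boundary class plus a multi-segment size — with this package's
own choice of 500/200/50-case sampling for the randomized laws, sized to
keep the full suite under a couple of minutes on one core.

## Design choices made where the design was open

- **Read-side KDF breadth, write-side narrowness** (write scrypt only,
  read scrypt/bcrypt/none): liberal in what is accepted, conservative in
  what is produced.
- **Multiple decryptable data keys are all kept**; segments try each.
- **Sender authenticity is opt-in**: the format carries the writer public
  key, and callers may pin an expected writer; by default any writer is
  accepted, since the header MAC already proves possession of a key
  exchange with the named writer key.
- **Empty payloads** produce a header and zero segments.
- **CLI passphrases** come from an environment variable, a file, or an
  interactive prompt — never argv, which is visible in process listings.

## Limitations

- The format authenticates segments individually: reordering, deleting or
  duplicating *whole segments* is not detected beyond what total length
  implies. This is a property of the container design, not of this
  implementation.
- Big-integer arithmetic is not constant-time; the X25519 ladder has
  scalar-independent structure but this implementation does not claim
  side-channel resistance on shared hardware.
- The bcrypt path's salted Blowfish schedule is validated against the
  unsalted cipher's published vectors and internal consistency only; no
  externally published bcrypt_pbkdf vector is bundled.
- Random access (fetching only the segments an edit list needs from
  remote storage) is enabled by the per-segment plan structure but not
  implemented; reading is sequential.
- Throughput (~10 MB/s per direction) is ample for streaming use but well
  below C implementations; the timing harness exists to measure, not to
  promise.
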