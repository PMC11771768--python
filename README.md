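# crypt4gh-stream

Streaming implementation of the Crypt4GH encrypted container format — the
GA4GH standard for storing and sharing sensitive (typically genomic) data
such as FASTQ/BAM/CRAM payloads, treated as opaque bytes. It is a Python
library plus a small CLI (`c4ghstream`) for anyone who needs to encrypt
data before it leaves the client, hand access to specific recipients, or
let a recipient recover only selected byte ranges of a file.

## The format and the algorithms

Crypt4GH uses **envelope encryption**, a two-layer scheme:

- **Inner layer** — a random 32-byte data key `K` encrypts the payload with
  ChaCha20-IETF-Poly1305. The plaintext is cut into segments of
  65 536 bytes; each segment travels as `nonce (12 B) ‖ ciphertext ‖
  MAC (16 B)`, i.e. exactly 28 bytes larger than its plaintext, so a full
  segment occupies 65 564 bytes on the wire. The final segment keeps its
  natural length (no padding).
- **Outer layer** — for each recipient, `K` is wrapped in a header packet
  encrypted under a key derived from an X25519 Diffie–Hellman exchange
  between writer and recipient:
  `key = BLAKE2b-512(X25519(sk, pk_peer) ‖ pk_reader ‖ pk_writer)[32:64]`.

Everything is processed **one segment at a time**, so memory stays bounded
no matter the file size — the container can be produced or consumed from a
pipe. Headers may also carry an **edit list**: alternating byte counts
`skip₀, keep₁, skip₂, …` over the plaintext, which restrict what the
recipient may recover. Because decryption is streamed, the global list is
rewritten on the fly into local skip/keep operations for each 65 536-byte
segment (`crypt4gh_stream.editlist`); the defining law, enforced by the
test suite against a naive oracle, is that streamed per-segment recovery is
byte-identical to applying the global list to the whole decrypted file.

Keys live in armored files (`-----BEGIN CRYPT4GH PRIVATE KEY-----`),
optionally passphrase-protected (scrypt on write; scrypt, bcrypt or none on
read). All cryptographic primitives (X25519, ChaCha20-Poly1305, BLAKE2b,
scrypt, bcrypt-pbkdf) follow their published specifications and are pinned
to the RFC 7748 / RFC 8439 test vectors in the test suite; the ChaCha20
core is vectorized with numpy so that pure-Python streaming stays practical.

## Worked example

```python
import io
import crypt4gh_stream as c4

rng = c4.seeded_rng(2024)                 # deterministic for the example
alice = c4.generate_keypair(rng)          # data owner (writer)
bob = c4.generate_keypair(rng)            # recipient

payload = c4.generate_payload(200_000, seed=7)   # stand-in for a CRAM file

container = io.BytesIO()
summary = c4.encrypt_stream(
    io.BytesIO(payload), alice, [bob.public_key], container,
    edit_list=[950, 837],                 # bob may read bytes 950..1786 only
    rng=rng,
)
print("encrypt:", summary)

container.seek(0)
recovered = io.BytesIO()
summary = c4.decrypt_stream(container, bob, recovered)
print("decrypt:", summary)
print("recovered == payload[950:1787]:", recovered.getvalue() == payload[950:1787])
```

prints

```
encrypt: StreamSummary(segments=4, bytes_in=200000, bytes_out=200328, header_length=216)
decrypt: StreamSummary(segments=4, bytes_in=200328, bytes_out=837, header_length=216)
recovered == payload[950:1787]: True
```

The 200 000-byte payload becomes 4 segments (3 full + 1 of 3 392 bytes);
the wire size is the 216-byte header plus 200 000 + 4 × 28 = 200 328 bytes.
The edit list `[950, 837]` (skip 950 bytes, keep 837, discard the rest —
the classic slice-of-a-CRAM example) means Bob's decryption emits exactly
837 bytes even though all 4 segments are authenticated and decrypted.

The same flows are available from the shell:

```console
$ c4ghstream keygen --secret bob.sec --public bob.pub --no-passphrase
$ c4ghstream encrypt --recipient bob.pub --range 950-1787 reads.cram reads.cram.c4gh
$ c4ghstream decrypt --secret bob.sec reads.cram.c4gh slice.bin
```

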