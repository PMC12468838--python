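"""Differential privacy and additively homomorphic secure aggregation.

Client updates are L2-clipped to sensitivity C and perturbed with Gaussian
noise of standard deviation sigma = C * sqrt(2 ln(1.25/delta)) / epsilon
(the classical Gaussian-mechanism calibration, valid for epsilon <= 1).
The noised updates are fixed-point encoded (scale 2^16), encrypted under a
Paillier public key, homomorphically summed around a logical ring of
clients, and decrypted exactly once by the aggregation server -- no
intermediate decryption is possible because only the server role holds the
private key.

The Paillier cryptosystem is implemented directly on Python integers
(g = n + 1 simplification); key generation draws random primes with a
seeded generator so test keys are reproducible.
"""

from __future__ import annotations

import base64
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sympy import isprime

__all__ = [
    "PrivacyConfig", "PlainUpdate", "calibrate_sigma", "privatize_update",
    "FixedPointCodec", "CipherVector", "PaillierPublicKey",
    "PaillierPrivateKey", "KeyPair", "generate_keypair",
    "AggregationServer", "secure_ring_aggregate",
    "save_public_key", "load_public_key",
]

DEFAULT_SCALE = 2**16


def calibrate_sigma(epsilon: float, delta: float, clip_norm: float) -> float:
    """Gaussian-mechanism noise scale for an (epsilon, delta) budget with
    L2 sensitivity clip_norm."""
    if epsilon <= 0:
        raise ValueError(f"epsilon must be positive, got {epsilon}")
    if not 0.0 < delta < 1.0:
        raise ValueError(f"delta must lie in (0, 1), got {delta}")
    if clip_norm <= 0:
        raise ValueError(f"clip_norm must be positive, got {clip_norm}")
    return clip_norm * math.sqrt(2.0 * math.log(1.25 / delta)) / epsilon


@dataclass(frozen=True)
class PrivacyConfig:
    """DP + encryption settings.  sigma is derived from (epsilon, delta,
    clip_norm) unless DP is disabled via ``noise=False``."""

    epsilon: float = 0.5
    delta: float = 1e-5
    clip_norm: float = 1.0
    key_bits: int = 2048
    scale: int = DEFAULT_SCALE
    noise: bool = True          # set False for sigma = 0 ablations
    encrypt: bool = True        # plaintext aggregation when False

    @property
    def sigma(self) -> float:
        if not self.noise:
            return 0.0
        return calibrate_sigma(self.epsilon, self.delta, self.clip_norm)


@dataclass
class PlainUpdate:
    g: np.ndarray          # original update
    g_tilde: np.ndarray    # clipped + noised update


def privatize_update(g: np.ndarray, cfg: PrivacyConfig, seed: int) -> PlainUpdate:
    """Clip to L2 norm <= clip_norm, then add i.i.d. N(0, sigma^2) noise."""
    g = np.asarray(g, dtype=np.float64)
    norm = float(np.linalg.norm(g))
    clipped = g * min(1.0, cfg.clip_norm / norm) if norm > 0 else g.copy()
    sigma = cfg.sigma
    if sigma > 0:
        rng = np.random.default_rng(seed)
        g_tilde = clipped + rng.normal(0.0, sigma, g.shape)
    else:
        g_tilde = clipped
    return PlainUpdate(g=g, g_tilde=g_tilde)


# ---------------------------------------------------------------------------
# fixed-point codec

class OverflowError_(OverflowError):
    """Encoded magnitude exceeds the key's plaintext bound."""


@dataclass(frozen=True)
class FixedPointCodec:
    """Signed fixed-point codec: encode = round(x * scale); the round-trip
    error is at most 1/(2*scale) per coordinate and sums of K encodings
    decode within K/(2*scale)."""

    scale: int = DEFAULT_SCALE

    def encode(self, x: np.ndarray, max_int: int | None = None) -> list[int]:
        arr = np.asarray(x, dtype=np.float64)
        ints = [int(round(v * self.scale)) for v in arr.ravel()]
        if max_int is not None and any(abs(v) > max_int for v in ints):
            raise OverflowError_("fixed-point encoding exceeds plaintext bound")
        return ints

    def decode(self, ints: list[int]) -> np.ndarray:
        return np.array(ints, dtype=np.float64) / self.scale


# ---------------------------------------------------------------------------
# Paillier cryptosystem

def _random_prime(bits: int, rng: np.random.Generator) -> int:
    nbytes = (bits + 7) // 8
    while True:
        candidate = int.from_bytes(rng.bytes(nbytes), "big") >> (8 * nbytes - bits)
        candidate |= (1 << (bits - 1)) | 1    # full bit length, odd
        if isprime(candidate):
            return candidate


@dataclass(frozen=True)
class PaillierPublicKey:
    n: int
    key_id: str = field(default="", compare=False)

    def __post_init__(self):
        object.__setattr__(self, "key_id", f"paillier-{self.n % (1 << 64):016x}")

    @property
    def nsquare(self) -> int:
        return self.n * self.n

    @property
    def max_int(self) -> int:
        # plaintext magnitude bound; leaves headroom for summation
        return self.n // 3

    def encrypt_int(self, m: int, rng: np.random.Generator) -> int:
        if abs(m) > self.max_int:
            raise OverflowError_(f"plaintext {m} exceeds key bound")
        n, n2 = self.n, self.nsquare
        m = m % n
        # g = n + 1:  g^m = 1 + m*n (mod n^2)
        gm = (1 + m * n) % n2
        nbytes = (n.bit_length() + 7) // 8
        while True:
            r = int.from_bytes(rng.bytes(nbytes), "big") % n
            if r > 1 and math.gcd(r, n) == 1:
                break
        return (gm * pow(r, n, n2)) % n2

    def add(self, c1: int, c2: int) -> int:
        return (c1 * c2) % self.nsquare


@dataclass(frozen=True)
class PaillierPrivateKey:
    public: PaillierPublicKey
    lam: int
    mu: int

    def decrypt_int(self, c: int) -> int:
        n, n2 = self.public.n, self.public.nsquare
        x = pow(c, self.lam, n2)
        m = ((x - 1) // n * self.mu) % n
        if m > n // 2:
            m -= n
        return m


@dataclass(frozen=True)
class KeyPair:
    public: PaillierPublicKey
    private: PaillierPrivateKey


def generate_keypair(bits: int = 2048, seed: int = 0) -> KeyPair:
    """Generate a Paillier key pair with an n of roughly ``bits`` bits."""
    rng = np.random.default_rng(seed)
    half = bits // 2
    while True:
        p = _random_prime(half, rng)
        q = _random_prime(half, rng)
        if p != q:
            break
    n = p * q
    lam = (p - 1) * (q - 1) // math.gcd(p - 1, q - 1)
    public = PaillierPublicKey(n=n)
    # mu = (L(g^lam mod n^2))^-1 mod n; with g = n+1, L(g^lam) = lam mod n
    mu = pow(lam % n, -1, n)
    return KeyPair(public=public, private=PaillierPrivateKey(public=public, lam=lam, mu=mu))


@dataclass
class CipherVector:
    """Per-coordinate Paillier ciphertexts of a fixed-point-encoded vector."""

    ciphertexts: list[int]
    scale: int
    key_id: str

    def __add__(self, other: "CipherVector") -> "CipherVector":
        raise TypeError("use PaillierPublicKey.add via add_cipher_vectors")


def encrypt_vector(
    x: np.ndarray, public: PaillierPublicKey, scale: int, rng: np.random.Generator
) -> CipherVector:
    codec = FixedPointCodec(scale)
    ints = codec.encode(x, max_int=public.max_int)
    return CipherVector(
        ciphertexts=[public.encrypt_int(m, rng) for m in ints],
        scale=scale,
        key_id=public.key_id,
    )


def add_cipher_vectors(
    a: CipherVector, b: CipherVector, public: PaillierPublicKey
) -> CipherVector:
    if a.key_id != b.key_id or a.key_id != public.key_id:
        raise ValueError("key mismatch between cipher vectors")
    if a.scale != b.scale:
        raise ValueError("scale mismatch between cipher vectors")
    if len(a.ciphertexts) != len(b.ciphertexts):
        raise ValueError("length mismatch between cipher vectors")
    return CipherVector(
        ciphertexts=[public.add(x, y) for x, y in zip(a.ciphertexts, b.ciphertexts)],
        scale=a.scale,
        key_id=a.key_id,
    )


class AggregationServer:
    """The only role holding the private key; decrypts the ring total once."""

    def __init__(self, keys: KeyPair):
        self._private = keys.private
        self.public = keys.public

    def decrypt_aggregate(self, total: CipherVector) -> np.ndarray:
        if total.key_id != self.public.key_id:
            raise ValueError("aggregate encrypted under a different key")
        ints = [self._private.decrypt_int(c) for c in total.ciphertexts]
        return FixedPointCodec(total.scale).decode(ints)


def secure_ring_aggregate(
    updates: list[np.ndarray],
    keys: KeyPair,
    cfg: PrivacyConfig,
    seed: int = 0,
) -> np.ndarray:
    """Sum client updates around a logical ring without exposing any
    individual one.

    Client i encrypts its update under the public key and homomorphically
    adds it to the running ciphertext received from client i-1; the server
    at the end of the ring decrypts the single total.  The result equals
    the plaintext sum within K/(2*scale) per coordinate.
    """
    if not updates:
        raise ValueError("need at least one update")
    dim = updates[0].shape
    if any(u.shape != dim for u in updates):
        raise ValueError("updates must share a common length")
    rng = np.random.default_rng(seed)
    public = keys.public
    running: CipherVector | None = None
    for u in updates:               # ring order 1 -> 2 -> ... -> K -> server
        enc = encrypt_vector(u, public, cfg.scale, rng)
        running = enc if running is None else add_cipher_vectors(running, enc, public)
    server = AggregationServer(keys)
    return server.decrypt_aggregate(running)


# ---------------------------------------------------------------------------
# PEM-like key serialization (text only)

def save_public_key(public: PaillierPublicKey, path: str | Path) -> None:
    payload = base64.b64encode(json.dumps({"n": str(public.n)}).encode()).decode()
    text = "-----BEGIN QAVFL PAILLIER PUBLIC KEY-----\n"
    text += "\n".join(payload[i:i + 64] for i in range(0, len(payload), 64))
    text += "\n-----END QAVFL PAILLIER PUBLIC KEY-----\n"
    Path(path).write_text(text)


def load_public_key(path: str | Path) -> PaillierPublicKey:
    lines = [ln for ln in Path(path).read_text().splitlines() if not ln.startswith("-")]
    data = json.loads(base64.b64decode("".join(lines)))
    return PaillierPublicKey(n=int(data["n"]))
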