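"""Binary molecular fingerprints and Tanimoto similarity kernels.

Fingerprints are ECFP-style circular (Morgan) bit vectors generated with
RDKit.  A :class:`Fingerprint` stores the set of on-bit indices together
with the vector length and the parameters that produced it, so two
fingerprints can never be compared unless they were generated compatibly.

Two Tanimoto paths are provided: :func:`tanimoto` computes the Jaccard
index on the Python bit sets directly, and :func:`bulk_tanimoto` /
:func:`pairwise_tanimoto` pack the bit sets into ``uint64`` words and use
hardware popcount (``numpy.bitwise_count``).  Both paths agree bit-exactly
because intersection and union cardinalities are exact integers either way.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .chem_io import Compound

__all__ = [
    "FingerprintParams",
    "Fingerprint",
    "FingerprintError",
    "IncompatibleFingerprints",
    "compute_fingerprint",
    "fingerprint_compounds",
    "tanimoto",
    "bulk_tanimoto",
    "pairwise_tanimoto",
    "pack_bits",
    "write_fingerprint_cache",
    "read_fingerprint_cache",
]

#: fingerprints with fewer set bits than this are flagged "low-information"
DEFAULT_MIN_BITS = 4


class FingerprintError(ValueError):
    """A structure could not be fingerprinted."""

    def __init__(self, compound_id: str, reason: str):
        self.compound_id = compound_id
        self.reason = reason
        super().__init__(f"cannot fingerprint {compound_id!r}: {reason}")


class IncompatibleFingerprints(ValueError):
    """Fingerprints with different length or parameters were compared."""


@dataclass(frozen=True)
class FingerprintParams:
    """Generation parameters for circular (ECFP-style) fingerprints.

    ``radius`` is the maximum bond radius of the hashed atom environments
    (radius 2 corresponds to ECFP4); ``n_bits`` is the folded vector
    length and must be a power of two of at least 64.
    """

    algorithm: str = "circular"
    radius: int = 2
    n_bits: int = 2048

    def __post_init__(self) -> None:
        if self.algorithm != "circular":
            raise ValueError(f"unsupported fingerprint algorithm {self.algorithm!r}")
        if not (0 <= self.radius <= 6):
            raise ValueError("radius must be in [0, 6]")
        if self.n_bits < 64 or (self.n_bits & (self.n_bits - 1)) != 0:
            raise ValueError("n_bits must be a power of two >= 64")

    def digest(self) -> str:
        """Short stable digest identifying this parameter set."""
        text = f"{self.algorithm}:r{self.radius}:b{self.n_bits}"
        return hashlib.sha1(text.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class Fingerprint:
    """A fixed-length binary substructure vector as a set of on-bit indices."""

    bits: frozenset[int]
    n_bits: int
    params: FingerprintParams

    def __post_init__(self) -> None:
        if any(b < 0 or b >= self.n_bits for b in self.bits):
            raise ValueError("bit index out of range")
        if self.n_bits != self.params.n_bits:
            raise ValueError("n_bits inconsistent with params")

    @property
    def n_on(self) -> int:
        return len(self.bits)

    def compatible_with(self, other: "Fingerprint") -> bool:
        return self.n_bits == other.n_bits and self.params == other.params

    def to_hex(self) -> str:
        """Hex encoding of the bit vector, most-significant word first."""
        v = np.zeros(self.n_bits // 8, dtype=np.uint8)
        for b in self.bits:
            v[b // 8] |= 1 << (b % 8)
        return bytes(v).hex()

    @classmethod
    def from_hex(cls, hexstr: str, params: FingerprintParams) -> "Fingerprint":
        raw = bytes.fromhex(hexstr)
        if len(raw) * 8 != params.n_bits:
            raise ValueError("hex length inconsistent with n_bits")
        bits = {
            8 * i + j for i, byte in enumerate(raw) for j in range(8) if byte >> j & 1
        }
        return cls(bits=frozenset(bits), n_bits=params.n_bits, params=params)


# generator cache keyed by params: RDKit generators are reusable and
# construction is not free
_GENERATORS: dict[FingerprintParams, object] = {}
_FP_CACHE: dict[tuple[str, FingerprintParams], Fingerprint] = {}


def _generator(params: FingerprintParams):
    gen = _GENERATORS.get(params)
    if gen is None:
        gen = rdFingerprintGenerator.GetMorganGenerator(
            radius=params.radius, fpSize=params.n_bits
        )
        _GENERATORS[params] = gen
    return gen


def compute_fingerprint(
    compound: Compound,
    params: FingerprintParams | None = None,
    min_bits: int = DEFAULT_MIN_BITS,
) -> tuple[Fingerprint, bool]:
    """Fingerprint one compound.

    Returns ``(fingerprint, low_information)`` where the flag is true when
    fewer than ``min_bits`` bits are set — typical for small inorganics
    (e.g. platinum complexes) whose graphs expose almost no circular
    environments, making Tanimoto comparisons against them uninformative.

    If the compound already carries an injected fingerprint (synthetic
    populations), it is returned as-is after a parameter check.

    Results are cached on ``(smiles_canonical, params)`` because screening
    re-uses reference fingerprints across many queries.
    """
    if params is None:
        params = FingerprintParams()
    if compound.fingerprint is not None:
        fp = compound.fingerprint
        if fp.params != params:
            raise IncompatibleFingerprints(
                f"compound {compound.id!r} carries a fingerprint with params "
                f"{fp.params}, expected {params}"
            )
        return fp, fp.n_on < min_bits

    key = (compound.smiles_canonical, params)
    fp = _FP_CACHE.get(key)
    if fp is None:
        mol = Chem.MolFromSmiles(compound.smiles_canonical)
        if mol is None:
            raise FingerprintError(compound.id, "canonical SMILES failed to parse")
        bv = _generator(params).GetFingerprint(mol)
        fp = Fingerprint(
            bits=frozenset(bv.GetOnBits()), n_bits=params.n_bits, params=params
        )
        _FP_CACHE[key] = fp
    return fp, fp.n_on < min_bits


def fingerprint_compounds(
    compounds: Iterable[Compound],
    params: FingerprintParams | None = None,
    min_bits: int = DEFAULT_MIN_BITS,
) -> tuple[list[Fingerprint], list[str]]:
    """Fingerprint a collection; returns fingerprints plus the ids flagged
    low-information."""
    fps: list[Fingerprint] = []
    low_info: list[str] = []
    for c in compounds:
        fp, low = compute_fingerprint(c, params, min_bits=min_bits)
        fps.append(fp)
        if low:
            low_info.append(c.id)
    return fps, low_info


def _check_compatible(a: Fingerprint, b: Fingerprint) -> None:
    if not a.compatible_with(b):
        raise IncompatibleFingerprints(
            f"fingerprints are not comparable: {a.n_bits} bits / {a.params} "
            f"vs {b.n_bits} bits / {b.params}"
        )


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto (Jaccard) similarity |A∩B| / |A∪B| in [0, 1].

    Two empty fingerprints are defined to have similarity 0 (no perceivable
    features carry no evidence of similarity); a warning is emitted so that
    low-information structures remain visible.
    """
    _check_compatible(a, b)
    union = len(a.bits | b.bits)
    if union == 0:
        warnings.warn(
            "Tanimoto of two empty fingerprints defined as 0", stacklevel=2
        )
        return 0.0
    return len(a.bits & b.bits) / union


def pack_bits(fps: Sequence[Fingerprint]) -> np.ndarray:
    """Pack fingerprints into a (n, n_bits/64) uint64 matrix for popcount."""
    if not fps:
        return np.zeros((0, 0), dtype=np.uint64)
    n_bits = fps[0].n_bits
    words = n_bits // 64
    out = np.zeros((len(fps), words), dtype=np.uint64)
    for i, fp in enumerate(fps):
        for b in fp.bits:
            out[i, b // 64] |= np.uint64(1) << np.uint64(b % 64)
    return out


def bulk_tanimoto(
    query: Fingerprint, references: Sequence[Fingerprint]
) -> np.ndarray:
    """Vectorized Tanimoto of one query against many references.

    Output order matches reference order and each entry equals
    ``tanimoto(query, ref)`` bit-exactly.  All references are validated for
    compatibility before any computation.
    """
    for ref in references:
        _check_compatible(query, ref)
    if not references:
        return np.zeros(0, dtype=float)
    q = pack_bits([query])[0]
    r = pack_bits(references)
    inter = np.bitwise_count(q[None, :] & r).sum(axis=1)
    union = np.bitwise_count(q[None, :] | r).sum(axis=1)
    out = np.zeros(len(references), dtype=float)
    nz = union > 0
    out[nz] = inter[nz] / union[nz]
    if (~nz).any():
        warnings.warn(
            "Tanimoto of two empty fingerprints defined as 0", stacklevel=2
        )
    return out


def bulk_tanimoto_packed(query: Fingerprint, packed: np.ndarray) -> np.ndarray:
    """Tanimoto of one query against a pre-packed uint64 reference matrix.

    The caller guarantees the packed references were generated under the
    same parameters as ``query`` (the model layer enforces this); used to
    avoid re-packing reference sets for every query during screening.
    """
    if packed.shape[0] == 0:
        return np.zeros(0, dtype=float)
    q = pack_bits([query])[0]
    if packed.shape[1] != q.shape[0]:
        raise IncompatibleFingerprints("packed width does not match query n_bits")
    inter = np.bitwise_count(q[None, :] & packed).sum(axis=1)
    union = np.bitwise_count(q[None, :] | packed).sum(axis=1)
    out = np.zeros(packed.shape[0], dtype=float)
    nz = union > 0
    out[nz] = inter[nz] / union[nz]
    return out


def pairwise_tanimoto(
    queries: Sequence[Fingerprint], references: Sequence[Fingerprint]
) -> np.ndarray:
    """(len(queries), len(references)) matrix of Tanimoto similarities."""
    for fp in list(queries) + list(references):
        if queries:
            _check_compatible(queries[0], fp)
    if not queries or not references:
        return np.zeros((len(queries), len(references)), dtype=float)
    q = pack_bits(queries)
    r = pack_bits(references)
    out = np.zeros((len(queries), len(references)), dtype=float)
    for i in range(len(queries)):
        inter = np.bitwise_count(q[i][None, :] & r).sum(axis=1)
        union = np.bitwise_count(q[i][None, :] | r).sum(axis=1)
        nz = union > 0
        out[i, nz] = inter[nz] / union[nz]
    return out


# ---------------------------------------------------------------------------
# plain-text fingerprint cache (versioned TSV)

CACHE_FORMAT_VERSION = "1"


def write_fingerprint_cache(
    path,
    ids: Sequence[str],
    smiles: Sequence[str],
    fps: Sequence[Fingerprint],
) -> None:
    """Write a versioned plain-text cache: one TSV record per compound with
    id, canonical SMILES, params digest and hex-encoded bit vector."""
    if not (len(ids) == len(smiles) == len(fps)):
        raise ValueError("ids, smiles and fps must have equal length")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#ototox-fp-cache\tv{CACHE_FORMAT_VERSION}\n")
        if fps:
            p = fps[0].params
            fh.write(
                f"#params\t{p.algorithm}\t{p.radius}\t{p.n_bits}\t{p.digest()}\n"
            )
        for cid, smi, fp in zip(ids, smiles, fps):
            fh.write(f"{cid}\t{smi}\t{fp.params.digest()}\t{fp.to_hex()}\n")


def read_fingerprint_cache(path) -> tuple[list[str], list[str], list[Fingerprint]]:
    """Read a cache written by :func:`write_fingerprint_cache`."""
    ids: list[str] = []
    smiles: list[str] = []
    fps: list[Fingerprint] = []
    params: FingerprintParams | None = None
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("#ototox-fp-cache"):
            raise ValueError(f"{path}: not a fingerprint cache file")
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#params"):
                _, algo, radius, n_bits, _digest = line.split("\t")
                params = FingerprintParams(
                    algorithm=algo, radius=int(radius), n_bits=int(n_bits)
                )
                continue
            if not line or line.startswith("#"):
                continue
            if params is None:
                raise ValueError(f"{path}: missing #params line")
            cid, smi, digest, hexbits = line.split("\t")
            if digest != params.digest():
                raise ValueError(f"{path}: record {cid!r} has mismatched params")
            ids.append(cid)
            smiles.append(smi)
            fps.append(Fingerprint.from_hex(hexbits, params))
    return ids, smiles, fps
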