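"""Molecular fingerprints for drug representation.

Three complementary binary fingerprints feed the three fingerprint-specific
subnetworks of the synergy model:

* **MACCS** — 166 predefined structural keys (presence/absence of fragments
  such as 3-membered rings); the conventional unused leading bit emitted by
  RDKit is dropped so the vector is exactly 166 long.
* **HashTT** — hashed topological torsions: linear paths of four
  consecutively bonded heavy atoms, labelled by atom type, heavy-atom branch
  count and pi-electron count, hashed into ``n_bits`` buckets.
* **MAP4** — MinHashed atom pairs: for every heavy-atom pair, the circular
  substructures of radius 1 and 2 bonds around each atom are written as
  canonical SMILES and combined with the topological distance between the
  atoms; the resulting shingle set is MinHashed and folded into ``dims``
  presence/absence buckets.

All three are deterministic functions of the canonical SMILES and are used
as plain 0/1 sequences by the downstream Conv1D encoders.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator

from .errors import DegenerateMoleculeWarning, InvalidSmilesError

MACCS_LENGTH = 166
DEFAULT_N_BITS = 1024

_MERSENNE_PRIME = (1 << 61) - 1
_MINHASH_SEED = 42  # fixed: MAP4 must be identical across runs and processes


@dataclass(frozen=True)
class Molecule:
    """A parsed small molecule identified by its canonical SMILES."""

    smiles: str
    id: str = ""

    def to_rdkit(self) -> Chem.Mol:
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None:  # pragma: no cover - canonical SMILES always reparse
            raise InvalidSmilesError(f"stored SMILES no longer parses: {self.smiles!r}")
        return mol


@dataclass(frozen=True)
class FingerprintVector:
    """Fixed-length binary vector for one drug under one fingerprint kind."""

    kind: str  # {"hashtt", "map4", "maccs"}
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.uint8)
        if v.ndim != 1 or not np.isin(v, (0, 1)).all():
            raise ValueError("fingerprint values must be a 1-D 0/1 vector")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.shape[0]


def parse_smiles(smiles: str, drug_id: str = "") -> Molecule:
    """Parse and canonicalize a SMILES string.

    Multi-fragment inputs (salts, mixtures) are reduced to the largest
    fragment by heavy-atom count before canonicalization.

    Raises
    ------
    InvalidSmilesError
        If the string is empty or chemically unparsable.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        raise InvalidSmilesError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSmilesError(f"unparsable SMILES: {smiles!r}")
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) > 1:
        mol = max(frags, key=lambda f: f.GetNumHeavyAtoms())
    return Molecule(smiles=Chem.MolToSmiles(mol), id=drug_id)


def compute_maccs(mol: Molecule) -> FingerprintVector:
    """166-bit MACCS structural keys (RDKit's unused bit 0 dropped)."""
    bv = MACCSkeys.GenMACCSKeys(mol.to_rdkit())  # 167 bits, bit 0 unused
    arr = np.zeros(bv.GetNumBits(), dtype=np.uint8)
    for bit in bv.GetOnBits():
        arr[bit] = 1
    return FingerprintVector(kind="maccs", values=arr[1:])


def compute_hashtt(mol: Molecule, n_bits: int = DEFAULT_N_BITS) -> FingerprintVector:
    """Hashed topological-torsion fingerprint as a binary vector.

    Molecules with fewer than four heavy atoms contain no torsion path;
    a ``DegenerateMoleculeWarning`` is emitted and the (possibly all-zero)
    vector is still returned.
    """
    if n_bits < 64:
        raise ValueError("n_bits must be >= 64")
    rdmol = mol.to_rdkit()
    if rdmol.GetNumHeavyAtoms() < 4:
        warnings.warn(
            f"molecule {mol.smiles!r} has < 4 heavy atoms: no topological torsion exists",
            DegenerateMoleculeWarning,
            stacklevel=2,
        )
    gen = rdFingerprintGenerator.GetTopologicalTorsionGenerator(fpSize=n_bits)
    bv = gen.GetFingerprint(rdmol)
    arr = np.zeros(n_bits, dtype=np.uint8)
    for bit in bv.GetOnBits():
        arr[bit] = 1
    return FingerprintVector(kind="hashtt", values=arr)


def _shingle_hash(shingle: str) -> int:
    digest = hashlib.sha1(shingle.encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "big") % _MERSENNE_PRIME


def _atom_env_smiles(rdmol: Chem.Mol, atom_idx: int, radius: int) -> str:
    env = Chem.FindAtomEnvironmentOfRadiusN(rdmol, radius, atom_idx)
    if not env and radius > 0:
        return ""
    amap: dict[int, int] = {}
    sub = Chem.PathToSubmol(rdmol, env, atomMap=amap)
    if atom_idx not in amap:
        return ""
    return Chem.MolToSmiles(sub, rootedAtAtom=amap[atom_idx], canonical=True)


def _map4_shingles(rdmol: Chem.Mol) -> set[str]:
    n = rdmol.GetNumAtoms()
    if n < 2:
        return set()
    dist = Chem.GetDistanceMatrix(rdmol)
    envs = {
        (i, r): _atom_env_smiles(rdmol, i, r) for i in range(n) for r in (1, 2)
    }
    shingles: set[str] = set()
    for i in range(n):
        for j in range(i + 1, n):
            d = int(dist[i, j])
            for r in (1, 2):
                a, b = sorted((envs[(i, r)], envs[(j, r)]))
                shingles.add(f"{a}|{d}|{b}")
    return shingles


def _minhash_coeffs(dims: int) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.Generator(np.random.PCG64(_MINHASH_SEED))
    a = rng.integers(1, _MERSENNE_PRIME, size=dims, dtype=np.int64)
    b = rng.integers(0, _MERSENNE_PRIME, size=dims, dtype=np.int64)
    return a, b


_COEFF_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def compute_map4(mol: Molecule, dims: int = DEFAULT_N_BITS) -> FingerprintVector:
    """MinHashed atom-pair fingerprint (radii 1-2 bonds), folded to ``dims`` bits.

    The MinHash signature (one minimum per seeded affine permutation over a
    61-bit prime field) is folded modulo ``dims`` into presence/absence
    buckets, giving a binary vector compatible with the other fingerprints.
    Single-atom molecules have no atom pair; a ``DegenerateMoleculeWarning``
    is emitted and the all-zero vector returned.
    """
    if dims < 64:
        raise ValueError("dims must be >= 64")
    rdmol = mol.to_rdkit()
    shingles = _map4_shingles(rdmol)
    arr = np.zeros(dims, dtype=np.uint8)
    if not shingles:
        warnings.warn(
            f"molecule {mol.smiles!r} has no atom pair: MAP4 is all-zero",
            DegenerateMoleculeWarning,
            stacklevel=2,
        )
        return FingerprintVector(kind="map4", values=arr)
    if dims not in _COEFF_CACHE:
        _COEFF_CACHE[dims] = _minhash_coeffs(dims)
    a, b = _COEFF_CACHE[dims]
    hashes = np.array(sorted(_shingle_hash(s) for s in shingles), dtype=np.int64)
    # signature[k] = min over shingles of (a_k * h + b_k) mod p, in objects to
    # avoid 64-bit overflow of a_k * h
    sig = np.full(dims, _MERSENNE_PRIME, dtype=object)
    for h in hashes:
        vals = (a.astype(object) * int(h) + b.astype(object)) % _MERSENNE_PRIME
        sig = np.minimum(sig, vals)
    arr[np.array([int(s) % dims for s in sig], dtype=np.int64)] = 1
    return FingerprintVector(kind="map4", values=arr)


def featurize_drug_table(
    drugs,
    n_bits_hashtt: int = DEFAULT_N_BITS,
    dims_map4: int = DEFAULT_N_BITS,
) -> dict[str, tuple[FingerprintVector, FingerprintVector, FingerprintVector]]:
    """Compute (hashtt, map4, maccs) for every ``(id, smiles)`` pair.

    Results are cached by canonical SMILES, so duplicate structures under
    different ids share one computation and yield identical triples.
    Unparsable entries are aggregated into one ``InvalidSmilesError`` whose
    ``offenders`` attribute maps drug id to the offending SMILES.
    """
    offenders: dict[str, str] = {}
    molecules: dict[str, Molecule] = {}
    for drug_id, smiles in drugs:
        try:
            molecules[drug_id] = parse_smiles(smiles, drug_id=drug_id)
        except InvalidSmilesError:
            offenders[drug_id] = smiles
    if offenders:
        raise InvalidSmilesError(
            f"{len(offenders)} drug(s) had unparsable SMILES: {sorted(offenders)}",
            offenders=offenders,
        )
    cache: dict[str, tuple] = {}
    out: dict[str, tuple] = {}
    for drug_id, mol in molecules.items():
        if mol.smiles not in cache:
            cache[mol.smiles] = (
                compute_hashtt(mol, n_bits_hashtt),
                compute_map4(mol, dims_map4),
                compute_maccs(mol),
            )
        out[drug_id] = cache[mol.smiles]
    return out
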