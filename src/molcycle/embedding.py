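"""The 56-dimensional latent space the translation networks operate in.

The reference pipeline obtains latent vectors from a pretrained graph
autoencoder; here the encoder/decoder is a pluggable contract.  The bundled
surrogate projects circular substructure fingerprints through a seeded
random linear map (standardised over its library) and decodes by nearest
neighbour, which guarantees an exact round trip on the library itself.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from . import LATENT_DIM
from .mol_features import MoleculeRecord, parse_molecule

_FP_BITS = 2048
_fpgen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=_FP_BITS)


def _fingerprint_array(canonical: str) -> np.ndarray:
    mol = Chem.MolFromSmiles(canonical)
    arr = np.zeros(_FP_BITS, dtype=np.float64)
    fp = _fpgen.GetFingerprint(mol)
    arr[list(fp.GetOnBits())] = 1.0
    return arr


def check_latent(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=np.float64)
    if z.shape != (LATENT_DIM,):
        raise ValueError(f"latent vector must have shape ({LATENT_DIM},), got {z.shape}")
    if not np.all(np.isfinite(z)):
        raise ValueError("latent vector must be finite")
    return z


@dataclass
class SurrogateEmbedder:
    """Fingerprint-projection embedder with nearest-neighbour decoding.

    ``decode(encode(m)) == m`` holds exactly for every library molecule,
    because a library point is its own (unique) nearest neighbour.
    """

    name: str
    library: List[Tuple[str, np.ndarray]]  # (canonical SMILES, latent)
    seed: int
    dimension: int = LATENT_DIM
    _mean: np.ndarray = None  # type: ignore[assignment]
    _scale: np.ndarray = None  # type: ignore[assignment]
    _projection: np.ndarray = None  # type: ignore[assignment]

    def encode(self, rec: MoleculeRecord) -> np.ndarray:
        if not rec.valid:
            raise ValueError("cannot encode an invalid molecule")
        fp = _fingerprint_array(rec.canonical)
        return (fp - self._mean) / self._scale @ self._projection

    def decode(self, z: np.ndarray) -> MoleculeRecord:
        z = check_latent(z)
        lib = np.stack([v for _, v in self.library])
        d2 = np.sum((lib - z) ** 2, axis=1)
        idx = int(np.argmin(d2))  # argmin takes the first minimum: library order
        return parse_molecule(self.library[idx][0])

    def library_hash(self) -> str:
        h = hashlib.sha256()
        for smi, _ in self.library:
            h.update(smi.encode())
        return h.hexdigest()[:16]


def fit_surrogate(mols: Sequence[MoleculeRecord], seed: int) -> SurrogateEmbedder:
    """Fit the surrogate embedder on a molecule library.

    Binary substructure fingerprints are standardised to zero mean / unit
    variance over the library (constant bits left unscaled) and projected
    to 56 dimensions by a seeded Gaussian linear map.
    """
    canon = []
    seen = set()
    for m in mols:
        if m.valid and m.canonical not in seen:
            seen.add(m.canonical)
            canon.append(m.canonical)
    if len(canon) < 2:
        raise ValueError(f"need at least 2 distinct valid molecules, got {len(canon)}")

    fps = np.stack([_fingerprint_array(s) for s in canon])
    mean = fps.mean(axis=0)
    std = fps.std(axis=0)
    scale = np.where(std > 0, std, 1.0)
    rng = np.random.default_rng(seed)
    projection = rng.standard_normal((_FP_BITS, LATENT_DIM)) / np.sqrt(_FP_BITS)

    latents = (fps - mean) / scale @ projection
    emb = SurrogateEmbedder(
        name="surrogate-fp56",
        library=[(s, latents[i]) for i, s in enumerate(canon)],
        seed=seed,
    )
    emb._mean = mean
    emb._scale = scale
    emb._projection = projection
    return emb


def encode(embedder, rec: MoleculeRecord) -> np.ndarray:
    return embedder.encode(rec)


def decode(embedder, z: np.ndarray):
    return embedder.decode(z)


def encode_batch(embedder, mols: Sequence[MoleculeRecord]) -> np.ndarray:
    return np.stack([embedder.encode(m) for m in mols])


@dataclass
class SyntheticDomainPair:
    x: np.ndarray  # (n, 56)
    y: np.ndarray  # (n, 56)
    true_shift: np.ndarray  # (56,)
    seed: int


def sample_synthetic_domains(
    n_per_domain: int, shift_magnitude: float, noise_sd: float, seed: int
) -> SyntheticDomainPair:
    """Two isotropic Gaussian latent domains related by a known translation.

    ``x ~ N(0, sd^2 I)``, ``y ~ N(shift, sd^2 I)`` where the shift has the
    requested magnitude along a seeded random unit direction.
    """
    if n_per_domain < 1:
        raise ValueError("n_per_domain must be >= 1")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    rng = np.random.default_rng(seed)
    direction = rng.standard_normal(LATENT_DIM)
    direction /= np.linalg.norm(direction)
    true_shift = shift_magnitude * direction
    x = noise_sd * rng.standard_normal((n_per_domain, LATENT_DIM))
    y = true_shift + noise_sd * rng.standard_normal((n_per_domain, LATENT_DIM))
    return SyntheticDomainPair(x=x, y=y, true_shift=true_shift, seed=seed)


# ---------------------------------------------------------------------------
# Latent matrix I/O: delimited text, one row per molecule, 56 columns.

def save_latents(
    path: str,
    latents: np.ndarray,
    ids: Optional[Sequence[str]] = None,
    meta: Optional[dict] = None,
) -> None:
    latents = np.asarray(latents, dtype=np.float64)
    if latents.ndim != 2 or latents.shape[1] != LATENT_DIM:
        raise ValueError(f"latent matrix must be (n, {LATENT_DIM})")
    with open(path, "w", encoding="utf-8") as fh:
        for i, row in enumerate(latents):
            prefix = f"{ids[i]}\t" if ids is not None else ""
            fh.write(prefix + "\t".join(f"{v:.10g}" for v in row) + "\n")
    if meta is not None:
        with open(path + ".json", "w", encoding="utf-8") as fh:
            json.dump(meta, fh, indent=2)


def load_latents(path: str) -> Tuple[np.ndarray, Optional[List[str]]]:
    rows, ids = [], []
    has_ids = None
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or parts == [""]:
                continue
            if has_ids is None:
                has_ids = len(parts) == LATENT_DIM + 1
            if has_ids:
                ids.append(parts[0])
                parts = parts[1:]
            if len(parts) != LATENT_DIM:
                raise ValueError(
                    f"expected {LATENT_DIM} latent columns, got {len(parts)}"
                )
            rows.append([float(v) for v in parts])
    return np.asarray(rows, dtype=np.float64), (ids if has_ids else None)
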