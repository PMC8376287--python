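"""Evaluation suite for generated molecule sets.

Set-level ratios (validity, filter pass rate, novelty, uniqueness,
non-identity, transformation success rate), fingerprint similarities
(Tanimoto, SNN, internal diversity), frequency-vector similarities over
BRICS fragments and Bemis-Murcko scaffolds, a Frechet distance over
activation statistics, and MW/logP/SA property profiles.

Conventions (documented deviations from the printed formulas):

* Frag and Scaff are reported as cosine *similarities* (higher = more
  similar), matching the benchmark suite the result tables follow; pass
  ``as_distance=True`` for the 1 - cos form.
* IntDiv_p = 1 - (mean of T^p over all ordered pairs, self-pairs
  included)^(1/p).
* The default activation provider for the Frechet distance is a
  physicochemical-descriptor surrogate, NOT the pretrained ChemNet of the
  published FCD; reports label it accordingly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, FrozenSet, Iterable, Optional, Sequence, Union

import numpy as np
import scipy.linalg
from rdkit import Chem
from rdkit.Chem import BRICS, Crippen, Descriptors, rdFingerprintGenerator, rdMolDescriptors
from rdkit.Chem.Scaffolds import MurckoScaffold

from .mol_features import DomainSpec, MoleculeRecord, passes_filters

FP_BITS = 2048
_fpgen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=FP_BITS)


def fingerprint(mol_or_smiles: Union[str, MoleculeRecord, Chem.Mol]) -> FrozenSet[int]:
    """Circular substructure fingerprint (radius 2, 2048 bits) as a bit-index set."""
    if isinstance(mol_or_smiles, MoleculeRecord):
        mol = Chem.MolFromSmiles(mol_or_smiles.canonical)
    elif isinstance(mol_or_smiles, str):
        mol = Chem.MolFromSmiles(mol_or_smiles)
    else:
        mol = mol_or_smiles
    return frozenset(_fpgen.GetFingerprint(mol).GetOnBits())


def tanimoto(a: Iterable[int], b: Iterable[int]) -> float:
    """|a & b| / |a | b|; two empty sets count as identical (1.0)."""
    a, b = set(a), set(b)
    union = len(a | b)
    if union == 0:
        return 1.0
    return len(a & b) / union


def _fp_matrix(fps: Sequence[FrozenSet[int]]) -> np.ndarray:
    m = np.zeros((len(fps), FP_BITS), dtype=np.float64)
    for i, fp in enumerate(fps):
        m[i, list(fp)] = 1.0
    return m


def _pairwise_tanimoto(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    inter = A @ B.T
    na = A.sum(axis=1)[:, None]
    nb = B.sum(axis=1)[None, :]
    union = na + nb - inter
    with np.errstate(invalid="ignore"):
        t = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 1.0)
    return t


def snn(g_fps: Sequence[FrozenSet[int]], r_fps: Sequence[FrozenSet[int]]) -> float:
    """Mean Tanimoto similarity of each generated fingerprint to its nearest reference."""
    if not g_fps or not r_fps:
        raise ValueError("both fingerprint sets must be non-empty")
    t = _pairwise_tanimoto(_fp_matrix(g_fps), _fp_matrix(r_fps))
    return float(t.max(axis=1).mean())


def intdiv(g_fps: Sequence[FrozenSet[int]], p: int = 1) -> float:
    """1 - p-power mean of pairwise Tanimoto over all ordered pairs (incl. self)."""
    if not g_fps:
        raise ValueError("fingerprint set must be non-empty")
    if p not in (1, 2):
        raise ValueError("p must be 1 or 2")
    A = _fp_matrix(g_fps)
    t = _pairwise_tanimoto(A, A)
    return float(1.0 - (np.mean(t**p)) ** (1.0 / p))


# ---------------------------------------------------------------------------
# Fragment / scaffold frequency vectors


def _as_mol(m: Union[str, MoleculeRecord, Chem.Mol]) -> Chem.Mol:
    if isinstance(m, MoleculeRecord):
        return Chem.MolFromSmiles(m.canonical)
    if isinstance(m, str):
        return Chem.MolFromSmiles(m)
    return m


def fragment_vector(mols: Sequence[Union[str, MoleculeRecord, Chem.Mol]]) -> Dict[str, int]:
    """BRICS fragment frequency map over a molecule set."""
    counts: Dict[str, int] = {}
    for m in mols:
        for frag in BRICS.BRICSDecompose(_as_mol(m)):
            key = Chem.MolToSmiles(Chem.MolFromSmiles(frag))
            counts[key] = counts.get(key, 0) + 1
    return counts


def scaffold_vector(mols: Sequence[Union[str, MoleculeRecord, Chem.Mol]]) -> Dict[str, int]:
    """Bemis-Murcko scaffold frequency map (empty scaffolds omitted)."""
    counts: Dict[str, int] = {}
    for m in mols:
        scaf = MurckoScaffold.MurckoScaffoldSmiles(mol=_as_mol(m))
        if scaf:
            counts[scaf] = counts.get(scaf, 0) + 1
    return counts


def _cosine(a: Dict[str, int], b: Dict[str, int]) -> float:
    keys = sorted(set(a) | set(b))
    if not keys:
        raise ValueError("both frequency vectors are empty")
    va = np.array([a.get(k, 0) for k in keys], dtype=np.float64)
    vb = np.array([b.get(k, 0) for k in keys], dtype=np.float64)
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise ValueError("cannot take cosine of an all-zero frequency vector")
    return float(va @ vb / (na * nb))


def frag_similarity(G, R, as_distance: bool = False) -> float:
    """Cosine similarity of BRICS fragment frequency vectors (1-cos if requested)."""
    c = _cosine(
        G if isinstance(G, dict) else fragment_vector(G),
        R if isinstance(R, dict) else fragment_vector(R),
    )
    return 1.0 - c if as_distance else c


def scaff_similarity(G, R, as_distance: bool = False) -> float:
    """Cosine similarity of Bemis-Murcko scaffold frequency vectors."""
    c = _cosine(
        G if isinstance(G, dict) else scaffold_vector(G),
        R if isinstance(R, dict) else scaffold_vector(R),
    )
    return 1.0 - c if as_distance else c


# ---------------------------------------------------------------------------
# Frechet distance over activation statistics


@dataclass
class ActivationStats:
    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=np.float64)
        self.sigma = np.asarray(self.sigma, dtype=np.float64)
        if self.sigma.shape != (self.mu.size, self.mu.size):
            raise ValueError("covariance shape must match mean dimension")
        if np.abs(self.sigma - self.sigma.T).max() > 1e-9:
            raise ValueError("covariance must be symmetric")


DESCRIPTOR_NAMES = (
    "MolWt",
    "MolLogP",
    "TPSA",
    "NumHAcceptors",
    "NumHDonors",
    "NumRotatableBonds",
    "RingCount",
    "FractionCSP3",
    "HeavyAtomCount",
)


def descriptor_activations(mols: Sequence[Union[str, MoleculeRecord, Chem.Mol]]) -> np.ndarray:
    """Default activation provider: a 9-descriptor physicochemical vector.

    A stand-in for a pretrained neural activation model; distances computed
    from it are *surrogate* values, not published-scale FCDs.
    """
    rows = []
    for m in mols:
        mol = _as_mol(m)
        rows.append(
            [
                Descriptors.MolWt(mol),
                Crippen.MolLogP(mol),
                rdMolDescriptors.CalcTPSA(mol),
                rdMolDescriptors.CalcNumHBA(mol),
                rdMolDescriptors.CalcNumHBD(mol),
                rdMolDescriptors.CalcNumRotatableBonds(mol),
                rdMolDescriptors.CalcNumRings(mol),
                rdMolDescriptors.CalcFractionCSP3(mol),
                mol.GetNumHeavyAtoms(),
            ]
        )
    return np.asarray(rows, dtype=np.float64)


def activation_stats(
    mols: Sequence,
    model: Callable[[Sequence], np.ndarray] = descriptor_activations,
) -> ActivationStats:
    """Column mean and covariance of per-molecule activation vectors."""
    if len(mols) < 2:
        raise ValueError("need at least 2 molecules for covariance statistics")
    acts = np.asarray(model(mols), dtype=np.float64)
    mu = acts.mean(axis=0)
    sigma = np.cov(acts, rowvar=False, bias=False)
    sigma = np.atleast_2d(sigma)
    return ActivationStats(mu=mu, sigma=0.5 * (sigma + sigma.T))


def _sqrtm(A: np.ndarray) -> np.ndarray:
    res = scipy.linalg.sqrtm(A)
    if isinstance(res, tuple):  # older scipy returned (sqrtm, errest)
        res = res[0]
    return np.real(res)


def fcd(a: ActivationStats, b: ActivationStats) -> float:
    """||mu_a - mu_b||^2 + Tr(S_a + S_b - 2 (S_a S_b)^{1/2})."""
    if a.mu.shape != b.mu.shape:
        raise ValueError("activation statistics have mismatched dimensions")
    diff = a.mu - b.mu
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        covmean = _sqrtm(a.sigma @ b.sigma)
        if not np.all(np.isfinite(covmean)):
            # singular product (e.g. tiny sets): jitter the diagonals
            eps = 1e-9 * np.eye(a.mu.size)
            covmean = _sqrtm((a.sigma + eps) @ (b.sigma + eps))
    val = float(diff @ diff + np.trace(a.sigma + b.sigma - 2.0 * covmean))
    if val < -1e-8:
        raise ValueError(f"Frechet distance came out negative ({val}); non-PSD input?")
    return max(val, 0.0)


# ---------------------------------------------------------------------------
# Conversion (set-level) metrics


@dataclass
class MetricReport:
    valid: float
    filters: Optional[float]
    novelty: Optional[float]
    uniqueness: Optional[float]
    non_identity: Optional[float]
    success_rate: float

    def as_dict(self) -> Dict[str, Optional[float]]:
        return {
            "valid": self.valid,
            "filters": self.filters,
            "novelty": self.novelty,
            "uniqueness": self.uniqueness,
            "non_identity": self.non_identity,
            "success_rate": self.success_rate,
        }


def conversion_metrics(
    sources: Sequence[MoleculeRecord],
    generated: Sequence[Optional[MoleculeRecord]],
    train_set: Iterable[str],
    spec: DomainSpec,
    direction: str,
) -> MetricReport:
    """Structure-transformation scores for aligned source/generated lists.

    ``generated[i]`` is the decoded translation of ``sources[i]``, or None
    for a decode failure.  ``direction`` is ``"x_to_y"`` or ``"y_to_x"``;
    success requires a valid, structurally changed molecule whose feature
    count lies in the *target* domain's count set.  Ratios other than
    ``valid`` and ``success_rate`` are conditioned on valid outputs.
    """
    if len(sources) != len(generated):
        raise ValueError("sources and generated must be aligned 1:1")
    if len(sources) == 0:
        raise ValueError("empty evaluation set")
    if direction not in ("x_to_y", "y_to_x"):
        raise ValueError("direction must be 'x_to_y' or 'y_to_x'")
    target_counts = spec.y_counts if direction == "x_to_y" else spec.x_counts
    train_set = set(train_set)

    valid_pairs = [
        (s, g) for s, g in zip(sources, generated) if g is not None and g.valid
    ]
    n = len(sources)
    nv = len(valid_pairs)
    valid = nv / n
    if nv == 0:
        return MetricReport(valid, None, None, None, None, 0.0)

    filters = sum(passes_filters(g) for _, g in valid_pairs) / nv
    uniqueness = len({g.canonical for _, g in valid_pairs}) / nv
    novelty = sum(g.canonical not in train_set for _, g in valid_pairs) / nv
    non_identical = [(s, g) for s, g in valid_pairs if g.canonical != s.canonical]
    non_identity = len(non_identical) / nv
    success = sum(
        g.feature_count(spec.feature) in target_counts for _, g in non_identical
    )
    return MetricReport(valid, filters, novelty, uniqueness, non_identity, success / n)


# ---------------------------------------------------------------------------
# Property profiles (MW / logP / SA)


@dataclass
class PropertyProfile:
    mw: np.ndarray
    logp: np.ndarray
    sa: np.ndarray
    summary: Dict[str, Dict[str, float]] = field(default_factory=dict)


def property_profile(mols: Sequence[MoleculeRecord]) -> PropertyProfile:
    """Per-molecule MW, logP and SA plus mean/median summaries."""
    mw = np.array([m.mw for m in mols], dtype=np.float64)
    logp = np.array([m.logp for m in mols], dtype=np.float64)
    sa = np.array([m.sa for m in mols], dtype=np.float64)
    summary = {}
    for name, vals in (("mw", mw), ("logp", logp), ("sa", sa)):
        summary[name] = (
            {"mean": float(vals.mean()), "median": float(np.median(vals))}
            if len(vals)
            else {"mean": float("nan"), "median": float("nan")}
        )
    return PropertyProfile(mw=mw, logp=logp, sa=sa, summary=summary)
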