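"""SMILES parsing, pharmacophore feature counting, and X/Y domain splitting.

Feature conventions
-------------------
* Ring counts are taken over the SSSR.  A ring is *aromatic* iff every bond
  in it is aromatic; any other ring is *aliphatic*.
* HBA is the Lipinski-style acceptor count (number of N and O atoms);
  HBD is the donor-atom count (each N-H / O-H heteroatom counted once).
* The corpus filter removes molecules carrying a formally charged atom.
"""

from __future__ import annotations

import json
import logging
import os
import sys
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from rdkit import Chem, RDConfig
from rdkit import RDLogger
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

RDLogger.DisableLog("rdApp.*")

sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
import sascorer  # noqa: E402  (RDKit contrib, resolved via RDConfig)

logger = logging.getLogger(__name__)

FEATURES = ("aliphatic_rings", "aromatic_rings", "hba", "hbd")


@dataclass(frozen=True)
class MoleculeRecord:
    """A parsed molecule with its feature counts and filter flags."""

    raw: str
    canonical: Optional[str] = None
    valid: bool = False
    n_aliphatic_rings: Optional[int] = None
    n_aromatic_rings: Optional[int] = None
    n_hba: Optional[int] = None
    n_hbd: Optional[int] = None
    has_charged_atom: Optional[bool] = None
    mw: Optional[float] = None
    logp: Optional[float] = None
    sa: Optional[float] = None

    def feature_count(self, feature: str) -> int:
        if not self.valid:
            raise ValueError(f"invalid record {self.raw!r} has no feature counts")
        return {
            "aliphatic_rings": self.n_aliphatic_rings,
            "aromatic_rings": self.n_aromatic_rings,
            "hba": self.n_hba,
            "hbd": self.n_hbd,
        }[feature]


@dataclass(frozen=True)
class DomainSpec:
    """A named pharmacophore feature with allowed count sets for X and Y."""

    feature: str
    x_counts: frozenset
    y_counts: frozenset

    def __post_init__(self) -> None:
        if self.feature not in FEATURES:
            raise ValueError(f"unknown feature {self.feature!r}")
        object.__setattr__(self, "x_counts", frozenset(self.x_counts))
        object.__setattr__(self, "y_counts", frozenset(self.y_counts))
        if not self.x_counts or not self.y_counts:
            raise ValueError("x_counts and y_counts must be non-empty")
        if self.x_counts & self.y_counts:
            raise ValueError("x_counts and y_counts must be disjoint")

    def domain_of(self, rec: MoleculeRecord) -> Optional[str]:
        """Return ``"x"``, ``"y"``, or ``None`` for an eligible record."""
        c = rec.feature_count(self.feature)
        if c in self.x_counts:
            return "x"
        if c in self.y_counts:
            return "y"
        return None


#: The four structural-transformation presets: X has the small count,
#: Y the neighbouring larger counts (aromatic rings: X=2, Y={1,3,4}).
PRESETS: Dict[str, DomainSpec] = {
    "aliphatic_rings": DomainSpec("aliphatic_rings", frozenset({1}), frozenset({2, 3})),
    "aromatic_rings": DomainSpec("aromatic_rings", frozenset({2}), frozenset({1, 3, 4})),
    "hba": DomainSpec("hba", frozenset({1}), frozenset({2, 3})),
    "hbd": DomainSpec("hbd", frozenset({1}), frozenset({2, 3, 4})),
}


@dataclass
class SplitResult:
    x_train: List[MoleculeRecord]
    x_test: List[MoleculeRecord]
    y_train: List[MoleculeRecord]
    y_test: List[MoleculeRecord]
    excluded: List[MoleculeRecord]
    seed: int
    spec: DomainSpec = field(default=None)  # type: ignore[assignment]

    def bins(self) -> Dict[str, List[MoleculeRecord]]:
        return {
            "x_train": self.x_train,
            "x_test": self.x_test,
            "y_train": self.y_train,
            "y_test": self.y_test,
            "excluded": self.excluded,
        }


def _count_rings(mol: Chem.Mol) -> Tuple[int, int]:
    """(aliphatic, aromatic) SSSR ring counts; aromatic = all bonds aromatic."""
    n_arom = 0
    n_alip = 0
    for bond_ring in mol.GetRingInfo().BondRings():
        if all(mol.GetBondWithIdx(b).GetIsAromatic() for b in bond_ring):
            n_arom += 1
        else:
            n_alip += 1
    return n_alip, n_arom


def parse_molecule(raw: str) -> MoleculeRecord:
    """Parse a SMILES string into a fully populated :class:`MoleculeRecord`.

    Never raises on malformed input: an unparsable string yields a record
    with ``valid=False`` and all feature fields unset.
    """
    if not raw or not raw.strip():
        raise ValueError("raw SMILES must be a non-empty string")
    mol = Chem.MolFromSmiles(raw)
    if mol is None:
        return MoleculeRecord(raw=raw)
    n_alip, n_arom = _count_rings(mol)
    sa = float(sascorer.calculateScore(mol))
    return MoleculeRecord(
        raw=raw,
        canonical=Chem.MolToSmiles(mol),
        valid=True,
        n_aliphatic_rings=n_alip,
        n_aromatic_rings=n_arom,
        n_hba=int(rdMolDescriptors.CalcNumLipinskiHBA(mol)),
        n_hbd=int(rdMolDescriptors.CalcNumHBD(mol)),
        has_charged_atom=any(a.GetFormalCharge() != 0 for a in mol.GetAtoms()),
        mw=float(Descriptors.MolWt(mol)),
        logp=float(Crippen.MolLogP(mol)),
        sa=min(10.0, max(1.0, sa)),
    )


def count_features(rec: MoleculeRecord) -> MoleculeRecord:
    """Return a record with the four feature counts populated.

    ``parse_molecule`` already populates counts; this re-derives them from
    the canonical form, which makes the operation usable on records built
    by other means (e.g. decoded molecules).
    """
    if not rec.valid:
        raise ValueError("cannot count features of an invalid record")
    mol = Chem.MolFromSmiles(rec.canonical)
    n_alip, n_arom = _count_rings(mol)
    return replace(
        rec,
        n_aliphatic_rings=n_alip,
        n_aromatic_rings=n_arom,
        n_hba=int(rdMolDescriptors.CalcNumLipinskiHBA(mol)),
        n_hbd=int(rdMolDescriptors.CalcNumHBD(mol)),
    )


def passes_filters(rec: MoleculeRecord) -> bool:
    """True iff no atom carries a nonzero formal charge."""
    if not rec.valid:
        raise ValueError("cannot filter an invalid record")
    return not rec.has_charged_atom


def dedupe(mols: Iterable[MoleculeRecord]) -> List[MoleculeRecord]:
    """Collapse duplicate canonical strings, keeping first occurrence order."""
    seen: Set[str] = set()
    out = []
    for m in mols:
        if m.canonical in seen:
            continue
        seen.add(m.canonical)
        out.append(m)
    return out


def split_domains(
    mols: Sequence[MoleculeRecord],
    spec: DomainSpec,
    train_sizes: Tuple[int, int],
    seed: int,
) -> SplitResult:
    """Partition valid, filter-passing molecules into X/Y train/test bins.

    Duplicates (by canonical string) are collapsed before assignment; the
    charge filter is applied before domain assignment.  Within each domain
    the train subset is a uniform random sample of the requested size
    (seeded); the test subset is the remainder.
    """
    valid = [m for m in mols if m.valid]
    n_dropped = len(mols) - len(valid)
    if n_dropped:
        logger.warning("dropping %d invalid molecules", n_dropped)
    pool = [m for m in dedupe(valid) if passes_filters(m)]

    by_domain: Dict[Optional[str], List[MoleculeRecord]] = {"x": [], "y": [], None: []}
    for m in pool:
        by_domain[spec.domain_of(m)].append(m)

    rng = np.random.default_rng(seed)
    out: Dict[str, List[MoleculeRecord]] = {}
    for domain, n_train in zip(("x", "y"), train_sizes):
        members = by_domain[domain]
        if n_train > len(members):
            raise ValueError(
                f"requested {n_train} training molecules for domain "
                f"{domain.upper()} but only {len(members)} are eligible"
            )
        train_idx = set(rng.choice(len(members), size=n_train, replace=False).tolist())
        out[f"{domain}_train"] = [m for i, m in enumerate(members) if i in train_idx]
        out[f"{domain}_test"] = [m for i, m in enumerate(members) if i not in train_idx]

    return SplitResult(
        x_train=out["x_train"],
        x_test=out["x_test"],
        y_train=out["y_train"],
        y_test=out["y_test"],
        excluded=by_domain[None],
        seed=seed,
        spec=spec,
    )


def feature_histogram(
    mols: Sequence[MoleculeRecord], feature: str
) -> Dict[int, int]:
    """Map each observed feature count to its frequency (absent counts omitted)."""
    hist: Dict[int, int] = {}
    for m in mols:
        c = m.feature_count(feature)
        hist[c] = hist.get(c, 0) + 1
    return hist


# ---------------------------------------------------------------------------
# SMILES line format I/O

def read_smi(path: str) -> List[MoleculeRecord]:
    """Read a ``.smi`` file: one ``SMILES[\\tID]`` per line, ``#`` comments."""
    records = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            smiles = line.split("\t")[0].split()[0]
            records.append(parse_molecule(smiles))
    return records


def write_smi(path: str, mols: Iterable[MoleculeRecord]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for m in mols:
            fh.write((m.canonical if m.valid else m.raw) + "\n")


def write_split(split: SplitResult, out_dir: str) -> Dict[str, str]:
    """Write the five .smi bins plus a JSON manifest; returns paths."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for name, members in split.bins().items():
        p = os.path.join(out_dir, f"{name}.smi")
        write_smi(p, members)
        paths[name] = p
    manifest = {
        "feature": split.spec.feature,
        "x_counts": sorted(split.spec.x_counts),
        "y_counts": sorted(split.spec.y_counts),
        "seed": split.seed,
        "counts": {name: len(members) for name, members in split.bins().items()},
    }
    mpath = os.path.join(out_dir, "split_manifest.json")
    with open(mpath, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    paths["manifest"] = mpath
    return paths


def write_histogram_csv(path: str, hist: Dict[int, int]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("count,frequency\n")
        for c in sorted(hist):
            fh.write(f"{c},{hist[c]}\n")
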