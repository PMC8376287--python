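"""Pipeline stages tying the modules together, plus bundled toy fixtures.

Stages: ``fixtures`` -> ``split`` -> ``train`` -> ``generate`` ->
``evaluate``; ``all`` chains the last four over the bundled toy corpus or
a user corpus.  Every stage is deterministic given its inputs and the
run seed, and writes a ``run.json`` provenance record.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from . import __version__
from .embedding import (
    SurrogateEmbedder,
    encode_batch,
    fit_surrogate,
    load_latents,
    sample_synthetic_domains,
    save_latents,
)
from .metrics import (
    activation_stats,
    conversion_metrics,
    fcd,
    fingerprint,
    property_profile,
    snn,
    frag_similarity,
    intdiv,
    scaff_similarity,
    tanimoto,
)
from .mol_features import (
    FEATURES,
    PRESETS,
    DomainSpec,
    MoleculeRecord,
    SplitResult,
    dedupe,
    feature_histogram,
    parse_molecule,
    passes_filters,
    read_smi,
    split_domains,
    write_histogram_csv,
    write_smi,
    write_split,
)
from .networks import generator_forward
from .training import (
    LossWeights,
    TrainConfig,
    init_bundle,
    load_checkpoint,
    save_checkpoint,
    train,
)

logger = logging.getLogger(__name__)

STAGES = ("fixtures", "split", "train", "generate", "evaluate", "all")

# Deterministic toy corpus covering every preset's X and Y count sets,
# plus charged molecules for the filter path.
_TOY_SMILES: Tuple[str, ...] = (
    # 1 aliphatic ring
    "C1CCCCC1",
    "C1CCCC1",
    "CC1CCCCC1",
    "OC1CCCCC1",
    "C1CCCCCC1",
    "CC1CCC(C)CC1",
    "C1CC1",
    "CC1(C)CCCC1",
    # 2-3 aliphatic rings
    "C1CCC2CCCCC2C1",
    "C1CC2CCC1C2",
    "C1CCC2(CC1)CCCC2",
    "C1CCC(C2CCCCC2)CC1",
    "C1C2CC3CC1CC(C2)C3",
    "C1CCC2C(C1)CCC1CCCCC21",
    "C1CC2CC3CCCC3CC2C1",
    # 1 aromatic ring
    "c1ccccc1",
    "Cc1ccccc1",
    "Oc1ccccc1",
    "Nc1ccccc1",
    "c1ccncc1",
    "Cc1ccc(C)cc1",
    # 2 aromatic rings
    "c1ccc2ccccc2c1",
    "c1ccc(-c2ccccc2)cc1",
    "c1ccc2[nH]ccc2c1",
    "Cc1ccc(-c2ccccc2)cc1",
    "c1ccc2ncccc2c1",
    # 3-4 aromatic rings
    "c1ccc2cc3ccccc3cc2c1",
    "c1ccc(-c2ccc(-c3ccccc3)cc2)cc1",
    "c1ccc2c(c1)ccc1ccccc12",
    "c1ccc2c(c1)ccc1c2ccc2ccccc21",
    "c1ccc(-c2ccccc2-c2ccccc2)cc1",
    # 1 HBA / 1 HBD
    "CCO",
    "CCCO",
    "CC(C)O",
    "CCN",
    "CCCCO",
    # 2-3 HBA / 2-4 HBD
    "OCCO",
    "OCC(O)CO",
    "OCCCO",
    "OCC(O)C(O)CO",
    "NCCO",
    "NC(=O)N",
    "NCC(O)CO",
    # charged (filtered out of every domain)
    "CC(=O)[O-]",
    "CC[NH3+]",
)


def make_toy_molecules() -> List[MoleculeRecord]:
    """Deterministic, hard-coded molecule library for tests and fixtures."""
    return [parse_molecule(s) for s in _TOY_SMILES]


@dataclass
class RunConfig:
    """Serializable configuration for a pipeline run."""

    seed: int = 0
    out_dir: str = "runs/molcycle"
    spec: str = "aliphatic_rings"
    x_counts: Optional[List[int]] = None  # override preset when both given
    y_counts: Optional[List[int]] = None
    train_sizes: Tuple[int, int] = (4, 4)
    input_smi: Optional[str] = None  # None -> bundled toy corpus
    latent_x: Optional[str] = None  # train directly from latent matrices
    latent_y: Optional[str] = None  # (bypasses split/embedding when both set)
    embedder: str = "surrogate"
    epochs: int = 20
    batch_size: int = 64
    learning_rate: float = 1e-3
    lambda1: float = 0.4
    lambda2: float = 0.15
    checkpoint_interval: int = 50
    fixture_n: int = 200
    fixture_shift: float = 3.0
    fixture_sd: float = 1.0

    def domain_spec(self) -> DomainSpec:
        if self.x_counts is not None and self.y_counts is not None:
            return DomainSpec(self.spec, frozenset(self.x_counts), frozenset(self.y_counts))
        return PRESETS[self.spec]

    def train_config(self, out_dir: Optional[str] = None) -> TrainConfig:
        return TrainConfig(
            epochs=self.epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            seed=stage_seed(self.seed, "train"),
            checkpoint_interval=self.checkpoint_interval,
            out_dir=out_dir,
        )

    def to_yaml(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.train_sizes = tuple(cfg.train_sizes)  # YAML round-trips as list
        return cfg


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed derived from the run seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big")


def _hash_file(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _write_run_json(out_dir: str, cfg: RunConfig, stage: str, inputs: Dict[str, str]) -> None:
    record = {
        "stage": stage,
        "config": dataclasses.asdict(cfg),
        "seed": cfg.seed,
        "stage_seed": stage_seed(cfg.seed, stage),
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "input_hashes": {k: _hash_file(v) for k, v in inputs.items() if os.path.exists(v)},
    }
    with open(os.path.join(out_dir, "run.json"), "w", encoding="utf-8") as fh:
        json.dump(record, fh, indent=2)


# ---------------------------------------------------------------------------
# Stages


def stage_fixtures(cfg: RunConfig, kind: str = "gaussian") -> Dict[str, str]:
    """Write synthetic fixtures: Gaussian latent domains and/or the toy corpus."""
    out = os.path.join(cfg.out_dir, "fixtures")
    os.makedirs(out, exist_ok=True)
    paths: Dict[str, str] = {}
    if kind in ("gaussian", "both"):
        pair = sample_synthetic_domains(
            cfg.fixture_n, cfg.fixture_shift, cfg.fixture_sd,
            seed=stage_seed(cfg.seed, "fixtures"),
        )
        for name, arr in (("x", pair.x), ("y", pair.y)):
            p = os.path.join(out, f"latent_{name}.tsv")
            save_latents(p, arr, meta={"kind": "gaussian", "seed": pair.seed})
            paths[f"latent_{name}"] = p
        np.savetxt(os.path.join(out, "true_shift.tsv"), pair.true_shift[None, :], delimiter="\t")
        paths["true_shift"] = os.path.join(out, "true_shift.tsv")
    if kind in ("toy", "both"):
        p = os.path.join(out, "toy.smi")
        write_smi(p, make_toy_molecules())
        paths["toy"] = p
    _write_run_json(out, cfg, "fixtures", {})
    return paths


def stage_split(cfg: RunConfig) -> SplitResult:
    out = os.path.join(cfg.out_dir, "split")
    os.makedirs(out, exist_ok=True)
    if cfg.input_smi:
        mols = read_smi(cfg.input_smi)
        inputs = {"input_smi": cfg.input_smi}
    else:
        mols = make_toy_molecules()
        inputs = {}
    split = split_domains(
        mols, cfg.domain_spec(), tuple(cfg.train_sizes), seed=stage_seed(cfg.seed, "split")
    )
    write_split(split, out)
    # corpus feature distributions (over the deduplicated, filter-passing pool)
    pool = [m for m in dedupe([m for m in mols if m.valid]) if passes_filters(m)]
    for feature in FEATURES:
        write_histogram_csv(
            os.path.join(out, f"histogram_{feature}.csv"),
            feature_histogram(pool, feature),
        )
    _write_run_json(out, cfg, "split", inputs)
    return split


def _fit_embedder(cfg: RunConfig, mols: Sequence[MoleculeRecord]) -> SurrogateEmbedder:
    if cfg.embedder != "surrogate":
        raise ValueError(f"unknown embedder {cfg.embedder!r}")
    return fit_surrogate(mols, seed=stage_seed(cfg.seed, "embed"))


def stage_train(cfg: RunConfig, split: Optional[SplitResult] = None):
    out = os.path.join(cfg.out_dir, "train")
    os.makedirs(out, exist_ok=True)
    if cfg.latent_x and cfg.latent_y:
        # direct latent-matrix training (no molecules, no embedder)
        zx, _ = load_latents(cfg.latent_x)
        zy, _ = load_latents(cfg.latent_y)
        bundle = init_bundle(
            seed=stage_seed(cfg.seed, "init"),
            weights=LossWeights(cfg.lambda1, cfg.lambda2),
        )
        tcfg = cfg.train_config(out_dir=out)
        bundle, history = train(bundle, zx, zy, tcfg)
        save_checkpoint(bundle, os.path.join(out, "final"), seed=tcfg.seed)
        history.save_csv(os.path.join(out, "history.csv"))
        _write_run_json(out, cfg, "train",
                        {"latent_x": cfg.latent_x, "latent_y": cfg.latent_y})
        return bundle, history, None
    split_dir = os.path.join(cfg.out_dir, "split")
    if split is None:
        x_path = os.path.join(split_dir, "x_train.smi")
        if not os.path.exists(x_path):
            raise FileNotFoundError(f"missing split artifact {x_path}; run the split stage first")
        x_train = read_smi(x_path)
        y_train = read_smi(os.path.join(split_dir, "y_train.smi"))
        pool = [
            m
            for name in ("x_train", "x_test", "y_train", "y_test")
            for m in read_smi(os.path.join(split_dir, f"{name}.smi"))
        ]
    else:
        x_train, y_train = split.x_train, split.y_train
        pool = split.x_train + split.x_test + split.y_train + split.y_test

    embedder = _fit_embedder(cfg, pool)
    zx = encode_batch(embedder, x_train)
    zy = encode_batch(embedder, y_train)
    save_latents(os.path.join(out, "x_train_latent.tsv"), zx,
                 meta={"embedder": embedder.name, "seed": embedder.seed,
                       "library_hash": embedder.library_hash()})
    save_latents(os.path.join(out, "y_train_latent.tsv"), zy,
                 meta={"embedder": embedder.name, "seed": embedder.seed,
                       "library_hash": embedder.library_hash()})

    bundle = init_bundle(
        seed=stage_seed(cfg.seed, "init"),
        weights=LossWeights(cfg.lambda1, cfg.lambda2),
    )
    tcfg = cfg.train_config(out_dir=out)
    bundle, history = train(bundle, zx, zy, tcfg)
    save_checkpoint(bundle, os.path.join(out, "final"), seed=tcfg.seed)
    history.save_csv(os.path.join(out, "history.csv"))
    _write_run_json(out, cfg, "train", {})
    return bundle, history, embedder


def stage_generate(cfg: RunConfig, bundle=None, embedder=None, split=None) -> Dict[str, str]:
    out = os.path.join(cfg.out_dir, "generate")
    os.makedirs(out, exist_ok=True)
    if bundle is None:
        bundle = load_checkpoint(os.path.join(cfg.out_dir, "train", "final"))
    if split is None:
        split_dir = os.path.join(cfg.out_dir, "split")
        split_mols = {
            name: read_smi(os.path.join(split_dir, f"{name}.smi"))
            for name in ("x_train", "x_test", "y_train", "y_test")
        }
    else:
        split_mols = {
            "x_train": split.x_train,
            "x_test": split.x_test,
            "y_train": split.y_train,
            "y_test": split.y_test,
        }
    if embedder is None:
        embedder = _fit_embedder(
            cfg, [m for mols in split_mols.values() for m in mols]
        )

    paths = {}
    for src_name, gen, gen_name in (
        ("x_test", bundle.G, "g_of_x"),
        ("y_test", bundle.F, "f_of_y"),
    ):
        sources = split_mols[src_name]
        if not sources:
            continue
        z = encode_batch(embedder, sources)
        z_out = generator_forward(z, gen, training=False)
        save_latents(os.path.join(out, f"{gen_name}_latent.tsv"), z_out)
        decoded = [embedder.decode(z_out[i]) for i in range(len(sources))]
        p = os.path.join(out, f"{gen_name}.smi")
        write_smi(p, decoded)
        write_smi(os.path.join(out, f"{src_name}_sources.smi"), sources)
        paths[gen_name] = p
    _write_run_json(out, cfg, "generate", {})
    return paths


def stage_evaluate(cfg: RunConfig) -> Dict[str, Dict]:
    """Score generated sets against their sources and reference sets."""
    out = os.path.join(cfg.out_dir, "evaluate")
    os.makedirs(out, exist_ok=True)
    gen_dir = os.path.join(cfg.out_dir, "generate")
    split_dir = os.path.join(cfg.out_dir, "split")
    spec = cfg.domain_spec()

    reports: Dict[str, Dict] = {}
    rows = []
    tanimoto_rows = []
    prop_rows = []
    for direction, src_name, gen_name, train_name, ref_name in (
        ("x_to_y", "x_test", "g_of_x", "x_train", "y_test"),
        ("y_to_x", "y_test", "f_of_y", "y_train", "x_test"),
    ):
        gen_path = os.path.join(gen_dir, f"{gen_name}.smi")
        if not os.path.exists(gen_path):
            continue
        sources = read_smi(os.path.join(gen_dir, f"{src_name}_sources.smi"))
        generated = read_smi(gen_path)
        train_mols = read_smi(os.path.join(split_dir, f"{train_name}.smi"))
        ref_mols = read_smi(os.path.join(split_dir, f"{ref_name}.smi"))

        report = conversion_metrics(
            sources,
            [g if g.valid else None for g in generated],
            {m.canonical for m in train_mols},
            spec,
            direction,
        ).as_dict()

        gen_valid = [g for g in generated if g.valid]
        if gen_valid and ref_mols:
            g_fps = [fingerprint(m) for m in gen_valid]
            r_fps = [fingerprint(m) for m in ref_mols]
            report["snn"] = snn(g_fps, r_fps)
            report["intdiv1"] = intdiv(g_fps, 1)
            report["intdiv2"] = intdiv(g_fps, 2)
            try:
                report["frag"] = frag_similarity(gen_valid, ref_mols)
            except ValueError:
                report["frag"] = None
            try:
                report["scaff"] = scaff_similarity(gen_valid, ref_mols)
            except ValueError:
                report["scaff"] = None
            if len(gen_valid) >= 2 and len(ref_mols) >= 2:
                report["fcd_surrogate"] = fcd(
                    activation_stats(gen_valid), activation_stats(ref_mols)
                )
            for s, g in zip(sources, generated):
                if g.valid:
                    tanimoto_rows.append(
                        (direction, s.canonical, g.canonical,
                         tanimoto(fingerprint(s), fingerprint(g)))
                    )
            prof = property_profile(gen_valid)
            for m, mw, lp, sa in zip(gen_valid, prof.mw, prof.logp, prof.sa):
                prop_rows.append((direction, m.canonical, mw, lp, sa))
        reports[direction] = report
        for metric, value in report.items():
            rows.append((direction, metric, value))

    with open(os.path.join(out, "report.csv"), "w", encoding="utf-8") as fh:
        fh.write("direction,metric,value\n")
        fh.write("# fcd_surrogate uses the descriptor activation surrogate, "
                 "not pretrained ChemNet\n")
        for direction, metric, value in rows:
            fh.write(f"{direction},{metric},{'' if value is None else value}\n")
    with open(os.path.join(out, "tanimoto_pairs.csv"), "w", encoding="utf-8") as fh:
        fh.write("direction,source,generated,tanimoto\n")
        for r in tanimoto_rows:
            fh.write(",".join(str(v) for v in r) + "\n")
    with open(os.path.join(out, "properties.csv"), "w", encoding="utf-8") as fh:
        fh.write("direction,canonical,mw,logp,sa\n")
        for r in prop_rows:
            fh.write(",".join(str(v) for v in r) + "\n")
    _write_run_json(out, cfg, "evaluate", {})
    return reports


def run_pipeline(cfg: RunConfig, stage: str = "all"):
    """Run one stage (or the whole chain) of the pipeline."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    os.makedirs(cfg.out_dir, exist_ok=True)
    if stage == "fixtures":
        return stage_fixtures(cfg)
    if stage == "split":
        return stage_split(cfg)
    if stage == "train":
        return stage_train(cfg)
    if stage == "generate":
        return stage_generate(cfg)
    if stage == "evaluate":
        return stage_evaluate(cfg)
    split = stage_split(cfg)
    bundle, history, embedder = stage_train(cfg, split=split)
    stage_generate(cfg, bundle=bundle, embedder=embedder, split=split)
    return stage_evaluate(cfg)
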