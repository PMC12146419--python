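"""One-command orchestration: similarities → embeddings → hypergraph
operators → localisation propagation → cross-validated prediction.

Each stage writes its outputs as plain TSV under ``<outdir>/cache`` and is
skipped on re-runs when the SHA-256 of its inputs (upstream files plus the
stage's parameters) matches the cache manifest.  Downstream stages always
consume the *written* artefacts, so a cached re-run reproduces the report
bit-identically.  Every run emits ``manifest.json`` with the resolved
configuration, seed and package versions.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .datamodel import (
    COMPARTMENTS,
    FeatureMatrix,
    SimilarityMatrix,
    read_matrix,
    write_matrix,
)
from .dataset import LocalizationDataset
from .embedding import Node2vecParams
from .evaluate import EvalReport, cross_validate
from .features import HYPERGRAPH_BRANCHES, FeatureBundle, FeatureParams, build_features
from .model import MirnaLocalizationModel, ModelConfig
from .similarity import ScoringScheme

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    data_dir: str
    outdir: str
    seed: int = 0
    cv_folds: int = 10
    features: FeatureParams = field(default_factory=FeatureParams)
    model: ModelConfig = field(default_factory=ModelConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        feat = raw.get("features", {})
        scoring = ScoringScheme(**feat.pop("scoring", {}))
        node2vec = Node2vecParams(**feat.pop("node2vec", {}))
        model_raw = raw.get("model", {})
        model_raw["ablation"] = frozenset(model_raw.get("ablation", []))
        return cls(
            data_dir=raw["data_dir"],
            outdir=raw.get("outdir", "mirloc_out"),
            seed=int(raw.get("seed", 0)),
            cv_folds=int(raw.get("cv_folds", 10)),
            features=FeatureParams(scoring=scoring, node2vec=node2vec, **feat),
            model=ModelConfig(**model_raw),
        )


def _digest(*parts) -> str:
    h = hashlib.sha256()
    for p in parts:
        if isinstance(p, Path):
            h.update(p.read_bytes())
        else:
            h.update(repr(p).encode())
    return h.hexdigest()


class _Cache:
    def __init__(self, outdir: Path):
        self.dir = outdir / "cache"
        self.dir.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.dir / "manifest.json"
        try:
            self.manifest = json.loads(self.manifest_path.read_text())
        except (OSError, ValueError):
            self.manifest = {}

    def stage(self, name: str, key: str, outputs: list[str], compute) -> None:
        """Run ``compute`` unless this stage's key matches and outputs exist."""
        paths = [self.dir / o for o in outputs]
        if self.manifest.get(name) == key and all(p.exists() for p in paths):
            logger.info("stage %s: cached", name)
            return
        logger.info("stage %s: computing", name)
        compute()
        missing = [p for p in paths if not p.exists()]
        if missing:
            raise RuntimeError(f"stage {name} did not produce {missing}")
        self.manifest[name] = key
        self.manifest_path.write_text(json.dumps(self.manifest, indent=1))

    def path(self, name: str) -> Path:
        return self.dir / name


def _load_similarity(path: Path) -> SimilarityMatrix:
    ids, vals, _ = read_matrix(path)
    return SimilarityMatrix(ids, vals)


def run_pipeline(cfg: RunConfig) -> EvalReport:
    """Execute all stages with caching; returns the cross-validation report."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cache = _Cache(outdir)
    data_dir = Path(cfg.data_dir)
    dataset = LocalizationDataset.from_directory(data_dir)
    fp = cfg.features

    input_files = sorted(data_dir.glob("*.tsv")) + sorted(data_dir.glob("*.fasta"))
    data_key = _digest(*input_files)

    # Heavy feature stages are computed in one pass but cached under separate
    # keys so that, e.g., changing tau only invalidates the hypergraph stage.
    sim_key = _digest(data_key, fp.scoring, fp.delta, fp.gamma_prime, fp.set_agg)
    emb_key = _digest(data_key, fp.node2vec)
    loc_key = _digest(data_key, fp.loc_mode)
    hg_key = _digest(sim_key, data_key, fp.tau, fp.fallback_k)

    bundle_box: dict[str, FeatureBundle] = {}

    def ensure_bundle() -> FeatureBundle:
        if "bundle" not in bundle_box:
            bundle_box["bundle"] = build_features(dataset, fp)
        return bundle_box["bundle"]

    def write_sims() -> None:
        b = ensure_bundle()
        write_matrix(cache.path("seq_sim.tsv"), b.seq_sim.ids, b.seq_sim.values)
        write_matrix(cache.path("fused_sim.tsv"), b.fused_sim.ids, b.fused_sim.values)

    def write_embeddings() -> None:
        b = ensure_bundle()
        for branch in HYPERGRAPH_BRANCHES:
            fm = b.branches[branch]
            write_matrix(cache.path(f"emb_{branch}.tsv"), fm.mirna_ids, fm.values)

    def write_locfeat() -> None:
        b = ensure_bundle()
        fm = b.branches["mrna_loc"]
        write_matrix(cache.path("loc_features.tsv"), fm.mirna_ids, fm.values,
                     columns=COMPARTMENTS)

    def write_operators() -> None:
        b = ensure_bundle()
        for branch in HYPERGRAPH_BRANCHES:
            write_matrix(cache.path(f"ahat_{branch}.tsv"), b.mirna_ids,
                         b.operators[branch])

    cache.stage("similarity", sim_key, ["seq_sim.tsv", "fused_sim.tsv"], write_sims)
    cache.stage("embedding", emb_key,
                [f"emb_{b}.tsv" for b in HYPERGRAPH_BRANCHES], write_embeddings)
    cache.stage("locfeat", loc_key, ["loc_features.tsv"], write_locfeat)
    cache.stage("hypergraph", hg_key,
                [f"ahat_{b}.tsv" for b in HYPERGRAPH_BRANCHES], write_operators)

    bundle = load_cached_bundle(cache.dir, dataset)

    report = cross_validate(bundle, dataset.labels, cfg.model, k=cfg.cv_folds,
                            seed=cfg.seed)
    (outdir / "report.tsv").write_text(report.to_table() + "\n")

    final = MirnaLocalizationModel(bundle, dataset.labels, cfg.model).fit(seed=cfg.seed)
    ids, probs = final.prediction_matrix()
    write_matrix(outdir / "predictions.tsv", ids, probs, columns=COMPARTMENTS)
    final.save(outdir / "model")

    manifest = {
        "seed": cfg.seed,
        "cv_folds": cfg.cv_folds,
        "config_hash": _digest(cfg.features, cfg.model, cfg.seed, cfg.cv_folds),
        "versions": _versions(),
        "mean_auc": report.mean_auc,
        "mean_aupr": report.mean_aupr,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return report


def load_cached_bundle(cache_dir: Path, dataset: LocalizationDataset) -> FeatureBundle:
    """Reassemble a FeatureBundle from the cached stage artefacts."""
    cache_dir = Path(cache_dir)
    seq_sim = _load_similarity(cache_dir / "seq_sim.tsv")
    fused = _load_similarity(cache_dir / "fused_sim.tsv")
    branches = {"seq": FeatureMatrix(seq_sim.ids, seq_sim.values, "seq")}
    operators: dict[str, np.ndarray] = {}
    for branch in HYPERGRAPH_BRANCHES:
        ids, vals, _ = read_matrix(cache_dir / f"emb_{branch}.tsv")
        branches[branch] = FeatureMatrix(ids, vals, branch)
        _, operators[branch], _ = read_matrix(cache_dir / f"ahat_{branch}.tsv")
    ids, vals, _ = read_matrix(cache_dir / "loc_features.tsv")
    branches["mrna_loc"] = FeatureMatrix(ids, vals, "mrna_loc")
    return FeatureBundle(seq_sim.ids, branches, operators, seq_sim, fused)


def _versions() -> dict[str, str]:
    import importlib.metadata as md

    out = {}
    for pkg in ("mirloc", "numpy", "scipy", "networkx", "scikit-learn", "biopython"):
        try:
            out[pkg] = md.version(pkg)
        except md.PackageNotFoundError:
            out[pkg] = "unknown"
    return out
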