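"""Gated cross-attention fusion model for multi-label miRNA localisation.

:class:`MirnaLocalizationModel` is built from a :class:`FeatureBundle`
(five feature branches plus hypergraph operators) and a miRNA label
matrix; ``fit()`` trains the head end-to-end and returns a
:class:`LocalizationResults` carrying the learned parameters, the training
history and prediction/evaluation helpers.

Architecture (single forward pass over a batch of miRNAs):

1. the three network branches are refined by stacked hypergraph
   convolutions ``X^{l+1} = ReLU(A_hat X^l W^l)`` (final layer linear);
2. each branch is projected to a common width by a ReLU-linear layer,
   yielding one token per branch;
3. a softmax gate over the branch tokens re-weights them (weights sum to 1
   per miRNA), giving the attention queries; keys/values are the ungated
   tokens;
4. multi-head scaled dot-product cross-attention, residual connection and
   layer normalisation, then mean-pooling over tokens;
5. a residual two-layer MLP with a 7-unit sigmoid output produces
   per-compartment probabilities, trained with binary cross-entropy
   (averaged over samples, summed over compartments) under Adam with
   early stopping on a held-out validation split.

Ablation flags reproduce the reduced wirings used in ablation studies:
``no_hypergraph`` (raw embeddings forward), ``no_cross_attention``
(mean-pooled projected tokens) and ``no_<branch>`` (drop a branch).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .datamodel import DataModelError, LocalizationMatrix
from .dataset import LocalizationDataset
from .features import BRANCH_ORDER, HYPERGRAPH_BRANCHES, FeatureBundle, FeatureParams, build_features

ABLATION_FLAGS = frozenset(
    {"no_hypergraph", "no_cross_attention", "no_disease", "no_drug", "no_mrna", "no_loc"}
)
_FLAG_TO_BRANCH = {"no_disease": "disease", "no_drug": "drug",
                   "no_mrna": "mrna_net", "no_loc": "mrna_loc"}


@dataclass(frozen=True)
class ModelConfig:
    d_model: int = 128
    n_heads: int = 4
    dropout: float = 0.3
    lr: float = 0.001
    batch_size: int = 64
    epochs: int = 100
    patience: int = 50
    hg_layers: int = 3
    val_fraction: float = 0.1
    bce_average: str = "samples"  # "samples": mean over N, sum over C; "elements": mean over N*C
    ablation: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")
        unknown = set(self.ablation) - ABLATION_FLAGS
        if unknown:
            raise ValueError(f"unknown ablation flags {sorted(unknown)}")

    def active_branches(self) -> tuple[str, ...]:
        dropped = {_FLAG_TO_BRANCH[f] for f in self.ablation if f in _FLAG_TO_BRANCH}
        active = tuple(b for b in BRANCH_ORDER if b not in dropped)
        if not active:
            raise ValueError("ablation removed every branch")
        return active


def bce_loss(y: np.ndarray, p: np.ndarray, average: str = "samples") -> float:
    """Binary cross-entropy; probabilities clamped to [1e-7, 1 - 1e-7].

    ``average="samples"`` divides by the number of samples only (summing
    over compartments); ``"elements"`` divides by the full element count.
    """
    y = np.asarray(y, dtype=float)
    p = np.clip(np.asarray(p, dtype=float), 1e-7, 1 - 1e-7)
    if y.shape != p.shape:
        raise DataModelError(f"shape mismatch {y.shape} vs {p.shape}")
    terms = y * np.log(p) + (1 - y) * np.log(1 - p)
    denom = y.shape[0] if average == "samples" else y.size
    return float(-terms.sum() / denom)


# ---------------------------------------------------------------------------
# parameterised sub-layers (usable standalone with frozen parameters)


def modality_gate(h: nn.Tensor, w_att: nn.Tensor, b_att: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor]:
    """Softmax gate over branch tokens; returns (weights, gated tokens).

    ``h`` has shape (n, B, d); the gate weights sum to 1 over the B axis.
    """
    logits = h @ w_att + b_att            # (n, B, 1)
    a = nn.softmax(logits, axis=1)
    return a, a * h


def multi_head_cross_attention(
    q: nn.Tensor, k: nn.Tensor, v: nn.Tensor,
    wq: nn.Tensor, wk: nn.Tensor, wv: nn.Tensor, wo: nn.Tensor,
    n_heads: int,
) -> nn.Tensor:
    """Scaled dot-product attention over branch tokens, multi-head.

    All of ``q``/``k``/``v`` have shape (n, B, d); d must divide by n_heads.
    """
    n, b, d = q.shape
    if d % n_heads:
        raise DataModelError("d_model not divisible by n_heads")
    dk = d // n_heads

    def split(x: nn.Tensor, w: nn.Tensor) -> nn.Tensor:
        return (x @ w).reshape(n, b, n_heads, dk).transpose(0, 2, 1, 3)  # (n, h, B, dk)

    qh, kh, vh = split(q, wq), split(k, wk), split(v, wv)
    scores = (qh @ kh.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dk))
    attn = nn.softmax(scores, axis=-1)
    out = (attn @ vh).transpose(0, 2, 1, 3).reshape(n, b, d)
    return out @ wo


class _Head:
    """Parameter container + forward pass of the trainable head."""

    def __init__(self, config: ModelConfig, branch_dims: dict[str, int],
                 rng: np.random.Generator):
        self.config = config
        d = config.d_model
        self.params: dict[str, nn.Tensor] = {}

        def par(name: str, value: np.ndarray) -> nn.Tensor:
            t = nn.Tensor(value, requires_grad=True)
            self.params[name] = t
            return t

        self.hg_weights: dict[str, list[nn.Tensor]] = {}
        if "no_hypergraph" not in config.ablation:
            for branch in HYPERGRAPH_BRANCHES:
                if branch not in branch_dims:
                    continue
                dims = [branch_dims[branch]] + [d] * config.hg_layers
                self.hg_weights[branch] = [
                    par(f"hg_{branch}_{l}", nn.xavier_uniform(rng, dims[l], dims[l + 1]))
                    for l in range(config.hg_layers)
                ]
                branch_dims = dict(branch_dims, **{branch: d})
        self.proj: dict[str, tuple[nn.Tensor, nn.Tensor]] = {}
        for branch, din in branch_dims.items():
            self.proj[branch] = (
                par(f"proj_w_{branch}", nn.xavier_uniform(rng, din, d)),
                par(f"proj_b_{branch}", np.zeros(d)),
            )
        self.w_att = par("gate_w", nn.xavier_uniform(rng, d, 1))
        self.b_att = par("gate_b", np.zeros(1))
        if "no_cross_attention" not in config.ablation:
            for name in ("wq", "wk", "wv", "wo"):
                par(name, nn.xavier_uniform(rng, d, d))
            par("ln_gain", np.ones(d))
            par("ln_bias", np.zeros(d))
        par("mlp_w1", nn.xavier_uniform(rng, d, d))
        par("mlp_b1", np.zeros(d))
        par("mlp_w2", nn.xavier_uniform(rng, d, d))
        par("mlp_b2", np.zeros(d))
        par("out_w", nn.xavier_uniform(rng, d, 7))
        par("out_b", np.zeros(7))

    def forward(
        self,
        branch_inputs: dict[str, np.ndarray],
        operators: dict[str, np.ndarray],
        idx: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> nn.Tensor:
        cfg = self.config
        p = self.params
        drop = cfg.dropout if training else 0.0
        rng = rng or np.random.default_rng(0)

        tokens: list[nn.Tensor] = []
        for branch in cfg.active_branches():
            x = nn.Tensor(branch_inputs[branch])
            if branch in self.hg_weights:
                a_hat = nn.Tensor(operators[branch])
                for l, w in enumerate(self.hg_weights[branch]):
                    x = a_hat @ x @ w
                    if l < len(self.hg_weights[branch]) - 1:
                        x = x.relu()
            x = x.gather_rows(idx)
            w, b = self.proj[branch]
            tokens.append(nn.linear(x, w, b).relu())

        h = nn.stack_tokens(tokens)                     # (n, B, d)
        if "no_cross_attention" in cfg.ablation:
            h_final = h.mean(axis=1)
        else:
            _, h_sel = modality_gate(h, p["gate_w"], p["gate_b"])
            attn = multi_head_cross_attention(
                h_sel, h, h, p["wq"], p["wk"], p["wv"], p["wo"], cfg.n_heads
            )
            attn = nn.dropout(attn, drop, rng, training)
            h_final = nn.layer_norm(h + attn, p["ln_gain"], p["ln_bias"]).mean(axis=1)

        h1 = (nn.linear(h_final, p["mlp_w1"], p["mlp_b1"]).relu() + h_final)
        h1 = nn.dropout(h1, drop, rng, training)
        h2 = (nn.linear(h1, p["mlp_w2"], p["mlp_b2"]).relu() + h1)
        h2 = nn.dropout(h2, drop, rng, training)
        return nn.linear(h2, p["out_w"], p["out_b"]).sigmoid()

    def loss(self, probs: nn.Tensor, y: np.ndarray) -> nn.Tensor:
        pc = probs.clip(1e-7, 1 - 1e-7)
        yt = nn.Tensor(y.astype(float))
        terms = yt * pc.log() + (1.0 - yt) * (1.0 - pc).log()
        total = -terms.sum()
        denom = y.shape[0] if self.config.bce_average == "samples" else y.size
        return total / denom

    def state(self) -> dict[str, np.ndarray]:
        return {k: t.data.copy() for k, t in self.params.items()}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for k, t in self.params.items():
            t.data = state[k].copy()


class MirnaLocalizationModel:
    """End-to-end multi-label localisation predictor over five feature branches."""

    def __init__(self, features: FeatureBundle, labels: LocalizationMatrix,
                 config: ModelConfig | None = None):
        if labels.entity_ids != features.mirna_ids:
            raise DataModelError("label rows do not match the feature miRNA order")
        self.features = features
        self.labels = labels
        self.config = config or ModelConfig()
        self.branch_inputs = {
            b: fm.values for b, fm in features.branches.items()
        }

    @classmethod
    def from_dataset(
        cls,
        dataset: LocalizationDataset,
        config: ModelConfig | None = None,
        feature_params: FeatureParams | None = None,
    ) -> "MirnaLocalizationModel":
        """Run the full feature pipeline on a dataset and wrap it in a model."""
        bundle = build_features(dataset, feature_params)
        return cls(bundle, dataset.labels, config)

    @property
    def n_mirna(self) -> int:
        return len(self.features.mirna_ids)

    def _validation_split(
        self, train_idx: np.ndarray, rng: np.random.Generator
    ) -> tuple[np.ndarray, np.ndarray]:
        """Hold out ``val_fraction`` of training miRNAs, stratified by the
        most prevalent compartment's label."""
        y = self.labels.labels[train_idx]
        k_star = int(np.argmax(y.sum(axis=0)))
        strata = y[:, k_star]
        val: list[int] = []
        for value in (0, 1):
            members = train_idx[strata == value]
            members = members[rng.permutation(len(members))]
            n_val = int(round(self.config.val_fraction * len(members)))
            val.extend(members[:n_val])
        val_idx = np.asarray(sorted(val), dtype=int)
        tr_idx = np.asarray(sorted(set(train_idx.tolist()) - set(val_idx.tolist())), dtype=int)
        if len(val_idx) == 0 or len(tr_idx) == 0:
            raise DataModelError("training set too small for a validation split")
        return tr_idx, val_idx

    def fit(self, seed: int = 0, train_idx: np.ndarray | None = None) -> "LocalizationResults":
        """Train the head with Adam + early stopping; reproducible from seed."""
        cfg = self.config
        if train_idx is None:
            train_idx = np.arange(self.n_mirna)
        train_idx = np.asarray(train_idx, dtype=int)
        rng = np.random.default_rng(seed)
        dims = {b: self.branch_inputs[b].shape[1] for b in cfg.active_branches()}
        head = _Head(cfg, dims, rng)
        optim = nn.Adam(list(head.params.values()), lr=cfg.lr)
        tr_idx, val_idx = self._validation_split(train_idx, rng)
        y = self.labels.labels

        history: list[dict[str, float]] = []
        best_val = np.inf
        best_state = head.state()
        best_epoch = -1
        stale = 0
        for epoch in range(cfg.epochs):
            order = tr_idx[rng.permutation(len(tr_idx))]
            epoch_loss = 0.0
            n_batches = 0
            for lo in range(0, len(order), cfg.batch_size):
                batch = order[lo: lo + cfg.batch_size]
                optim.zero_grad()
                probs = head.forward(
                    self.branch_inputs, self.features.operators, batch,
                    training=True, rng=rng,
                )
                loss = head.loss(probs, y[batch])
                if not np.isfinite(loss.data):
                    raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
                loss.backward()
                optim.step()
                epoch_loss += float(loss.data)
                n_batches += 1
            val_probs = head.forward(
                self.branch_inputs, self.features.operators, val_idx, training=False
            )
            val_loss = float(head.loss(val_probs, y[val_idx]).data)
            history.append(
                {"epoch": epoch, "train_loss": epoch_loss / max(1, n_batches),
                 "val_loss": val_loss}
            )
            if val_loss < best_val - 1e-9:
                best_val = val_loss
                best_state = head.state()
                best_epoch = epoch
                stale = 0
            else:
                stale += 1
                if stale >= cfg.patience:
                    break
        head.load_state(best_state)
        return LocalizationResults(self, head, seed, history, best_epoch, train_idx)


class LocalizationResults:
    """Fitted model: learned parameters, history, prediction and summary."""

    def __init__(self, model: MirnaLocalizationModel, head: _Head, seed: int,
                 history: list[dict[str, float]], best_epoch: int,
                 train_idx: np.ndarray):
        self.model = model
        self._head = head
        self.seed = seed
        self.history = history
        self.best_epoch = best_epoch
        self.train_idx = train_idx

    @property
    def params(self) -> dict[str, np.ndarray]:
        return self._head.state()

    def predict_proba(self, idx: np.ndarray | None = None) -> np.ndarray:
        """Per-compartment probabilities; deterministic (dropout off)."""
        if idx is None:
            idx = np.arange(self.model.n_mirna)
        probs = self._head.forward(
            self.model.branch_inputs, self.model.features.operators,
            np.asarray(idx, dtype=int), training=False,
        )
        return probs.data

    def prediction_matrix(self) -> tuple[tuple[str, ...], np.ndarray]:
        return self.model.features.mirna_ids, self.predict_proba()

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Mirna localisation fusion model",
            "===============================",
            f"miRNAs:            {self.model.n_mirna}",
            f"branches:          {', '.join(cfg.active_branches())}",
            f"d_model/heads:     {cfg.d_model}/{cfg.n_heads}",
            f"hypergraph layers: {cfg.hg_layers}"
            + (" (ablated)" if "no_hypergraph" in cfg.ablation else ""),
            f"parameters:        {sum(p.size for p in self.params.values())}",
            f"epochs run:        {len(self.history)} (best @ {self.best_epoch})",
            f"final train BCE:   {self.history[-1]['train_loss']:.4f}",
            f"best val BCE:      {min(h['val_loss'] for h in self.history):.4f}",
            f"seed:              {self.seed}",
        ]
        if cfg.ablation:
            lines.insert(3, f"ablation:          {', '.join(sorted(cfg.ablation))}")
        return "\n".join(lines)

    def save(self, directory) -> None:
        """Dump parameters and config as plain-text TSV + YAML."""
        import yaml
        from pathlib import Path

        from .datamodel import write_matrix

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, value in self.params.items():
            arr = value if value.ndim == 2 else value.reshape(1, -1)
            write_matrix(directory / f"{name}.tsv", [f"r{i}" for i in range(arr.shape[0])], arr)
        cfg = self.model.config
        with open(directory / "config.yaml", "w") as fh:
            yaml.safe_dump(
                {"d_model": cfg.d_model, "n_heads": cfg.n_heads, "dropout": cfg.dropout,
                 "lr": cfg.lr, "batch_size": cfg.batch_size, "epochs": cfg.epochs,
                 "patience": cfg.patience, "hg_layers": cfg.hg_layers,
                 "ablation": sorted(cfg.ablation), "seed": self.seed}, fh)


def load_results(directory, model: MirnaLocalizationModel) -> LocalizationResults:
    """Rebuild a fitted results object from a saved checkpoint directory."""
    from pathlib import Path

    from .datamodel import read_matrix

    directory = Path(directory)
    cfg = model.config
    dims = {b: model.branch_inputs[b].shape[1] for b in cfg.active_branches()}
    head = _Head(cfg, dims, np.random.default_rng(0))
    state = {}
    for name, t in head.params.items():
        _, arr, _ = read_matrix(directory / f"{name}.tsv")
        state[name] = arr.reshape(t.data.shape)
    head.load_state(state)
    return LocalizationResults(model, head, seed=-1, history=[{"epoch": -1,
                               "train_loss": float("nan"), "val_loss": float("nan")}],
                               best_epoch=-1, train_idx=np.arange(model.n_mirna))


def project_branches(
    branches: dict[str, np.ndarray],
    weights: dict[str, tuple[np.ndarray, np.ndarray]],
) -> dict[str, np.ndarray]:
    """ReLU-linear projection of each branch to the common model width."""
    out: dict[str, np.ndarray] = {}
    n = None
    for name, x in branches.items():
        if n is None:
            n = x.shape[0]
        elif x.shape[0] != n:
            raise DataModelError("branch row counts disagree")
        w, b = weights[name]
        out[name] = np.maximum(x @ w + b, 0.0)
    return out
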