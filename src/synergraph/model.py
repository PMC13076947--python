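"""End-to-end synergy regression: modality projection, fusion and training.

The predictor scores a triplet (drug i, drug j, cell line r) from four
modalities, each pushed through its own two-layer perceptron with batch
normalization into a shared latent size:

* ``g_r`` — the cell line's gene-expression profile,
* ``s_i, s_j`` — molecular-graph GCN structure embeddings (shared MLP),
* ``x_i, x_j`` — physicochemical fingerprints (shared MLP),
* ``h_{r,i}, h_{r,j}`` — the per-cell-line global-local interaction feature
  ``[U_r; Z_r]`` rows (shared MLP),

concatenated in that order and mapped to a scalar by a three-layer MLP with
batch normalization.  Training minimizes mean squared error with Adam.  The
Tucker factor ``U_r`` is computed once per fit from the training-fold graph
and held fixed; the graph transformer and all MLPs train jointly.

The user-facing surface follows the model/results convention:
:class:`SynergyModel` is constructed from a dataset and configuration,
``fit`` trains on given indices, ``fit_cv`` runs the stratified k-fold
protocol, and both return results objects with predictions, diagnostics and
``summary()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import autodiff as F
from .autodiff import Tensor
from .graphs import build_cell_graph, stack_tensor
from .gtn import GtnParams, fuse_global_local, gtn_forward
from .io import SCHEMES, SynergyDataset, binarize_labels
from .metrics import (MetricReport, classification_metrics, regression_metrics,
                      stratified_kfold)
from .molecules import GcnParams, MolBatch, encode_batch, fingerprint_matrix
from .nn import MLP, Adam, Module
from .tensor import global_features

#: component switches mirroring the ablation design: the molecular GCN
#: ("A"), the Tucker global feature, and the GTN local feature.
ALL_SWITCHES = frozenset({"molecular_gcn", "tucker_global", "gtn_local"})


@dataclass
class ModelConfig:
    """Architecture and training configuration.

    Reference values: GTN embedding size ``d=32`` and ``C=2`` channels, Adam
    at learning rate 0.001; epochs and dropout are dataset presets (see
    :mod:`synergraph.config`).  Widths below are desk-scale defaults; the
    published sensitivity optimum for the fusion MLP width (8192) is
    available by overriding ``modality_hidden``/``pred_hidden``.
    """

    # architecture
    d: int = 32
    C: int = 2
    L: int = 1
    h_attn: int | None = None          # attention hidden size; default d
    r1: int | None = None              # Tucker mode-1 rank; default min(n, d)
    mol_layers: tuple[int, ...] = (64, 64, 64)
    latent: int = 64                   # shared modality latent size
    modality_hidden: int = 128
    pred_hidden: tuple[int, ...] = (256, 128)
    # training
    lr: float = 1e-3
    epochs: int = 200
    batch_size: int | None = 256       # None = full batch
    dropout: float = 0.0
    seed: int = 0
    symmetric_augmentation: bool = True
    standardize_y: bool = True
    # graph policy
    edge_weights: str = "binary"
    graph_policy: str = "train_only"   # build graphs from training fold only


@dataclass
class TrainContext:
    """Fixed (non-trainable) inputs of one fit: per-cell-line interaction
    tensors, frozen Tucker factors, fingerprints, expression, mol batch."""

    tensors: list[np.ndarray]
    U: list[np.ndarray] | None
    X: np.ndarray
    expression: np.ndarray
    mol_batch: MolBatch | None


class FusionNetwork(Module):
    """All trainable state: per-cell-line GTNs, molecular GCN, modality MLPs
    and the prediction head."""

    def __init__(self, config: ModelConfig, switches: frozenset, n_drugs: int,
                 n_cells: int, m_fp: int, n_genes: int,
                 rng: np.random.Generator):
        self.config = config
        self.switches = switches
        h_dim = 0
        if "tucker_global" in switches:
            h_dim += min(n_drugs, config.r1 or config.d)
        if "gtn_local" in switches:
            h_dim += config.d
            self.gtns = [
                GtnParams.init(rng, m_fp, C=config.C, L=config.L, d=config.d,
                               h=config.h_attn)
                for _ in range(n_cells)
            ]
        else:
            self.gtns = []
        if "molecular_gcn" in switches:
            self.gcn = GcnParams.init(rng, sizes=config.mol_layers)

        lat, hid = config.latent, config.modality_hidden
        self.mlp_g = MLP([n_genes, hid, lat], rng)
        self.mlp_x = MLP([m_fp, hid, lat], rng)
        n_blocks = 3  # g + x_i + x_j
        if "molecular_gcn" in switches:
            self.mlp_s = MLP([config.mol_layers[-1], hid, lat], rng)
            n_blocks += 2
        if h_dim > 0:
            self.mlp_h = MLP([h_dim, hid, lat], rng)
            n_blocks += 2
        self.h_dim = h_dim
        self.mlp_pred = MLP([n_blocks * lat, *config.pred_hidden, 1], rng,
                            dropout=config.dropout)

    def parameters(self) -> list[Tensor]:
        params = super().parameters()
        for g in self.gtns:
            params.extend(g.parameters())
        if "molecular_gcn" in self.switches:
            params.extend(self.gcn.parameters())
        return params

    # -- forward pieces --------------------------------------------------------
    def interaction_features(self, ctx: TrainContext):
        """Per-cell-line global-local feature matrices ``H_r`` (or None)."""
        if self.h_dim == 0:
            return None
        out = []
        for r, tensor in enumerate(ctx.tensors):
            parts = []
            if "tucker_global" in self.switches:
                parts.append(ctx.U[r])
            if "gtn_local" in self.switches:
                parts.append(gtn_forward(tensor, ctx.X, self.gtns[r]).pooled)
            out.append(parts[0] if len(parts) == 1 else
                       fuse_global_local(parts[0], parts[1]))
        return out

    def project_and_fuse(self, g, s_i, s_j, x_i, x_j, h_i, h_j):
        """Modality MLPs + concatenation in the fixed block order
        (g', s_i', s_j', x_i', x_j', h_i', h_j'); absent modalities are
        skipped.  The s/x/h projections are shared between the pair."""
        blocks = [self.mlp_g(g)]
        if s_i is not None:
            blocks += [self.mlp_s(s_i), self.mlp_s(s_j)]
        blocks += [self.mlp_x(x_i), self.mlp_x(x_j)]
        if h_i is not None:
            blocks += [self.mlp_h(h_i), self.mlp_h(h_j)]
        return F.concat(blocks, axis=1)

    def predict_synergy(self, z):
        """Prediction head; scalar per row."""
        out = self.mlp_pred(z)
        return out.reshape(-1) if isinstance(out, Tensor) else out.reshape(-1)

    def forward(self, ctx: TrainContext, i_idx, j_idx, r_idx):
        s_all = (encode_batch(ctx.mol_batch, self.gcn)
                 if "molecular_gcn" in self.switches else None)
        H = self.interaction_features(ctx)
        if H is not None:
            n = ctx.X.shape[0]
            H_cat = F.concat(H, axis=0) if len(H) > 1 else H[0]
            flat_i, flat_j = r_idx * n + i_idx, r_idx * n + j_idx
            h_i, h_j = H_cat[flat_i], H_cat[flat_j]
        else:
            h_i = h_j = None
        s_i = s_all[i_idx] if s_all is not None else None
        s_j = s_all[j_idx] if s_all is not None else None
        z = self.project_and_fuse(
            ctx.expression[r_idx], s_i, s_j,
            ctx.X[i_idx], ctx.X[j_idx], h_i, h_j)
        return self.predict_synergy(z)


def mse_loss(pairs) -> float:
    """Mean squared error over (y, y_hat) pairs."""
    arr = np.asarray(list(pairs), dtype=float)
    if arr.size == 0:
        raise ValueError("mse_loss of an empty collection")
    return float(np.mean((arr[:, 0] - arr[:, 1]) ** 2))


def _build_context(dataset: SynergyDataset, metric: str, config: ModelConfig,
                   switches: frozenset, edge_records) -> TrainContext:
    tensors = [
        stack_tensor(build_cell_graph(dataset, cell, metric,
                                      edge_source=edge_records,
                                      edge_weights=config.edge_weights)).values
        for cell in dataset.cell_lines
    ]
    U = None
    if "tucker_global" in switches:
        r1 = min(dataset.n_drugs, config.r1 or config.d)
        U = [global_features(t, r1) for t in tensors]
    X = dataset.fingerprints
    mol_batch = (MolBatch.from_smiles([dataset.smiles[d] for d in dataset.drugs])
                 if "molecular_gcn" in switches else None)
    return TrainContext(tensors, U, X, dataset.expression, mol_batch)


@dataclass
class SynergyFit:
    """Result of one training run."""

    model: "SynergyModel"
    network: FusionNetwork
    ctx: TrainContext
    loss_history: np.ndarray      # per-epoch training MSE (standardized scale)
    y_mean: float
    y_std: float
    train_idx: np.ndarray

    def predict(self, idx=None) -> np.ndarray:
        """Predicted synergy scores for record positions ``idx`` (default:
        all records carrying the fitted metric).  With symmetric evaluation
        both pair orderings are averaged."""
        triplets = self.model.triplets if idx is None else self.model.triplets[idx]
        i, j, r = triplets[:, 0], triplets[:, 1], triplets[:, 2]
        return self.predict_triplets(i, j, r)

    def predict_triplets(self, i, j, r) -> np.ndarray:
        i = np.atleast_1d(np.asarray(i, dtype=int))
        j = np.atleast_1d(np.asarray(j, dtype=int))
        r = np.atleast_1d(np.asarray(r, dtype=int))
        net = self.network
        net.set_training(False)
        out = net.forward(self.ctx, i, j, r)
        yhat = out.data if isinstance(out, Tensor) else np.asarray(out)
        if self.model.config.symmetric_augmentation:
            out2 = net.forward(self.ctx, j, i, r)
            yhat2 = out2.data if isinstance(out2, Tensor) else np.asarray(out2)
            yhat = 0.5 * (yhat + yhat2)
        return yhat * self.y_std + self.y_mean

    @property
    def final_train_mse(self) -> float:
        """Training MSE of the last epoch, on the original score scale."""
        return float(self.loss_history[-1] * self.y_std**2)

    def summary(self) -> str:
        lines = [
            "Synergy fusion model fit",
            f"  metric:        {self.model.metric}",
            f"  components:    {sorted(self.network.switches)}",
            f"  train records: {len(self.train_idx)}",
            f"  epochs:        {len(self.loss_history)}",
            f"  final train MSE: {self.final_train_mse:.4f}",
        ]
        return "\n".join(lines)


class SynergyModel:
    """Cell line-specific synergy predictor over a :class:`SynergyDataset`.

    Parameters
    ----------
    dataset
        The study.  If it carries no fingerprint matrix, the deterministic
        fallback featurizer is applied (with a warning; results are then not
        comparable to runs using pretrained fingerprints).
    metric
        Synergy metric to predict; graphs are built from the same metric.
    switches
        Enabled components, any subset of ``{"molecular_gcn",
        "tucker_global", "gtn_local"}`` (ablation support).
    """

    def __init__(self, dataset: SynergyDataset, metric: str = "loewe",
                 config: ModelConfig | None = None,
                 switches=ALL_SWITCHES):
        if metric not in SCHEMES:
            raise ValueError(f"unknown metric {metric!r}")
        unknown = set(switches) - set(ALL_SWITCHES)
        if unknown:
            raise ValueError(f"unknown component switches {sorted(unknown)}")
        self.dataset = dataset
        self.metric = metric
        self.config = config or ModelConfig()
        self.switches = frozenset(switches)
        if dataset.expression is None:
            raise ValueError("dataset needs an expression matrix")
        if dataset.fingerprints is None:
            warnings.warn("no fingerprint matrix supplied; using the "
                          "deterministic fallback featurizer")
            dataset.fingerprints = fingerprint_matrix(
                [dataset.smiles[d] for d in dataset.drugs], seed=self.config.seed)
        # records carrying the metric, in dataset order
        self.record_positions = np.array(
            [k for k, rec in enumerate(dataset.records) if metric in rec.scores])
        if self.record_positions.size == 0:
            raise ValueError(f"no records carry metric {metric!r}")
        self.triplets = dataset.triplet_indices(metric)
        self.y = dataset.scores(metric)
        self.labels3 = dataset.labels(metric)

    # -- single fit ------------------------------------------------------------
    def fit(self, train_idx=None, seed: int | None = None,
            epochs: int | None = None) -> SynergyFit:
        """Train on record positions ``train_idx`` (default: all records).

        Graphs, tensors and Tucker factors are built from the training
        records only (leakage guard), per the configured graph policy.
        """
        cfg = self.config
        if seed is not None or epochs is not None:
            cfg = replace(cfg, seed=cfg.seed if seed is None else seed,
                          epochs=cfg.epochs if epochs is None else epochs)
        if train_idx is None:
            train_idx = np.arange(len(self.y))
        train_idx = np.asarray(train_idx, dtype=int)
        if train_idx.size == 0:
            raise ValueError("empty training fold")

        edge_records = (self.record_positions[train_idx]
                        if cfg.graph_policy == "train_only" else None)
        ctx = _build_context(self.dataset, self.metric, cfg, self.switches,
                             edge_records)
        rng = np.random.default_rng(cfg.seed)
        net = FusionNetwork(cfg, self.switches, self.dataset.n_drugs,
                            self.dataset.n_cell_lines,
                            self.dataset.fingerprints.shape[1],
                            self.dataset.expression.shape[1], rng)

        trip = self.triplets[train_idx]
        i, j, r = trip[:, 0], trip[:, 1], trip[:, 2]
        y = self.y[train_idx].astype(float)
        if cfg.symmetric_augmentation:
            i, j = np.concatenate([i, j]), np.concatenate([j, i])
            r, y = np.concatenate([r, r]), np.concatenate([y, y])
        if cfg.standardize_y:
            y_mean, y_std = float(np.mean(y)), float(np.std(y))
            y_std = y_std if y_std > 0 else 1.0
        else:
            y_mean, y_std = 0.0, 1.0
        y_s = (y - y_mean) / y_std

        optimizer = Adam(net.parameters(), lr=cfg.lr)
        n_train = len(y_s)
        bs = n_train if cfg.batch_size is None else min(cfg.batch_size, n_train)
        history = np.empty(cfg.epochs)
        net.set_training(True)
        for epoch in range(cfg.epochs):
            perm = rng.permutation(n_train)
            total, count = 0.0, 0
            for start in range(0, n_train, bs):
                sel = perm[start:start + bs]
                optimizer.zero_grad()
                yhat = net.forward(ctx, i[sel], j[sel], r[sel])
                resid = yhat - y_s[sel]
                loss = (resid**2).mean()
                if not np.isfinite(loss.data):
                    raise RuntimeError(f"training diverged at epoch {epoch}")
                loss.backward()
                optimizer.step()
                total += float(loss.data) * len(sel)
                count += len(sel)
            history[epoch] = total / count
        return SynergyFit(self, net, ctx, history, y_mean, y_std, train_idx)

    # -- cross-validation ------------------------------------------------------
    def fit_cv(self, k: int = 10, seed: int = 0,
               epochs: int | None = None) -> "CrossValidationResult":
        """Stratified k-fold cross-validation (strata = 3-class labels)."""
        folds = stratified_kfold(self.labels3, k=k, seed=seed)
        scheme = SCHEMES[self.metric]
        binary = np.array([lab == "positive"
                           for lab in binarize_labels(self.labels3)], dtype=int)
        report = MetricReport()
        rows = []
        fits = []
        for fold in range(k):
            train, test = folds.train_test(fold)
            fit = self.fit(train_idx=train, seed=seed + fold, epochs=epochs)
            fits.append(fit)
            y_hat = fit.predict(test)
            y_true = self.y[test]
            reg = regression_metrics(y_true, y_hat)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                clf = classification_metrics(binary[test], y_hat,
                                             scheme.synergy_min)
            report.add_fold(fold, reg, clf)
            for pos, t in enumerate(test):
                rec = self.dataset.records[self.record_positions[t]]
                rows.append({"drug_i": rec.drug_i, "drug_j": rec.drug_j,
                             "cell_line": rec.cell_line, "y": y_true[pos],
                             "y_hat": y_hat[pos], "fold": fold})
        predictions = pd.DataFrame(rows)
        return CrossValidationResult(self, folds, report, predictions, fits)


@dataclass
class CrossValidationResult:
    """Per-fold metrics, pooled predictions and fold-level fits."""

    model: SynergyModel
    folds: object
    report: MetricReport
    predictions: pd.DataFrame
    fits: list[SynergyFit] = field(repr=False, default_factory=list)

    def metrics_frame(self) -> pd.DataFrame:
        return self.report.to_frame()

    @property
    def mean_pcc(self) -> float:
        return float(self.metrics_frame()["pcc"].mean())

    @property
    def mean_mse(self) -> float:
        return float(self.metrics_frame()["mse"].mean())

    def per_cell_line(self) -> pd.DataFrame:
        """Regression metrics per cell line over pooled predictions."""
        rows = []
        for cell, grp in self.predictions.groupby("cell_line"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                reg = regression_metrics(grp["y"], grp["y_hat"])
            rows.append({"cell_line": cell, "n": len(grp), **reg.as_dict()})
        return pd.DataFrame(rows).set_index("cell_line")

    def summary(self) -> str:
        df = self.metrics_frame()
        lo, hi = self.report.mse_ci95()
        lines = [
            f"{self.folds.k}-fold cross-validation "
            f"({self.model.metric} metric, {len(self.predictions)} predictions)",
            f"  MSE:  {df['mse'].mean():8.3f} +/- {df['mse'].std(ddof=1):.3f}"
            f"   CI95 [{lo:.2f}, {hi:.2f}]",
            f"  RMSE: {df['rmse'].mean():8.3f} +/- {df['rmse'].std(ddof=1):.3f}",
            f"  PCC:  {df['pcc'].mean():8.3f} +/- {df['pcc'].std(ddof=1):.3f}",
        ]
        if df["auc"].notna().any():
            lines.append(
                f"  AUC:  {df['auc'].mean():8.3f}   AUPR: {df['aupr'].mean():.3f}"
                f"   ACC: {df['acc'].mean():.3f}   F1: {df['f1'].mean():.3f}"
                f"   kappa: {df['kappa'].mean():.3f}")
        return "\n".join(lines)
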