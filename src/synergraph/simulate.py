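"""Synthetic studies with the statistical structure the model assumes.

Two generators are provided:

* :func:`make_planted_tensor` plants a known low-rank Tucker structure
  (orthonormal factors, Gaussian core) in an interaction-tensor-shaped array,
  the oracle for factor-recovery tests.

* :func:`make_synthetic_study` builds a complete study — synergy records,
  toy-molecule SMILES, fingerprints, expression profiles — whose continuous
  scores follow a bilinear latent-factor surface: each drug carries a latent
  vector (with a constant coordinate, so scores have additive per-drug main
  effects as well as pure interactions), each cell line a symmetric loading
  matrix.  Scores are affinely rescaled so the published class cut-offs
  reproduce the requested class proportions.  This matches the low-rank
  assumption behind the Tucker global features, making parameter recovery
  and held-out prediction meaningful tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import SCHEMES, SynergyDataset, SynergyRecord
from .molecules import TOY_SMILES, fingerprint_matrix
from .tensor import mode_n_product


@dataclass
class SyntheticSpec:
    """Study conditions for the synthetic generator.

    Defaults describe the desk-scale reference study used throughout the
    test-suite: 20 drugs, 2 cell lines, ~80% of pairs observed (~300
    triplets), unit-variance latent signal with additive noise of standard
    deviation ``sigma``, and class proportions loosely shaped like published
    Loewe label distributions (synergy rare).
    """

    n_drugs: int = 20
    n_cell_lines: int = 2
    metrics: tuple[str, ...] = ("loewe",)
    latent_dim: int = 4
    sigma: float = 0.1
    class_proportions: tuple[float, float, float] = (0.10, 0.50, 0.40)
    #: variance share of the pure interaction term relative to main effects
    interaction_strength: float = 0.5
    density: float = 0.8
    n_genes: int = 50
    fingerprint_dim: int = 300
    seed: int = 0

    def validate(self) -> None:
        p = np.asarray(self.class_proportions, dtype=float)
        if p.shape != (3,) or np.any(p <= 0) or not np.isclose(p.sum(), 1.0):
            raise ValueError(
                f"class proportions must be 3 positive values summing to 1, got {p}")
        if not 0 < self.density <= 1:
            raise ValueError(f"density must be in (0, 1], got {self.density}")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.latent_dim < 1 or self.n_drugs < 2 or self.n_cell_lines < 1:
            raise ValueError("invalid study dimensions")
        if self.n_drugs > len(TOY_SMILES):
            raise ValueError(
                f"at most {len(TOY_SMILES)} drugs available, got {self.n_drugs}")
        for m in self.metrics:
            if m not in SCHEMES:
                raise ValueError(f"unknown metric {m!r}")


@dataclass
class SyntheticTruth:
    """Ground-truth state of a generated study."""

    drug_latents: np.ndarray | None = None        # (n, latent_dim + 1)
    cell_loadings: np.ndarray | None = None       # (R, k+1, k+1)
    signal: dict = field(default_factory=dict)    # metric -> noiseless scores
    class_counts: dict = field(default_factory=dict)  # metric -> {class: count}
    # planted-tensor fields
    core: np.ndarray | None = None
    U: np.ndarray | None = None
    V: np.ndarray | None = None
    J: np.ndarray | None = None


def _orthonormal(rng: np.random.Generator, n: int, r: int) -> np.ndarray:
    q, _ = np.linalg.qr(rng.standard_normal((n, r)))
    return q


def make_planted_tensor(
    n: int,
    ranks: tuple[int, int, int],
    sigma: float = 0.0,
    seed: int = 0,
    symmetric: bool = True,
) -> tuple[np.ndarray, SyntheticTruth]:
    """Plant a Tucker structure ``G x1 U x2 V x3 J`` plus Gaussian noise.

    With ``symmetric=True`` (default) the mode-2 factor equals the mode-1
    factor and the core is symmetrized in its first two modes, so every
    frontal slice is exactly symmetric — the structure of an undirected
    interaction tensor — while the mode-1 row space stays span(U), keeping
    the factor-recovery oracle exact.  Symmetric noise is added with entry
    standard deviation ``sigma``.
    """
    r1, r2, r3 = ranks
    if not (1 <= r1 <= n and 1 <= r2 <= n and 1 <= r3 <= 3):
        raise ValueError(f"invalid ranks {ranks} for tensor ({n}, {n}, 3)")
    if symmetric and r1 != r2:
        raise ValueError("symmetric planting requires R1 == R2")
    rng = np.random.default_rng(seed)
    U = _orthonormal(rng, n, r1)
    V = U if symmetric else _orthonormal(rng, n, r2)
    J = _orthonormal(rng, 3, r3)
    core = rng.standard_normal((r1, r2, r3))
    if symmetric:
        core = 0.5 * (core + core.transpose(1, 0, 2))
    tensor = mode_n_product(mode_n_product(mode_n_product(core, U, 0), V, 1), J, 2)
    if sigma > 0:
        noise = rng.normal(0.0, sigma, size=tensor.shape)
        if symmetric:
            noise = (noise + noise.transpose(1, 0, 2)) / np.sqrt(2.0)
        tensor = tensor + noise
    return tensor, SyntheticTruth(core=core, U=U, V=V, J=J)


def _rescale_to_scheme(raw: np.ndarray, metric: str,
                       proportions: tuple[float, float, float]) -> np.ndarray:
    """Affine map sending the empirical class-boundary quantiles of ``raw``
    onto the published cut-offs, so realized class proportions approximate
    the requested ones."""
    scheme = SCHEMES[metric]
    p_syn, _, p_ant = proportions
    lo_q = float(np.quantile(raw, p_ant))
    hi_q = float(np.quantile(raw, 1.0 - p_syn))
    if hi_q <= lo_q:
        raise ValueError("degenerate score distribution; proportions infeasible")
    scale = (scheme.synergy_min - scheme.additive_low) / (hi_q - lo_q)
    return scheme.additive_low + (raw - lo_q) * scale


def make_synthetic_study(spec: SyntheticSpec) -> tuple[SynergyDataset, SyntheticTruth]:
    """Generate a full, self-contained synthetic study."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, R, k = spec.n_drugs, spec.n_cell_lines, spec.latent_dim

    drugs = [f"D{d:03d}" for d in range(n)]
    smiles = {d: TOY_SMILES[idx] for idx, d in enumerate(drugs)}
    cells = [f"CL{c:02d}" for c in range(R)]

    # latent drug vectors with a constant coordinate -> per-drug main effects
    latents = np.hstack([np.ones((n, 1)), rng.standard_normal((n, k))])
    loadings = np.zeros((R, k + 1, k + 1))
    for c in range(R):
        main = rng.standard_normal(k)
        inter = rng.standard_normal((k, k))
        inter = spec.interaction_strength * 0.5 * (inter + inter.T) / np.sqrt(k)
        m = np.zeros((k + 1, k + 1))
        m[0, 1:] = m[1:, 0] = 0.5 * main
        m[1:, 1:] = inter
        loadings[c] = m

    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    raw = np.empty((R, len(pairs)))
    for c in range(R):
        surface = latents @ loadings[c] @ latents.T
        raw[c] = np.array([surface[i, j] for i, j in pairs])
    raw = (raw - raw.mean()) / raw.std()  # unit-variance signal
    signal = raw.copy()
    if spec.sigma > 0:
        raw = raw + rng.normal(0.0, spec.sigma, size=raw.shape)

    # observed subset of pairs, per cell line
    n_obs = max(1, int(round(spec.density * len(pairs))))
    observed = [rng.choice(len(pairs), size=n_obs, replace=False) for _ in range(R)]

    scaled = {m: _rescale_to_scheme(raw.ravel(), m, spec.class_proportions)
              .reshape(raw.shape) for m in spec.metrics}
    signal_scaled = {m: _rescale_to_scheme(signal.ravel(), m, spec.class_proportions)
                     .reshape(raw.shape) for m in spec.metrics}

    records = []
    for c in range(R):
        for p in sorted(observed[c]):
            i, j = pairs[p]
            scores = {m: float(scaled[m][c, p]) for m in spec.metrics}
            records.append(SynergyRecord(drugs[i], drugs[j], cells[c], scores))

    fingerprints = fingerprint_matrix([smiles[d] for d in drugs],
                                      m=spec.fingerprint_dim, seed=spec.seed)
    expression = (rng.standard_normal((R, spec.n_genes))
                  + rng.standard_normal((R, 1)))  # per-cell-line mean shift

    dataset = SynergyDataset(records, drugs, smiles, cells, fingerprints, expression)
    truth = SyntheticTruth(drug_latents=latents, cell_loadings=loadings,
                           signal=signal_scaled)
    for m in spec.metrics:
        counts = {"synergistic": 0, "additive": 0, "antagonistic": 0}
        for rec in records:
            counts[rec.label(m)] += 1
        truth.class_counts[m] = counts
    return dataset, truth
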