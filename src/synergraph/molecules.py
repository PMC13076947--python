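"""SMILES parsing, molecular-graph GCN encoding, and a deterministic
fingerprint featurizer.

Molecules are heavy-atom graphs (implicit hydrogens): one node per atom, one
undirected edge per bond.  Atom features are one-hot over a fixed vocabulary:
element identity (20 common elements + "other"), degree bucket (0-4+), and an
aromaticity flag.  A learnable GCN with symmetric degree normalization and
self-loops followed by global average pooling produces the structure
embedding ``s_i``.

When precomputed fingerprints (e.g. pretrained 300-dimensional graph-infomax
embeddings) are not supplied, :func:`fallback_fingerprint` provides a
deterministic stand-in: hashed circular substructure counts (radius <= 2)
pushed through a seeded random projection.  It preserves substructure
identity and determinism, not the pretrained embedding geometry, so results
with it are not comparable to runs using pretrained fingerprints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

from . import autodiff as F
from .autodiff import Tensor
from .nn import glorot

RDLogger.DisableLog("rdApp.*")

ELEMENTS = ("C", "N", "O", "S", "F", "Cl", "Br", "I", "P", "B",
            "Si", "Se", "Na", "K", "Li", "Mg", "Ca", "Zn", "Fe", "Cu")
N_DEGREE_BUCKETS = 5  # degrees 0, 1, 2, 3, 4+
FEATURE_SIZE = len(ELEMENTS) + 1 + N_DEGREE_BUCKETS + 1  # +other, +aromatic


@dataclass
class MolGraph:
    """Heavy-atom molecular graph with one-hot atom features."""

    atom_features: np.ndarray  # (a, FEATURE_SIZE)
    adjacency: np.ndarray      # (a, a) symmetric 0/1, zero diagonal
    atom_symbols: list[str]

    @property
    def n_atoms(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_bonds(self) -> int:
        return int(self.adjacency.sum() // 2)


def smiles_to_graph(smiles: str) -> MolGraph:
    """Parse a SMILES string into a :class:`MolGraph`."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    a = mol.GetNumAtoms()
    if a == 0:
        raise ValueError(f"empty molecule from SMILES: {smiles!r}")
    feats = np.zeros((a, FEATURE_SIZE))
    symbols = []
    for atom in mol.GetAtoms():
        k = atom.GetIdx()
        sym = atom.GetSymbol()
        symbols.append(sym)
        elem = ELEMENTS.index(sym) if sym in ELEMENTS else len(ELEMENTS)
        feats[k, elem] = 1.0
        deg = min(atom.GetDegree(), N_DEGREE_BUCKETS - 1)
        feats[k, len(ELEMENTS) + 1 + deg] = 1.0
        if atom.GetIsAromatic():
            feats[k, -1] = 1.0
    adj = np.zeros((a, a))
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        adj[i, j] = adj[j, i] = 1.0
    return MolGraph(feats, adj, symbols)


def _sym_norm(adj: np.ndarray) -> np.ndarray:
    """Symmetric normalization with self-loops: D~^{-1/2} (A+I) D~^{-1/2}."""
    a_tilde = adj + np.eye(adj.shape[0])
    d = a_tilde.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    return a_tilde * inv_sqrt[:, None] * inv_sqrt[None, :]


@dataclass
class GcnParams:
    """Layer weights of the molecular GCN."""

    layer_weights: list  # L_mol matrices, chained shapes

    @classmethod
    def init(cls, rng: np.random.Generator, n_in: int = FEATURE_SIZE,
             sizes: tuple[int, ...] = (64, 64, 64), trainable: bool = True):
        weights, prev = [], n_in
        for s in sizes:
            weights.append(Tensor(glorot(rng, (prev, s)), requires_grad=trainable))
            prev = s
        return cls(weights)

    @property
    def output_size(self) -> int:
        return self.layer_weights[-1].shape[1]

    def parameters(self) -> list[Tensor]:
        return list(self.layer_weights)


def gcn_encode(graph: MolGraph, params: GcnParams):
    """Encode one molecule: L symmetric-normalized propagation steps with
    ReLU, then a mean over atom rows (global average pooling)."""
    norm = _sym_norm(graph.adjacency)
    h = graph.atom_features
    for w in params.layer_weights:
        h = F.relu(norm @ (h @ w))
    return h.mean(axis=0)


@dataclass
class MolBatch:
    """All molecules of a study packed into one block-diagonal graph, so a
    single propagation encodes every drug at once."""

    features: np.ndarray  # (total_atoms, FEATURE_SIZE)
    norm_adj: np.ndarray  # (total_atoms, total_atoms), block-diagonal
    pool: np.ndarray      # (n_mols, total_atoms), row i averages molecule i

    @classmethod
    def from_smiles(cls, smiles_list: list[str]) -> "MolBatch":
        graphs = [smiles_to_graph(s) for s in smiles_list]
        sizes = [g.n_atoms for g in graphs]
        total = sum(sizes)
        feats = np.vstack([g.atom_features for g in graphs])
        norm = np.zeros((total, total))
        pool = np.zeros((len(graphs), total))
        offset = 0
        for k, g in enumerate(graphs):
            a = g.n_atoms
            norm[offset:offset + a, offset:offset + a] = _sym_norm(g.adjacency)
            pool[k, offset:offset + a] = 1.0 / a
            offset += a
        return cls(feats, norm, pool)


def encode_batch(batch: MolBatch, params: GcnParams):
    """Structure embeddings for every molecule in the batch, (n_mols, d_s)."""
    h = batch.features
    for w in params.layer_weights:
        h = F.relu(batch.norm_adj @ (h @ w))
    return batch.pool @ h


_FP_GENERATOR = None


def _morgan_counts(mol, n_bits: int = 2048) -> np.ndarray:
    global _FP_GENERATOR
    if _FP_GENERATOR is None:
        _FP_GENERATOR = rdFingerprintGenerator.GetMorganGenerator(
            radius=2, fpSize=n_bits)
    fp = _FP_GENERATOR.GetCountFingerprint(mol)
    counts = np.zeros(n_bits)
    for k, v in fp.GetNonzeroElements().items():
        counts[k] = v
    return counts


def fallback_fingerprint(smiles: str, m: int = 300, seed: int = 0) -> np.ndarray:
    """Deterministic m-dimensional fingerprint from hashed circular
    substructure counts and a seeded Gaussian random projection."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    counts = _morgan_counts(mol)
    proj = np.random.default_rng(seed).standard_normal((counts.size, m))
    return counts @ proj / np.sqrt(counts.size)


def fingerprint_matrix(smiles_list: list[str], m: int = 300, seed: int = 0) -> np.ndarray:
    """Fingerprints for a list of molecules (shared projection matrix)."""
    counts = np.stack([_morgan_counts(Chem.MolFromSmiles(s)) for s in smiles_list])
    proj = np.random.default_rng(seed).standard_normal((counts.shape[1], m))
    return counts @ proj / np.sqrt(counts.shape[1])


#: Common small molecules used by the synthetic study generator, so no
#: external chemistry resource is needed.
TOY_SMILES = [
    "CCO",                      # ethanol
    "CC(=O)O",                  # acetic acid
    "c1ccccc1",                 # benzene
    "Cc1ccccc1",                # toluene
    "Oc1ccccc1",                # phenol
    "Nc1ccccc1",                # aniline
    "CC(=O)Oc1ccccc1C(=O)O",    # aspirin
    "CC(=O)Nc1ccc(O)cc1",       # paracetamol
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",  # ibuprofen
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",  # caffeine
    "CN1CCC[C@H]1c1cccnc1",     # nicotine
    "C1CCCCC1",                 # cyclohexane
    "c1ccncc1",                 # pyridine
    "c1ccc2ccccc2c1",           # naphthalene
    "CC(C)O",                   # isopropanol
    "CCOC(=O)C",                # ethyl acetate
    "CC(C)=O",                  # acetone
    "CCN(CC)CC",                # triethylamine
    "OCC(O)CO",                 # glycerol
    "NCCO",                     # ethanolamine
    "OC(=O)c1ccccc1",           # benzoic acid
    "COc1ccccc1",               # anisole
    "Clc1ccccc1",               # chlorobenzene
    "Brc1ccccc1",               # bromobenzene
    "Fc1ccccc1",                # fluorobenzene
    "O=C(O)CC(O)(CC(=O)O)C(=O)O",  # citric acid
    "NC(=O)c1ccccc1",           # benzamide
    "CC(N)C(=O)O",              # alanine
    "NCC(=O)O",                 # glycine
    "OC(=O)C=Cc1ccccc1",        # cinnamic acid
    "CCCCCC",                   # hexane
    "CCCCO",                    # butanol
    "CC#N",                     # acetonitrile
    "CS(=O)C",                  # DMSO
    "O=S(=O)(O)O",              # sulfuric acid
    "OP(=O)(O)O",               # phosphoric acid
    "c1ccc(cc1)c1ccccc1",       # biphenyl
    "C1CCOC1",                  # tetrahydrofuran
    "C1COCCO1",                 # dioxane
    "c1cc[nH]c1",               # pyrrole
    "c1ccoc1",                  # furan
    "c1ccsc1",                  # thiophene
    "c1cnc2[nH]ccc2c1",         # azaindole
    "c1ccc2[nH]ccc2c1",         # indole
    "CC1=CC(=O)CC(C)(C)C1",     # isophorone
    "O=C1CCCCC1",               # cyclohexanone
    "OC1CCCCC1",                # cyclohexanol
    "CC(C)(C)O",                # tert-butanol
    "CNC",                      # dimethylamine
    "CCOCC",                    # diethyl ether
    "O=Cc1ccccc1",              # benzaldehyde
    "CC(=O)c1ccccc1",           # acetophenone
    "OCc1ccccc1",               # benzyl alcohol
    "NCc1ccccc1",               # benzylamine
    "CCc1ccccc1",               # ethylbenzene
    "COC(=O)c1ccccc1",          # methyl benzoate
]
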