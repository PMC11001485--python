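"""Molecular featurization, dataset I/O, scaffolds, and fixture generation.

Molecules are represented as attributed graphs with two categorical node
features (atom type over atomic numbers 1-118 plus a mask token; chirality
tag) and two categorical edge features (bond type: single/double/triple/
aromatic plus a mask token; bond direction).  Hydrogens are implicit.
Every undirected bond is stored as two directed arcs with identical
features, which is what message-passing layers consume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.Scaffolds import MurckoScaffold

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureVocab",
    "MolecularGraph",
    "LabeledDataset",
    "SmilesParseError",
    "smiles_to_graph",
    "scaffold_of",
    "generate_fixture_molecules",
    "make_synthetic_labels",
    "load_labeled_csv",
    "save_labeled_csv",
    "read_smiles_file",
    "write_smiles_file",
]


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed."""


# chirality tags, in RDKit enum order; anything beyond tetrahedral maps to OTHER
_CHIRALITY_TAGS = {
    Chem.ChiralType.CHI_UNSPECIFIED: 0,
    Chem.ChiralType.CHI_TETRAHEDRAL_CW: 1,
    Chem.ChiralType.CHI_TETRAHEDRAL_CCW: 2,
}
_CHIRALITY_OTHER = 3

_BOND_TYPES = {
    Chem.BondType.SINGLE: 0,
    Chem.BondType.DOUBLE: 1,
    Chem.BondType.TRIPLE: 2,
    Chem.BondType.AROMATIC: 3,
}

_BOND_DIRS = {
    Chem.BondDir.NONE: 0,
    Chem.BondDir.ENDUPRIGHT: 1,
    Chem.BondDir.ENDDOWNRIGHT: 2,
}


@dataclass(frozen=True)
class FeatureVocab:
    """Category counts for the categorical atom/bond features.

    The node mask indicator is the last atom-type category; the bond mask
    indicator is the last bond-type category.
    """

    atom_type_count: int = 119  # atomic numbers 1..118 + mask token
    chirality_count: int = 4
    bond_type_count: int = 5  # single/double/triple/aromatic + mask token
    bond_dir_count: int = 3

    def __post_init__(self) -> None:
        for name in ("atom_type_count", "chirality_count", "bond_type_count", "bond_dir_count"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")

    @property
    def mask_atom_index(self) -> int:
        return self.atom_type_count - 1

    @property
    def mask_bond_index(self) -> int:
        return self.bond_type_count - 1

    @property
    def num_real_atom_types(self) -> int:
        """Atom-type classes excluding the mask token (the reconstruction label space)."""
        return self.atom_type_count - 1


@dataclass
class MolecularGraph:
    """An attributed molecular graph.

    ``node_features`` is |V|x2 (atom-type index, chirality index);
    ``edge_index`` is 2x|E_directed|; ``edge_features`` is |E_directed|x2
    (bond-type index, bond-direction index).
    """

    node_features: np.ndarray
    edge_index: np.ndarray
    edge_features: np.ndarray
    smiles: str = ""

    @property
    def num_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def num_directed_edges(self) -> int:
        return self.edge_index.shape[1]

    def validate(self, vocab: FeatureVocab) -> None:
        if self.num_nodes < 1:
            raise ValueError("graph must have at least one node")
        if self.node_features.shape[1] != 2 or (
            self.num_directed_edges and self.edge_features.shape[1] != 2
        ):
            raise ValueError("feature matrices must have two columns")
        nf, ef = self.node_features, self.edge_features
        if nf[:, 0].max() >= vocab.atom_type_count or nf[:, 1].max() >= vocab.chirality_count:
            raise ValueError("node feature index out of vocabulary range")
        if self.num_directed_edges:
            if self.edge_index.min() < 0 or self.edge_index.max() >= self.num_nodes:
                raise ValueError("edge endpoint out of range")
            if ef[:, 0].max() >= vocab.bond_type_count or ef[:, 1].max() >= vocab.bond_dir_count:
                raise ValueError("edge feature index out of vocabulary range")

    def copy(self) -> "MolecularGraph":
        return MolecularGraph(
            node_features=self.node_features.copy(),
            edge_index=self.edge_index.copy(),
            edge_features=self.edge_features.copy(),
            smiles=self.smiles,
        )


@dataclass
class LabeledDataset:
    """Graphs with an n x T label matrix; NaN encodes a missing label."""

    graphs: list[MolecularGraph]
    labels: np.ndarray
    task_names: list[str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.float64)
        if self.labels.ndim != 2 or self.labels.shape[0] != len(self.graphs):
            raise ValueError("labels must be n x T with one row per graph")
        degenerate = []
        for t in range(self.labels.shape[1]):
            col = self.labels[:, t]
            observed = col[~np.isnan(col)]
            if observed.size == 0 or np.unique(observed).size < 2:
                degenerate.append(self.task_names[t])
        if degenerate:
            self.metadata.setdefault("degenerate_tasks", degenerate)
            logger.warning("degenerate task column(s): %s", degenerate)

    def __len__(self) -> int:
        return len(self.graphs)


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparseable SMILES: {smiles!r}")
    return mol


def smiles_to_graph(smiles: str, vocab: FeatureVocab | None = None) -> MolecularGraph:
    """Parse a SMILES string into a :class:`MolecularGraph`.

    Nodes follow RDKit's canonical atom ranking, so any SMILES spelling of
    the same molecule yields the same node order.  Hydrogens are implicit.
    """
    vocab = vocab or FeatureVocab()
    mol = _mol_from_smiles(smiles)
    ranks = list(Chem.CanonicalRankAtoms(mol))
    order = [int(i) for i in np.argsort(ranks, kind="stable")]
    mol = Chem.RenumberAtoms(mol, order)

    node_features = np.empty((mol.GetNumAtoms(), 2), dtype=np.int64)
    for atom in mol.GetAtoms():
        atomic_num = atom.GetAtomicNum()
        if not 1 <= atomic_num <= vocab.atom_type_count - 1:
            raise ValueError(f"atomic number {atomic_num} outside vocabulary in {smiles!r}")
        node_features[atom.GetIdx(), 0] = atomic_num - 1
        node_features[atom.GetIdx(), 1] = _CHIRALITY_TAGS.get(atom.GetChiralTag(), _CHIRALITY_OTHER)

    src, dst, feats = [], [], []
    for bond in mol.GetBonds():
        u, v = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        btype = _BOND_TYPES.get(bond.GetBondType())
        if btype is None:
            raise ValueError(f"unsupported bond type {bond.GetBondType()} in {smiles!r}")
        bdir = _BOND_DIRS.get(bond.GetBondDir(), 0)
        src.extend((u, v))
        dst.extend((v, u))
        feats.extend(((btype, bdir), (btype, bdir)))

    graph = MolecularGraph(
        node_features=node_features,
        edge_index=np.asarray([src, dst], dtype=np.int64).reshape(2, -1),
        edge_features=np.asarray(feats, dtype=np.int64).reshape(-1, 2),
        smiles=smiles,
    )
    graph.validate(vocab)
    return graph


def scaffold_of(smiles: str) -> str:
    """Canonical Bemis-Murcko scaffold SMILES; acyclic molecules map to ''."""
    mol = _mol_from_smiles(smiles)
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    if scaffold is None or scaffold.GetNumAtoms() == 0:
        return ""
    return Chem.MolToSmiles(scaffold)


# --------------------------------------------------------------------------
# Fixture generation: a deterministic pool of small drug-like molecules that
# stands in for a large unlabeled corpus during development and testing.
# --------------------------------------------------------------------------

_RING_CORES = [
    "c1ccccc1",        # benzene
    "c1ccncc1",        # pyridine
    "c1ccc2ccccc2c1",  # naphthalene
    "c1ccoc1",         # furan
    "c1ccsc1",         # thiophene
    "c1cc[nH]c1",      # pyrrole
    "C1CCNCC1",        # piperidine
    "C1CCCCC1",        # cyclohexane
    "C1CCOC1",         # tetrahydrofuran
    "c1ccc2[nH]ccc2c1",  # indole
]

# fragments written so that their last atom bonds to the core's first atom
_SUBSTITUENTS = [
    "C", "CC", "CCC", "CC(C)", "N", "NC", "O", "OC", "OCC",
    "F", "Cl", "Br", "I", "C(F)(F)F", "CC(=O)", "N#C", "OCC(=O)", "CS",
]

_ACYCLIC = [
    "C", "CC", "CCC", "CCCC", "CCCCC", "CCCCCC", "CC(C)C", "CC(C)CC",
    "CCO", "CCCO", "CC(C)O", "OCCO", "COC", "CCOC", "CCOCC", "CCCOC",
    "CN", "CCN", "CCCN", "CNC", "CCNCC", "CN(C)C",
    "CCl", "CCCl", "CCCCl", "CBr", "CCBr", "CI", "CCI", "CF", "CCF",
    "FC(F)F", "ClCCCl", "BrCCBr",
    "CC=O", "CCC=O", "CC(=O)C", "CC(=O)CC", "CC(=O)O", "CCC(=O)O",
    "CC#N", "CCC#N", "CSC", "CCS", "CCSC", "CS",
]

_REQUIRED_SYMBOLS = ("C", "N", "O", "S", "F", "Cl", "Br", "I")


def _fixture_pool() -> list[str]:
    """Canonical, de-duplicated pool of generated molecules (deterministic)."""
    candidates: list[str] = list(_ACYCLIC)
    for core in _RING_CORES:
        candidates.append(core)
        for sub in _SUBSTITUENTS:
            candidates.append(sub + core)
    # disubstituted benzenes widen the scaffold-sharing structure
    for s1 in _SUBSTITUENTS:
        for s2 in _SUBSTITUENTS[:9]:
            candidates.append(f"{s1}c1ccc({s2})cc1")
    pool: list[str] = []
    seen: set[str] = set()
    for smi in candidates:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:  # pragma: no cover - templates are curated to parse
            continue
        canonical = Chem.MolToSmiles(mol)
        if canonical not in seen:
            seen.add(canonical)
            pool.append(canonical)
    return pool


def _atom_symbols(smiles: str) -> set[str]:
    return {a.GetSymbol() for a in _mol_from_smiles(smiles).GetAtoms()}


def generate_fixture_molecules(n: int, seed: int) -> list[str]:
    """Draw ``n`` distinct, parseable SMILES from the seeded fixture pool.

    Any sample of at least 64 molecules covers all eight heavy-atom element
    types the pool uses and at least five Bemis-Murcko scaffolds, so small
    corpora already exercise the full feature vocabulary.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    pool = _fixture_pool()
    if n > len(pool):
        raise ValueError(f"fixture generator capacity is {len(pool)} distinct molecules")
    rng = np.random.default_rng(seed)
    shuffled = [pool[i] for i in rng.permutation(len(pool))]
    sample = shuffled[:n]
    if n >= 64:
        # guarantee element coverage by swapping in carriers of missing types
        present: set[str] = set()
        for smi in sample:
            present |= _atom_symbols(smi)
        missing = [s for s in _REQUIRED_SYMBOLS if s not in present]
        replace_at = n - 1
        for symbol in missing:
            donor = next(s for s in shuffled[n:] if symbol in _atom_symbols(s))
            sample[replace_at] = donor
            replace_at -= 1
    return sample


def make_synthetic_labels(
    graphs: Sequence[MolecularGraph],
    rule: str | Sequence[str],
    noise_rate: float = 0.0,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> LabeledDataset:
    """Label molecules by substructure match, with optional label noise.

    Each rule is a SMARTS pattern; the clean label is 1 iff the molecule
    contains the pattern.  Labels are then flipped independently with
    probability ``noise_rate`` and masked to missing with probability
    ``missing_rate``.
    """
    if not (0 <= noise_rate < 0.5 and 0 <= missing_rate < 0.5):
        raise ValueError("noise_rate and missing_rate must lie in [0, 0.5)")
    rules = [rule] if isinstance(rule, str) else list(rule)
    patterns = []
    for r in rules:
        patt = Chem.MolFromSmarts(r)
        if patt is None:
            raise ValueError(f"invalid SMARTS pattern: {r!r}")
        patterns.append(patt)

    rng = np.random.default_rng(seed)
    n, T = len(graphs), len(rules)
    labels = np.zeros((n, T), dtype=np.float64)
    for i, g in enumerate(graphs):
        mol = _mol_from_smiles(g.smiles)
        for t, patt in enumerate(patterns):
            labels[i, t] = float(mol.HasSubstructMatch(patt))
    flip = rng.random((n, T)) < noise_rate
    labels = np.where(flip, 1.0 - labels, labels)
    miss = rng.random((n, T)) < missing_rate
    labels = np.where(miss, np.nan, labels)
    return LabeledDataset(list(graphs), labels, [f"task_{r}" for r in rules])


# ------------------------------------------------------------------ file I/O

def read_smiles_file(path: str | Path) -> list[str]:
    """Read one SMILES per line; blank lines and '#' comments are skipped."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            out.append(line)
    return out


def write_smiles_file(path: str | Path, smiles: Iterable[str]) -> None:
    Path(path).write_text("".join(f"{s}\n" for s in smiles))


def load_labeled_csv(
    path: str | Path,
    smiles_column: str = "smiles",
    vocab: FeatureVocab | None = None,
) -> LabeledDataset:
    """Load a multi-task CSV (one SMILES column, numeric task columns).

    Empty cells become missing labels.  Rows with unparseable SMILES are
    dropped; the count is logged and recorded in the dataset metadata.
    """
    frame = pd.read_csv(path)
    if smiles_column not in frame.columns:
        raise KeyError(f"column {smiles_column!r} not found in {path}")
    task_names = [c for c in frame.columns if c != smiles_column]
    graphs, rows = [], []
    dropped = 0
    for _, row in frame.iterrows():
        try:
            graphs.append(smiles_to_graph(str(row[smiles_column]), vocab))
        except (SmilesParseError, ValueError):
            dropped += 1
            continue
        rows.append([float(row[c]) if pd.notna(row[c]) else np.nan for c in task_names])
    if dropped:
        logger.warning("dropped %d unparseable SMILES row(s) from %s", dropped, path)
    if not graphs:
        raise ValueError(f"no valid SMILES rows in {path}")
    labels = np.asarray(rows, dtype=np.float64).reshape(len(graphs), len(task_names))
    return LabeledDataset(graphs, labels, task_names, metadata={"dropped_rows": dropped})


def save_labeled_csv(dataset: LabeledDataset, path: str | Path, smiles_column: str = "smiles") -> None:
    frame = pd.DataFrame({smiles_column: [g.smiles for g in dataset.graphs]})
    for t, name in enumerate(dataset.task_names):
        frame[name] = dataset.labels[:, t]
    frame.to_csv(path, index=False)
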