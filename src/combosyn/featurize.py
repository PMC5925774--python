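"""Chemical and genomic feature blocks.

Drugs are described by three blocks computed from SMILES: counts of
extended-connectivity substructure environments (ECFP, diameter 6 = radius
3, hashed and folded), a fixed panel of physico-chemical descriptors, and
binary toxicophore flags from a configurable SMARTS set.  Cell lines are
described by a gene-expression block loaded from a summarized matrix,
optionally restricted to an informative-gene mask produced upstream.

Every block carries a per-column kind tag in {count, continuous, binary};
the tags survive filtering and concatenation because the MinMax kernel
downstream needs to know which continuous columns to split into positive
and negative parts.

Feature matrices are reduced by dropping columns with exactly zero variance
over a reference (training) set; the retained-column mask is reusable on
new entities so train and test vectors always align.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdFingerprintGenerator, rdMolDescriptors

__all__ = [
    "FeatureBlock",
    "ToxicophoreSet",
    "DEFAULT_TOXICOPHORES",
    "PHYSCHEM_DESCRIPTORS",
    "SmilesParseError",
    "EmptyBlockError",
    "parse_smiles",
    "ecfp_counts",
    "toxicophore_flags",
    "physchem_descriptors",
    "featurize_drugs",
    "zero_variance_filter",
    "load_expression",
    "read_smiles_file",
]

KINDS = ("count", "continuous", "binary")


class SmilesParseError(ValueError):
    """A SMILES string could not be parsed; the message names the input."""


class EmptyBlockError(ValueError):
    """A filter removed every column of a feature block."""


@dataclass(frozen=True)
class FeatureBlock:
    """Entity x feature matrix with typed, uniquely named columns.

    ``values`` is a DataFrame indexed by entity identifier; ``kinds`` maps
    each column to one of {count, continuous, binary}.
    """

    values: pd.DataFrame
    kinds: pd.Series

    def __post_init__(self):
        if not self.values.columns.is_unique:
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature columns: {dupes[:5]}")
        if list(self.kinds.index) != list(self.values.columns):
            raise ValueError("kinds must be indexed exactly by the value columns")
        bad = set(self.kinds.unique()) - set(KINDS)
        if bad:
            raise ValueError(f"unknown column kinds {bad}")
        vals = self.values
        for col in self.kinds.index[self.kinds == "count"]:
            v = vals[col].to_numpy()
            if np.any(v < 0) or np.any(v != np.floor(v)):
                raise ValueError(f"count column {col!r} must hold nonnegative integers")
        for col in self.kinds.index[self.kinds == "binary"]:
            if not np.isin(vals[col].to_numpy(), (0, 1)).all():
                raise ValueError(f"binary column {col!r} must be 0/1")

    @property
    def column_names(self) -> list[str]:
        return list(self.values.columns)

    def select_columns(self, columns) -> "FeatureBlock":
        return FeatureBlock(self.values[list(columns)], self.kinds[list(columns)])

    @staticmethod
    def concat(blocks: list["FeatureBlock"]) -> "FeatureBlock":
        """Column-wise concatenation of blocks sharing an entity index."""
        values = pd.concat([b.values for b in blocks], axis=1)
        kinds = pd.concat([b.kinds for b in blocks])
        return FeatureBlock(values, kinds)


class ToxicophoreSet:
    """Named SMARTS substructure patterns, validated at load time."""

    def __init__(self, patterns: dict[str, str]):
        self.names: list[str] = []
        self._mols: list[Chem.Mol] = []
        bad = []
        for name, smarts in patterns.items():
            query = Chem.MolFromSmarts(smarts)
            if query is None:
                bad.append((name, smarts))
            else:
                self.names.append(name)
                self._mols.append(query)
        if bad:
            raise ValueError(f"invalid SMARTS patterns: {bad}")

    def __len__(self) -> int:
        return len(self.names)

    def matches(self, mol: Chem.Mol) -> np.ndarray:
        return np.array(
            [int(mol.HasSubstructMatch(q)) for q in self._mols], dtype=np.int64
        )

    @classmethod
    def from_file(cls, path) -> "ToxicophoreSet":
        """Load a ``name<TAB>pattern`` file (blank lines and # comments skipped)."""
        patterns = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                name, _, smarts = line.partition("\t")
                patterns[name.strip()] = smarts.strip()
        return cls(patterns)


# Default toxicophore panel: widely cited structural alerts (nitro/azo
# groups, Michael acceptors, reactive carbonyls, alkylating motifs).  The
# set is deliberately small and overridable via a SMARTS file.
DEFAULT_TOXICOPHORES = ToxicophoreSet(
    {
        "nitroaromatic": "[c][N+](=O)[O-]",
        "aromatic_amine": "[NX3;H2,H1;!$(NC=O)][c]",
        "azo": "[#6]N=N[#6]",
        "aromatic_nitroso": "[c]N=O",
        "aliphatic_halide": "[CX4][Cl,Br,I]",
        "epoxide": "C1OC1",
        "aziridine": "C1NC1",
        "aldehyde": "[CX3H1](=O)[#6]",
        "michael_acceptor": "[CX3]=[CX3][CX3]=[OX1]",
        "quinone": "O=C1C=CC(=O)C=C1",
        "hydrazine": "[NX3][NX3]",
        "acyl_halide": "[CX3](=O)[Cl,Br,I]",
        "isocyanate": "N=C=O",
        "thiourea": "[NX3][CX3](=S)[NX3]",
        "polycyclic_aromatic": "c1ccc2cc3ccccc3cc2c1",
    }
)


def parse_smiles(smiles: str) -> Chem.Mol:
    """Parse SMILES and keep the largest covalent fragment (salt stripping)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"could not parse SMILES {smiles!r}")
    frags = Chem.GetMolFrags(mol, asMols=True)
    if len(frags) > 1:
        mol = max(frags, key=lambda m: m.GetNumHeavyAtoms())
    return mol


def ecfp_counts(smiles: str, radius: int = 3, fold_size: int = 2048) -> pd.Series:
    """Hashed counts of circular atom environments up to ``radius`` bonds.

    Radius 3 corresponds to diameter-6 extended-connectivity fingerprints.
    Returns a Series of ``fold_size`` nonnegative integer counts named
    ``ecfp_0000`` ...; identical structures give identical vectors.
    """
    mol = parse_smiles(smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=fold_size)
    fp = gen.GetCountFingerprint(mol)
    counts = np.zeros(fold_size, dtype=np.int64)
    for idx, count in fp.GetNonzeroElements().items():
        counts[idx] = count
    width = len(str(fold_size - 1))
    return pd.Series(
        counts, index=[f"ecfp_{i:0{width}d}" for i in range(fold_size)]
    )


def toxicophore_flags(
    smiles: str, patterns: ToxicophoreSet = DEFAULT_TOXICOPHORES
) -> pd.Series:
    """Binary flag per toxicophore pattern: 1 iff the substructure matches."""
    mol = parse_smiles(smiles)
    return pd.Series(patterns.matches(mol), index=[f"tox_{n}" for n in patterns.names])


# The physico-chemical panel: name -> (callable on Mol, description).  The
# exact list is this package's own documented choice.
PHYSCHEM_DESCRIPTORS: dict[str, tuple] = {
    "mol_weight": (Descriptors.MolWt, "molecular weight, g/mol"),
    "logp": (Crippen.MolLogP, "Crippen logP estimate"),
    "tpsa": (rdMolDescriptors.CalcTPSA, "topological polar surface area, A^2"),
    "hbd": (Lipinski.NumHDonors, "H-bond donor count"),
    "hba": (Lipinski.NumHAcceptors, "H-bond acceptor count"),
    "rotatable_bonds": (Lipinski.NumRotatableBonds, "rotatable bond count"),
    "ring_count": (rdMolDescriptors.CalcNumRings, "ring count"),
    "aromatic_rings": (rdMolDescriptors.CalcNumAromaticRings, "aromatic ring count"),
    "heavy_atoms": (Descriptors.HeavyAtomCount, "non-hydrogen atom count"),
    "fraction_csp3": (rdMolDescriptors.CalcFractionCSP3, "fraction sp3 carbons"),
    "molar_refractivity": (Crippen.MolMR, "Crippen molar refractivity"),
    "formal_charge": (Chem.GetFormalCharge, "net formal charge"),
    "hetero_atoms": (rdMolDescriptors.CalcNumHeteroatoms, "heteroatom count"),
    "stereo_centers": (
        rdMolDescriptors.CalcNumAtomStereoCenters,
        "assigned stereocenter count",
    ),
}


def physchem_descriptors(smiles: str) -> pd.Series:
    """Continuous descriptor panel for one structure; deterministic.

    A descriptor that fails for a molecule is reported as NaN (flagged
    missing), never silently zero.
    """
    mol = parse_smiles(smiles)
    out = {}
    for name, (func, _doc) in PHYSCHEM_DESCRIPTORS.items():
        try:
            out[name] = float(func(mol))
        except Exception:  # noqa: BLE001 - descriptor failure is data, not a bug
            out[name] = np.nan
    return pd.Series(out).add_prefix("pc_")


def featurize_drugs(
    smiles: dict[str, str],
    radius: int = 3,
    fold_size: int = 2048,
    toxicophores: ToxicophoreSet = DEFAULT_TOXICOPHORES,
) -> FeatureBlock:
    """Full chemical block (counts + continuous + binary) for a drug panel."""
    rows = {}
    for drug, smi in smiles.items():
        rows[drug] = pd.concat(
            [
                ecfp_counts(smi, radius=radius, fold_size=fold_size),
                physchem_descriptors(smi),
                toxicophore_flags(smi, toxicophores),
            ]
        )
    values = pd.DataFrame.from_dict(rows, orient="index")
    kinds = pd.Series("continuous", index=values.columns)
    kinds[kinds.index.str.startswith("ecfp_")] = "count"
    kinds[kinds.index.str.startswith("tox_")] = "binary"
    return FeatureBlock(values, kinds)


def zero_variance_filter(
    block: FeatureBlock, reference_rows=None
) -> tuple[FeatureBlock, pd.Series]:
    """Drop columns whose variance over the reference rows is exactly zero.

    ``reference_rows`` defaults to all rows; the returned boolean mask
    (indexed by original column) is reusable on blocks for new entities so
    train/test columns stay aligned.
    """
    ref = block.values if reference_rows is None else block.values.loc[list(reference_rows)]
    if ref.empty:
        raise ValueError("reference rows must be nonempty")
    arr = ref.to_numpy(float)
    mask = pd.Series(arr.max(axis=0) != arr.min(axis=0), index=block.values.columns)
    if not mask.any():
        raise EmptyBlockError("zero-variance filter would drop every column")
    kept = mask.index[mask]
    return block.select_columns(kept), mask


def load_expression(matrix_path, mask_path=None) -> FeatureBlock:
    """Load a summarized genes x cell-lines expression matrix as a cell-line block.

    The optional mask file lists one informative gene per line (order
    preserved); genes absent from the matrix raise with the missing names.
    No re-normalization is applied — summarization happens upstream.
    """
    mat = pd.read_csv(matrix_path, sep=None, engine="python", index_col=0)
    if mask_path is not None:
        with open(mask_path) as fh:
            genes = [line.strip() for line in fh if line.strip()]
        missing = [g for g in genes if g not in mat.index]
        if missing:
            raise ValueError(f"mask genes absent from expression matrix: {missing}")
        mat = mat.loc[genes]
    values = mat.T  # cell lines x genes
    values.columns = [f"expr_{g}" for g in values.columns]
    return FeatureBlock(values, pd.Series("continuous", index=values.columns))


def read_smiles_file(path) -> dict[str, str]:
    """Read one-structure-per-line SMILES, optional tab-separated identifier."""
    out = {}
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            smi, _, name = line.partition("\t")
            out[name.strip() or f"mol_{i}"] = smi.strip()
    return out
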