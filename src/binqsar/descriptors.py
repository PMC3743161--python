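"""2D molecular descriptors: atom/bond counts, rotatable/rigid bonds,
Wiener polarity, PEOE partial charges, approximate van der Waals surface
areas and the binned VSA descriptor block, plus the three amino-acid
scaffold indicator variables (R-/S-nipecotic acid, guvacine).

All surface-area work uses a conformation-free approximation: each atom of
the hydrogen-explicit molecule contributes its van der Waals sphere area
minus the spherical caps buried by its bonded neighbours, with ideal bond
lengths taken as the sum of covalent radii.  Because every atom lands in
exactly one bin of each property partition, each VSA bin family sums to
``vdw_area`` by construction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem, Crippen, Descriptors, rdCIPLabeler, rdMolDescriptors, rdmolops

from .chem_io import CompoundRecord

SetTag = Literal["vsa_ind", "physchem16", "contingency_selected", "custom"]

# ---------------------------------------------------------------------------
# VSA bin boundaries (interior bin edges; outer bins open).
# SlogP: 10 bins over the Crippen atomic logP contribution.
# SMR:    8 bins over the Crippen atomic molar-refractivity contribution.
# PEOE:  14 bins over the PEOE partial charge, -0.30..+0.30 in 0.05 steps.
# ---------------------------------------------------------------------------
SLOGP_BIN_EDGES: tuple[float, ...] = (-0.4, -0.2, 0.0, 0.1, 0.15, 0.2, 0.25, 0.3, 0.4)
SMR_BIN_EDGES: tuple[float, ...] = (0.11, 0.26, 0.35, 0.39, 0.44, 0.485, 0.56)
PEOE_BIN_EDGES: tuple[float, ...] = tuple(np.round(np.arange(-0.30, 0.301, 0.05), 10))

SLOGP_NAMES = tuple(f"SlogP_VSA{i}" for i in range(10))
SMR_NAMES = tuple(f"SMR_VSA{i}" for i in range(8))
PEOE_NAMES = tuple(f"PEOE_VSA{i}" for i in range(14))
VSA_BLOCK_NAMES = SLOGP_NAMES + SMR_NAMES + PEOE_NAMES
INDICATOR_NAMES = ("ind_R_nipecotic", "ind_S_nipecotic", "ind_guvacine")

#: charge at or above which an atom's surface counts as "polar positive".
FPPOS_CHARGE_CUTOFF = 0.20

COUNT_SET_NAMES = (
    "a_count",
    "b_count",
    "b_single",
    "b_rotN",
    "b_rotR",
    "b_1rotN",
    "b_1rotR",
    "opr_brigid",
    "wienerPol",
    "PEOE_VSA_FPPOS",
    "vdw_area",
)

# 16 standard physicochemical descriptors (the composition of this block is
# configurable; it is a conventional default, not a canonical list).
PHYSCHEM16: tuple[tuple[str, object], ...] = (
    ("weight", Descriptors.MolWt),
    ("logP", Crippen.MolLogP),
    ("mr", Crippen.MolMR),
    ("TPSA", rdMolDescriptors.CalcTPSA),
    ("a_heavy", lambda m: m.GetNumHeavyAtoms()),
    ("a_aro", rdMolDescriptors.CalcNumAromaticRings),
    ("rings", rdMolDescriptors.CalcNumRings),
    ("lip_don", rdMolDescriptors.CalcNumHBD),
    ("lip_acc", rdMolDescriptors.CalcNumHBA),
    ("b_rotatable", rdMolDescriptors.CalcNumRotatableBonds),
    ("FCsp3", rdMolDescriptors.CalcFractionCSP3),
    ("density", lambda m: Descriptors.MolWt(m) / max(m.GetNumHeavyAtoms(), 1)),
    ("balabanJ", Descriptors.BalabanJ),
    ("bertzCT", Descriptors.BertzCT),
    ("kappa1", rdMolDescriptors.CalcKappa1),
    ("chi0v", rdMolDescriptors.CalcChi0v),
)


class ScaffoldAmbiguityError(ValueError):
    """Nipecotic-acid core present but the C3 stereocentre is unspecified."""


@dataclass
class DescriptorMatrix:
    """Compounds x named descriptors with a descriptor-set provenance tag."""

    frame: pd.DataFrame
    set_tag: SetTag

    def __post_init__(self) -> None:
        if self.frame.columns.duplicated().any():
            raise ValueError("duplicate descriptor names")
        if self.frame.isna().any().any():
            raise ValueError("descriptor matrix has missing cells")

    @property
    def ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def names(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index_label="id")

    @classmethod
    def from_csv(cls, path: str | Path, set_tag: SetTag = "custom") -> "DescriptorMatrix":
        frame = pd.read_csv(path, index_col="id")
        frame.index = frame.index.astype(str)
        return cls(frame=frame, set_tag=set_tag)


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def count_atoms_bonds(mol: Chem.Mol) -> tuple[int, int, int]:
    """``(a_count, b_count, b_single)`` with implicit hydrogens included.

    Each implicit/explicit hydrogen counts as one atom and one single bond.
    Aromatic bonds count in ``b_count`` but not in ``b_single``.
    """
    n_h = sum(a.GetTotalNumHs() for a in mol.GetAtoms())
    heavy = mol.GetNumHeavyAtoms()
    a_count = heavy + n_h
    heavy_bonds = mol.GetNumBonds()
    b_count = heavy_bonds + n_h
    b_single = n_h + sum(
        1 for b in mol.GetBonds() if b.GetBondType() == Chem.BondType.SINGLE
    )
    return a_count, b_count, b_single


def _is_amide_cn(bond: Chem.Bond) -> bool:
    for a, b in ((bond.GetBeginAtom(), bond.GetEndAtom()),
                 (bond.GetEndAtom(), bond.GetBeginAtom())):
        if a.GetSymbol() == "C" and b.GetSymbol() == "N":
            for nb in a.GetBonds():
                other = nb.GetOtherAtom(a)
                if other.GetSymbol() == "O" and nb.GetBondType() == Chem.BondType.DOUBLE:
                    return True
    return False


def _is_terminal(bond: Chem.Bond) -> bool:
    return (
        sum(1 for n in bond.GetBeginAtom().GetNeighbors() if n.GetAtomicNum() > 1) < 2
        or sum(1 for n in bond.GetEndAtom().GetNeighbors() if n.GetAtomicNum() > 1) < 2
    )


def rotatable_bond_counts(mol: Chem.Mol) -> tuple[int, float, int, float, int]:
    """``(b_rotN, b_rotR, b_1rotN, b_1rotR, opr_brigid)``.

    A rotatable bond is an acyclic order-1 bond between two heavy atoms,
    each with at least two heavy neighbours; ``b_1rotN`` additionally
    excludes amide C-N bonds.  Fractions divide by the number of
    heavy-heavy bonds (0 when there are none).  Rigid bonds
    (``opr_brigid``) are non-terminal heavy-heavy bonds in a ring, of
    order > 1, or amide C-N bonds.
    """
    heavy_bonds = mol.GetNumBonds()
    b_rotn = b_1rotn = rigid = 0
    for bond in mol.GetBonds():
        in_ring = bond.IsInRing()
        order1 = bond.GetBondTypeAsDouble() == 1.0
        terminal = _is_terminal(bond)
        amide = _is_amide_cn(bond)
        if not in_ring and order1 and not terminal:
            b_rotn += 1
            if not amide:
                b_1rotn += 1
        if not terminal and (in_ring or not order1 or amide):
            rigid += 1
    b_rotr = b_rotn / heavy_bonds if heavy_bonds else 0.0
    b_1rotr = b_1rotn / heavy_bonds if heavy_bonds else 0.0
    return b_rotn, b_rotr, b_1rotn, b_1rotr, rigid


def wiener_polarity(mol: Chem.Mol) -> int:
    """Number of heavy-atom pairs at topological distance exactly 3."""
    if mol.GetNumHeavyAtoms() < 2:
        return 0
    dm = rdmolops.GetDistanceMatrix(mol)
    return int(np.count_nonzero(dm == 3) // 2)


# ---------------------------------------------------------------------------
# PEOE charges and approximate surface areas (explicit-H molecule)
# ---------------------------------------------------------------------------

def _with_explicit_hs(mol: Chem.Mol) -> Chem.Mol:
    return Chem.AddHs(mol)


def peoe_charges(mol: Chem.Mol, n_iter: int = 6) -> np.ndarray:
    """PEOE (Gasteiger) partial charges of the hydrogen-explicit molecule.

    Iterative partial equalisation of orbital electronegativities with
    damping 0.5 per iteration; charges sum to the molecule's formal charge.
    """
    molh = _with_explicit_hs(mol)
    AllChem.ComputeGasteigerCharges(molh, nIter=n_iter, throwOnParamFailure=False)
    charges = np.array(
        [a.GetDoubleProp("_GasteigerCharge") for a in molh.GetAtoms()], dtype=float
    )
    if not np.all(np.isfinite(charges)):
        bad = sorted(
            {molh.GetAtomWithIdx(i).GetSymbol() for i in np.flatnonzero(~np.isfinite(charges))}
        )
        raise ValueError(f"PEOE parameters unavailable for element(s): {', '.join(bad)}")
    return charges


def approximate_vsa(mol: Chem.Mol) -> tuple[np.ndarray, float]:
    """Per-atom approximate van der Waals surface contributions (A^2).

    Each atom of the hydrogen-explicit molecule contributes the area of
    its van der Waals sphere minus the spherical caps occluded by bonded
    neighbours at the ideal bond length (sum of covalent radii, clamped to
    the geometrically admissible range).  Returns the per-atom array and
    their sum ``vdw_area``.
    """
    molh = _with_explicit_hs(mol)
    pt = Chem.GetPeriodicTable()
    radii = np.empty(molh.GetNumAtoms())
    rcov = np.empty(molh.GetNumAtoms())
    for atom in molh.GetAtoms():
        z = atom.GetAtomicNum()
        r = pt.GetRvdw(z)
        if r <= 0:
            raise ValueError(f"no van der Waals radius for element {atom.GetSymbol()}")
        radii[atom.GetIdx()] = r
        rcov[atom.GetIdx()] = pt.GetRcovalent(z)
    areas = 4.0 * math.pi * radii**2
    for bond in molh.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        ri, rj = radii[i], radii[j]
        d = rcov[i] + rcov[j]
        d = min(max(d, abs(ri - rj) + 1e-6), ri + rj)
        # spherical cap of sphere i buried inside sphere j, and vice versa
        hi = ri - (d * d + ri * ri - rj * rj) / (2.0 * d)
        hj = rj - (d * d + rj * rj - ri * ri) / (2.0 * d)
        areas[i] -= 2.0 * math.pi * ri * max(hi, 0.0)
        areas[j] -= 2.0 * math.pi * rj * max(hj, 0.0)
    areas = np.maximum(areas, 0.0)
    return areas, float(areas.sum())


def _bin_sums(areas: np.ndarray, values: np.ndarray, edges: Sequence[float]) -> np.ndarray:
    idx = np.searchsorted(np.asarray(edges), values, side="left")
    out = np.zeros(len(edges) + 1)
    np.add.at(out, idx, areas)
    return out


def vsa_descriptor_block(
    mol: Chem.Mol, n_iter: int = 6
) -> tuple[dict[str, float], float, float]:
    """The 32 binned VSA descriptors plus ``vdw_area`` and ``PEOE_VSA_FPPOS``.

    Per-atom surface contributions are summed into bins of the Crippen
    atomic logP contribution (10 bins), the Crippen molar-refractivity
    contribution (8 bins) and the PEOE partial charge (14 bins).
    ``PEOE_VSA_FPPOS`` is the surface fraction on atoms with charge >=
    +0.20.
    """
    molh = _with_explicit_hs(mol)
    areas, vdw_area = approximate_vsa(mol)
    charges = peoe_charges(mol, n_iter=n_iter)
    crippen = rdMolDescriptors._CalcCrippenContribs(molh)
    logp = np.array([c[0] for c in crippen])
    mr = np.array([c[1] for c in crippen])

    block: dict[str, float] = {}
    for names, vals, edges in (
        (SLOGP_NAMES, logp, SLOGP_BIN_EDGES),
        (SMR_NAMES, mr, SMR_BIN_EDGES),
        (PEOE_NAMES, charges, PEOE_BIN_EDGES),
    ):
        sums = _bin_sums(areas, vals, edges)
        block.update(zip(names, sums.tolist()))
    fppos = float(areas[charges >= FPPOS_CHARGE_CUTOFF].sum() / vdw_area) if vdw_area else 0.0
    return block, vdw_area, fppos


# ---------------------------------------------------------------------------
# scaffold indicators
# ---------------------------------------------------------------------------

# carboxylic acid (or carboxylate) directly on the ring; esters do not match
_NIPECOTIC = Chem.MolFromSmarts("[OX2H1,OX1-]C(=O)[CX4;H1]1[CH2][CH2][CH2][NX3][CH2]1")
_GUVACINE = Chem.MolFromSmarts("[OX2H1,OX1-]C(=O)C1=C[CH2][CH2][NX3][CH2]1")


def scaffold_indicators(mol: Chem.Mol) -> tuple[int, int, int]:
    """``(ind_R_nipecotic, ind_S_nipecotic, ind_guvacine)`` as 0/1.

    Matches the N-(un)substituted piperidine-3-carboxylic acid core with
    CIP assignment at C3 deciding R vs S, and the guvacine core
    (1,2,5,6-tetrahydropyridine-3-carboxylic acid).  At most one indicator
    is set; a molecule matching neither scaffold returns all zeros with a
    warning.  A nipecotic core whose C3 stereocentre is unspecified raises
    :class:`ScaffoldAmbiguityError` rather than silently scoring 0.
    """
    if mol.HasSubstructMatch(_GUVACINE):
        return 0, 0, 1
    matches = mol.GetSubstructMatches(_NIPECOTIC)
    if matches:
        mol = Chem.Mol(mol)
        rdCIPLabeler.AssignCIPLabels(mol)
        c3 = mol.GetAtomWithIdx(matches[0][3])
        if not c3.HasProp("_CIPCode"):
            raise ScaffoldAmbiguityError(
                "nipecotic-acid core with unspecified C3 stereocentre"
            )
        code = c3.GetProp("_CIPCode")
        return (1, 0, 0) if code == "R" else (0, 1, 0)
    warnings.warn("molecule matches no amino-acid scaffold", stacklevel=2)
    return 0, 0, 0


# ---------------------------------------------------------------------------
# full matrices
# ---------------------------------------------------------------------------

def descriptor_vector(mol: Chem.Mol, n_iter: int = 6) -> dict[str, float]:
    """All named 2D descriptors of one molecule (counts + VSA + indicators)."""
    a_count, b_count, b_single = count_atoms_bonds(mol)
    b_rotn, b_rotr, b_1rotn, b_1rotr, rigid = rotatable_bond_counts(mol)
    block, vdw_area, fppos = vsa_descriptor_block(mol, n_iter=n_iter)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ind_r, ind_s, ind_g = scaffold_indicators(mol)
    vec = {
        "a_count": float(a_count),
        "b_count": float(b_count),
        "b_single": float(b_single),
        "b_rotN": float(b_rotn),
        "b_rotR": b_rotr,
        "b_1rotN": float(b_1rotn),
        "b_1rotR": b_1rotr,
        "opr_brigid": float(rigid),
        "wienerPol": float(wiener_polarity(mol)),
        "PEOE_VSA_FPPOS": fppos,
        "vdw_area": vdw_area,
    }
    vec.update(block)
    vec.update(zip(INDICATOR_NAMES, (float(ind_r), float(ind_s), float(ind_g))))
    return vec


def _columns_for(set_tag: SetTag) -> list[str]:
    if set_tag == "vsa_ind":
        return list(VSA_BLOCK_NAMES + INDICATOR_NAMES)
    if set_tag == "contingency_selected":
        return list(COUNT_SET_NAMES)
    raise ValueError(f"no fixed column set for tag {set_tag!r}")


def compute_descriptor_matrix(
    records: Sequence[CompoundRecord],
    set_tag: SetTag = "vsa_ind",
    physchem: Sequence[tuple[str, object]] = PHYSCHEM16,
) -> DescriptorMatrix:
    """Descriptor matrix for a compound list.

    ``vsa_ind`` yields the 32 VSA bins plus the three scaffold indicators
    (35 columns); ``physchem16`` the 16-descriptor physicochemical block;
    ``contingency_selected`` the count/polarity descriptor pool offered to
    contingency analysis.  Any per-molecule failure aborts with the
    compound id.
    """
    if not records:
        raise ValueError("empty record list")
    rows = []
    for rec in records:
        try:
            if set_tag == "physchem16":
                row = {name: float(fn(rec.mol)) for name, fn in physchem}
            else:
                full = descriptor_vector(rec.mol)
                row = {name: full[name] for name in _columns_for(set_tag)}
        except Exception as exc:
            raise RuntimeError(f"descriptor computation failed for {rec.id!r}: {exc}") from exc
        rows.append(row)
    frame = pd.DataFrame(rows, index=[r.id for r in records])
    return DescriptorMatrix(frame=frame, set_tag=set_tag)
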