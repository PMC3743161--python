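"""Synthetic data: descriptor tables with controlled class structure, and
a structure-level tiagabine-analog library with a known SAR rule.

The library generator assembles lipophilic GABA-uptake-inhibitor analogs
from the three amino-acid head groups (R-/S-nipecotic acid, guvacine), an
N-linked aliphatic linker of 2-7 heavy atoms and a diaryl tail (plain
methine, vinyl ether or oxime ether; optional ortho-methyl on one ring).
Synthetic pIC50 values follow an additive rule rewarding a 4-5 atom
linker, ortho substitution, R configuration and a polar (oxime/vinyl
ether) linker head, plus Gaussian noise — mirroring the qualitative SAR
of this compound class, not any measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem_io import ActivityConfig, CompoundRecord, assign_activity_labels
from .descriptors import DescriptorMatrix

# scaffold suffixes attached to the linker's last atom (at the ring N)
SCAFFOLD_SMILES = {
    "R": "N1CCC[C@@H](C(O)=O)C1",
    "S": "N1CCC[C@H](C(O)=O)C1",
    "guvacine": "N1CC(C(O)=O)=CCC1",
}

# head templates; {a1}/{a2} are aryl fragments written as branches
HEAD_TEMPLATES = {
    "plain": "C({a1})({a2})",        # diaryl methine, all-carbon linker
    "vinyl_ether": "C({a1})({a2})=CO",  # Ar2C=CH-O- (polar linker head)
    "oxime": "C({a1})({a2})=NO",        # Ar2C=N-O-  (polar linker head)
}

ARYL_PLAIN = "c1ccccc1"
ARYL_ORTHO_METHYL = "c1ccccc1C"  # methyl on the ring-closure atom = ortho


@dataclass(frozen=True)
class DescriptorSimConfig:
    """Gaussian descriptor-table simulation (class balance 57:105 default)."""

    n_active: int = 57
    n_inactive: int = 105
    n_informative: int = 3
    n_noise: int = 29
    effect_size: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_active, self.n_inactive, self.n_informative, self.n_noise) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_informative + self.n_noise < 1:
            raise ValueError("need at least one descriptor column")
        if self.n_active + self.n_inactive < 1:
            raise ValueError("zero compounds requested")


@dataclass(frozen=True)
class LibrarySimConfig:
    """Structure-level library simulation with a frozen additive SAR rule."""

    scaffold_weights: tuple[float, float, float] = (0.45, 0.15, 0.40)  # R, S, guvacine
    linker_lengths: tuple[int, ...] = (2, 3, 4, 5, 6, 7)  # heavy atoms N..head C
    p_ortho: float = 0.4
    p_polar_head: float = 0.5  # oxime or vinyl ether instead of plain methine
    base_pic50: float = 6.0
    beta_linker: float = 0.8   # linker length in {4, 5}
    beta_ortho: float = 0.4
    beta_r: float = 0.5
    beta_polar: float = 0.4
    noise_sd: float = 0.3
    n_compounds: int = 162
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.scaffold_weights) - 1.0) > 1e-9:
            raise ValueError("scaffold weights must sum to 1")
        if not self.scaffold_weights or min(self.scaffold_weights) < 0:
            raise ValueError("invalid scaffold weights")
        if min(self.linker_lengths) < 1 or max(self.linker_lengths) > 10:
            raise ValueError("linker lengths must lie in [1, 10]")


def generate_descriptor_table(
    cfg: DescriptorSimConfig,
) -> tuple[DescriptorMatrix, np.ndarray]:
    """Descriptor matrix with informative and noise columns plus 0/1 labels.

    Informative columns are N(effect_size, 1) for actives and N(0, 1) for
    inactives; noise columns are N(0, 1) for both.  Column names carry an
    ``inf_``/``noise_`` prefix so tests can introspect which is which.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_active + cfg.n_inactive
    y = np.array([1] * cfg.n_active + [0] * cfg.n_inactive)
    cols = {}
    for j in range(cfg.n_informative):
        shift = np.where(y == 1, cfg.effect_size, 0.0)
        cols[f"inf_{j}"] = rng.normal(0.0, 1.0, n) + shift
    for j in range(cfg.n_noise):
        cols[f"noise_{j}"] = rng.normal(0.0, 1.0, n)
    frame = pd.DataFrame(cols, index=[f"cpd_{i}" for i in range(n)])
    return DescriptorMatrix(frame=frame, set_tag="custom"), y


@dataclass
class _CompoundPlan:
    scaffold: str
    linker: int
    ortho: bool
    head: str

    @property
    def polar(self) -> bool:
        return self.head in ("vinyl_ether", "oxime")


def _assemble_smiles(plan: _CompoundPlan) -> str:
    a1 = ARYL_ORTHO_METHYL if plan.ortho else ARYL_PLAIN
    a2 = ARYL_PLAIN
    head = HEAD_TEMPLATES[plan.head].format(a1=a1, a2=a2)
    # polar heads already contribute two linker heavy atoms (=C-O / =N-O)
    n_chain = plan.linker - (2 if plan.polar else 0)
    return head + "C" * n_chain + SCAFFOLD_SMILES[plan.scaffold]


def _rule_pic50(plan: _CompoundPlan, cfg: LibrarySimConfig) -> float:
    return (
        cfg.base_pic50
        + cfg.beta_linker * (plan.linker in (4, 5))
        + cfg.beta_ortho * plan.ortho
        + cfg.beta_r * (plan.scaffold == "R")
        + cfg.beta_polar * plan.polar
    )


def generate_compound_library(
    cfg: LibrarySimConfig | None = None,
) -> list[CompoundRecord]:
    """Random tiagabine-analog library with rule-based synthetic pIC50s.

    Every record carries a valid SMILES with explicit C3 stereo for the
    nipecotic scaffolds; at zero noise the pIC50 of a compound is exactly
    the additive rule value.
    """
    cfg = cfg or LibrarySimConfig()
    rng = np.random.default_rng(cfg.seed)
    scaffolds = ("R", "S", "guvacine")
    heads = ("plain", "vinyl_ether", "oxime")
    records: list[CompoundRecord] = []
    for i in range(cfg.n_compounds):
        linker = int(rng.choice(cfg.linker_lengths))
        polar_ok = linker >= 3  # =X-O head needs at least one chain carbon
        polar = polar_ok and rng.random() < cfg.p_polar_head
        plan = _CompoundPlan(
            scaffold=scaffolds[int(rng.choice(3, p=cfg.scaffold_weights))],
            linker=linker,
            ortho=bool(rng.random() < cfg.p_ortho),
            head=heads[1 + int(rng.random() < 0.5)] if polar else "plain",
        )
        smiles = _assemble_smiles(plan)
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:  # pragma: no cover - generator invariant
            raise RuntimeError(f"generator produced invalid SMILES: {smiles}")
        pic50 = _rule_pic50(plan, cfg) + (rng.normal(0.0, cfg.noise_sd) if cfg.noise_sd else 0.0)
        records.append(
            CompoundRecord(id=f"syn_{i:03d}", mol=mol, pic50=float(pic50))
        )
    return records


def benchmark_dataset(
    seed: int = 1,
    n_active: int = 57,
    n_total: int = 162,
    threshold: float = 7.0,
    max_attempts: int = 5000,
) -> tuple[list[CompoundRecord], np.ndarray]:
    """A 162-compound library with exactly 57 actives at threshold 7.0.

    Regenerates the library with derived seeds (rejection resampling, so
    pIC50 values stay consistent with the structures) until the class
    balance matches; the scaffold mix is dominated by R-nipecotic acid and
    guvacine, with S-configured compounds underrepresented.
    """
    base = np.random.default_rng(seed).integers(0, 2**31 - 1)
    for attempt in range(max_attempts):
        sub_seed = int((base + attempt) % (2**31 - 1))
        cfg = LibrarySimConfig(n_compounds=n_total, seed=sub_seed)
        records = generate_compound_library(cfg)
        labelled, counts = assign_activity_labels(records, ActivityConfig(threshold))
        if counts["active"] == n_active:
            y = np.array([1 if r.label == "active" else 0 for r in labelled])
            return labelled, y
    raise RuntimeError(
        f"could not hit {n_active}/{n_total} actives in {max_attempts} resamples"
    )


def write_library_sdf(records: list[CompoundRecord], path) -> None:
    """Write a generated library as an SDF with a pIC50 property tag."""
    writer = Chem.SDWriter(str(path))
    try:
        for rec in records:
            mol = Chem.Mol(rec.mol)
            mol.SetProp("_Name", rec.id)
            if rec.pic50 is not None:
                mol.SetProp("pIC50", f"{rec.pic50:.4f}")
            writer.write(mol)
    finally:
        writer.close()


def write_library_csv(records: list[CompoundRecord], path) -> None:
    """Write a generated library as a SMILES CSV (id,smiles,pic50)."""
    frame = pd.DataFrame(
        {
            "id": [r.id for r in records],
            "smiles": [r.smiles for r in records],
            "pic50": [r.pic50 for r in records],
        }
    )
    frame.to_csv(path, index=False)
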