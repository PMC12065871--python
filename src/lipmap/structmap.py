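"""Mapping residue scores onto 3D structures.

A :class:`StructureModel` holds all-atom (non-hydrogen) coordinates of one
chain plus a binding-pocket residue set.  Minimal inter-residue distances are
all-atom pairwise minima; the score-to-binding-site relationship is
summarised by comparing the mean minimal pocket distance of super-threshold
residues against that of all residues.  Fingerprint scores can be exported
into the B-factor column of a PDB file for visualization in any molecular
viewer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .fingerprint import ResidueFingerprint
from .stats import DEFAULT_TAU

__all__ = [
    "StructureModel",
    "DistanceReport",
    "read_structure",
    "min_residue_distance",
    "distance_to_pocket",
    "export_scores_to_structure",
]

_WATER = {"HOH", "WAT", "DOD"}


@dataclass
class StructureModel:
    """One chain of a structure: per-residue atom coordinates and a pocket.

    ``atoms`` maps the author residue number to an (n_atoms, 3) coordinate
    array in Angstrom (non-hydrogen atoms only); ``atom_names`` and
    ``elements`` are parallel name lists used when writing PDB output;
    ``pocket`` is the set of residue numbers annotated as ligand-contacting.
    """

    chain_id: str
    atoms: dict[int, np.ndarray]
    residue_names: dict[int, str]
    atom_names: dict[int, list[str]] = field(default_factory=dict)
    elements: dict[int, list[str]] = field(default_factory=dict)
    pocket: set[int] = field(default_factory=set)

    def __post_init__(self):
        for idx, coords in self.atoms.items():
            if len(coords) == 0:
                raise ValueError(f"residue {idx} has no atoms")
        missing = self.pocket - set(self.atoms)
        if missing:
            raise ValueError(
                f"pocket residue(s) absent from model: {sorted(missing)}"
            )

    @property
    def residue_numbers(self) -> list[int]:
        return sorted(self.atoms)

    def with_pocket(self, pocket: set[int]) -> "StructureModel":
        return StructureModel(
            chain_id=self.chain_id,
            atoms=self.atoms,
            residue_names=self.residue_names,
            atom_names=self.atom_names,
            elements=self.elements,
            pocket=set(pocket),
        )


@dataclass(frozen=True)
class DistanceReport:
    """Minimal pocket distances per residue plus the two group means."""

    d_min: dict[int, float]
    mean_all: float
    mean_super_threshold: float  # NaN when no residue exceeds tau
    n_all: int
    n_super_threshold: int
    n_unmapped: int  # fingerprint residues absent from the structure


def read_structure(path, chain: str, pocket: set[int] | None = None) -> StructureModel:
    """Read one chain from a PDB or mmCIF file.

    Hydrogens, waters and hetero-compounds (ligands) are excluded; alternate
    conformations are resolved to the highest-occupancy location per atom
    name.
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    model = st[0]
    target = None
    for ch in model:
        if ch.name == chain:
            target = ch
            break
    if target is None:
        raise ValueError(
            f"chain {chain!r} not found in {path} "
            f"(available: {[c.name for c in model]})"
        )

    atoms: dict[int, np.ndarray] = {}
    residue_names: dict[int, str] = {}
    atom_names: dict[int, list[str]] = {}
    elements: dict[int, list[str]] = {}
    for res in target:
        if res.name in _WATER or res.het_flag == "H":
            continue
        # resolve altlocs: keep highest occupancy per atom name
        best: dict[str, gemmi.Atom] = {}
        for atom in res:
            if atom.element == gemmi.Element("H"):
                continue
            prev = best.get(atom.name)
            if prev is None or atom.occ > prev.occ:
                best[atom.name] = atom
        if not best:
            continue
        idx = res.seqid.num
        atoms[idx] = np.array(
            [[a.pos.x, a.pos.y, a.pos.z] for a in best.values()]
        )
        residue_names[idx] = res.name
        atom_names[idx] = list(best.keys())
        elements[idx] = [a.element.name for a in best.values()]

    return StructureModel(
        chain_id=chain,
        atoms=atoms,
        residue_names=residue_names,
        atom_names=atom_names,
        elements=elements,
        pocket=set(pocket or ()),
    )


def min_residue_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Minimal Euclidean distance (Angstrom) over all atom pairs."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("atom sets must be non-empty")
    diff = a[:, None, :] - b[None, :, :]
    return float(np.sqrt((diff**2).sum(axis=2)).min())


def distance_to_pocket(
    model: StructureModel,
    fingerprint: ResidueFingerprint,
    tau: float = DEFAULT_TAU,
    mapping: dict[int, int] | None = None,
) -> DistanceReport:
    """Minimal distance of every residue to the binding pocket, by group.

    ``mapping`` translates fingerprint (sequence) positions to structure
    author numbering; by default they are assumed identical.  Pocket residues
    have distance 0.  Residues present in the fingerprint but absent from the
    model are excluded and counted.  The super-threshold group contains the
    residues whose score exceeds ``tau``; its mean is NaN when empty.
    """
    if not model.pocket:
        raise ValueError("model has no pocket residues defined")
    mapping = mapping or {}
    pocket_atoms = [model.atoms[i] for i in sorted(model.pocket)]

    d_min: dict[int, float] = {}
    super_d: list[float] = []
    n_unmapped = 0
    for pos in range(1, fingerprint.length + 1):
        struct_idx = mapping.get(pos, pos)
        if struct_idx not in model.atoms:
            n_unmapped += 1
            continue
        if struct_idx in model.pocket:
            d = 0.0
        else:
            d = min(
                min_residue_distance(model.atoms[struct_idx], pa)
                for pa in pocket_atoms
            )
        d_min[pos] = d
        score = fingerprint.scores[pos - 1]
        if fingerprint.detected[pos - 1] and score > tau:
            super_d.append(d)

    if not d_min:
        raise ValueError("no fingerprint residue could be mapped to the model")
    mean_all = float(np.mean(list(d_min.values())))
    mean_super = float(np.mean(super_d)) if super_d else math.nan
    return DistanceReport(
        d_min=d_min,
        mean_all=mean_all,
        mean_super_threshold=mean_super,
        n_all=len(d_min),
        n_super_threshold=len(super_d),
        n_unmapped=n_unmapped,
    )


def export_scores_to_structure(
    model: StructureModel,
    fingerprint: ResidueFingerprint,
    path,
    mapping: dict[int, int] | None = None,
) -> None:
    """Write a PDB with residue scores in the temperature-factor column.

    Every atom of a residue carries that residue's score as its B-factor;
    undetected residues (and structure residues outside the fingerprint) get
    the sentinel -1.0, so external viewers can color detected/undetected
    states apart.
    """
    mapping = mapping or {}
    # invert: structure author number -> fingerprint position
    inverse = {mapping.get(p, p): p for p in range(1, fingerprint.length + 1)}

    st = gemmi.Structure()
    st.name = fingerprint.protein_id or "fingerprint"
    gm = gemmi.Model("1")
    ch = gemmi.Chain(model.chain_id or "A")
    for idx in model.residue_numbers:
        res = gemmi.Residue()
        res.name = model.residue_names.get(idx, "ALA")
        res.seqid = gemmi.SeqId(idx, " ")
        pos = inverse.get(idx)
        if pos is not None and fingerprint.detected[pos - 1]:
            b = float(fingerprint.scores[pos - 1])
        else:
            b = -1.0
        names = model.atom_names.get(idx) or [
            "CA" if i == 0 else f"X{i}" for i in range(len(model.atoms[idx]))
        ]
        elems = model.elements.get(idx) or ["C"] * len(model.atoms[idx])
        for name, elem, xyz in zip(names, elems, model.atoms[idx]):
            atom = gemmi.Atom()
            atom.name = name
            atom.element = gemmi.Element(elem)
            atom.pos = gemmi.Position(*map(float, xyz))
            atom.occ = 1.0
            atom.b_iso = b
            res.add_atom(atom)
        ch.add_residue(res)
    gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))
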