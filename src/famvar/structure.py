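"""Structural interface-proximity (DIST) scoring.

A missense variant close to another protein chain in a deposited complex is
more likely to perturb a protein-protein interaction. For each structure
containing the variant residue, the minimum Euclidean distance between any
atom of that residue and any atom of every other chain is computed; the DIST
score is the lowest rung of the ladder (2, 3, 4, 6, 8, 12, 16 angstrom) at
which that minimum yields at least one contact pair (distance <= rung), i.e.
the smallest ladder value >= the minimum distance. Distances beyond 16 A
score as absent. Across multiple structures the minimum rung is kept (the
most contact-proximal evidence). A rung strictly below 4 A (2 or 3) marks the
variant as interface-proximal for family-level ranking.

Structures are read with gemmi. Hydrogens and waters are excluded, alternate
locations resolve to the highest occupancy, and by default only amino-acid
residues count as chain content (non-polymer het chains are excluded,
configurable).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import gemmi
import numpy as np

from .cohort import Variant
from .errors import ConfigError, DataError

DEFAULT_LADDER: tuple[float, ...] = (2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 16.0)
INTERFACE_MAX_RUNG = 4.0  # interface flag requires rung strictly below this


@dataclass
class AtomRecord:
    name: str
    element: str
    x: float
    y: float
    z: float


@dataclass
class ResidueRecord:
    number: int  # author numbering
    name: str    # 3-letter code
    atoms: list[AtomRecord] = field(default_factory=list)

    def coords(self) -> np.ndarray:
        return np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float)


@dataclass
class StructureModel:
    structure_id: str
    chains: dict[str, list[ResidueRecord]] = field(default_factory=dict)

    def chain_coords(self, chain_id: str) -> np.ndarray:
        residues = self.chains.get(chain_id, [])
        pts = [[a.x, a.y, a.z] for r in residues for a in r.atoms]
        return np.array(pts, dtype=float).reshape(-1, 3)

    def find_residue(self, chain_id: str, number: int) -> ResidueRecord | None:
        for r in self.chains.get(chain_id, []):
            if r.number == number:
                return r
        return None


@dataclass(frozen=True)
class ResidueMapping:
    variant_id: str
    structure_id: str
    chain_id: str
    residue_number: int
    match_mode: Literal["explicit", "naive"] = "explicit"


@dataclass
class DistScore:
    variant_id: str
    threshold: float | None          # ladder rung, None = absent
    structure_id: str | None = None  # supporting structure
    n_contact_pairs: int = 0         # atom pairs within the rung
    log: list[str] = field(default_factory=list)

    @property
    def interface_flag(self) -> bool:
        return self.threshold is not None and self.threshold < INTERFACE_MAX_RUNG


def _is_amino_acid(resname: str) -> bool:
    info = gemmi.find_tabulated_residue(resname)
    return info is not None and info.is_amino_acid()


def read_structure(
    path: str | Path,
    fmt: Literal["pdb", "mmcif", "auto"] = "auto",
    include_nonpolymer: bool = False,
) -> StructureModel:
    """Parse a PDB/mmCIF file into a light coordinate model.

    Heavy atoms only; waters excluded; alternate locations resolved to the
    highest occupancy. Non-amino-acid residues (ligands, ions) are excluded
    unless ``include_nonpolymer`` is set.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"structure file not found: {path}")
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path)).sole_block())
        else:
            st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise DataError(f"unparsable structure file {path}: {exc}") from exc
    if len(st) == 0:
        raise DataError(f"structure {path} contains no models")

    model = StructureModel(structure_id=st.name or path.stem)
    for chain in st[0]:
        residues: list[ResidueRecord] = []
        for res in chain:
            if res.is_water():
                continue
            if not include_nonpolymer and not _is_amino_acid(res.name):
                continue
            # altloc groups by atom name -> keep highest occupancy
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                if atom.is_hydrogen():
                    continue
                prev = best.get(atom.name)
                if prev is None or (atom.occ or 0.0) > (prev.occ or 0.0):
                    best[atom.name] = atom
            atoms = [AtomRecord(a.name, a.element.name, a.pos.x, a.pos.y, a.pos.z)
                     for a in best.values()]
            if atoms:
                residues.append(ResidueRecord(number=res.seqid.num, name=res.name,
                                              atoms=atoms))
        if residues:
            model.chains[chain.name] = residues
    if not model.chains:
        raise DataError(f"structure {path} has no usable chains")
    return model


def write_structure_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a coordinate model to PDB format (via gemmi)."""
    st = gemmi.Structure()
    st.name = model.structure_id
    gm = gemmi.Model("1")
    for chain_id, residues in model.chains.items():
        ch = gemmi.Chain(chain_id)
        for res in residues:
            gr = gemmi.Residue()
            gr.name = res.name
            gr.seqid = gemmi.SeqId(res.number, " ")
            for a in res.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(a.x, a.y, a.z)
                ga.occ = 1.0
                gr.add_atom(ga)
            ch.add_residue(gr)
        gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


def min_interchain_distance(
    model: StructureModel, chain_id: str, residue_number: int
) -> tuple[float | None, int, float | None]:
    """Minimum distance between the residue's atoms and all atoms of every
    other chain. Returns (min_distance, n_other_atoms, None) or
    (None, n_other_atoms, None) when undefined."""
    res = model.find_residue(chain_id, residue_number)
    if res is None:
        return None, 0, None
    other = [model.chain_coords(c) for c in model.chains if c != chain_id]
    other = [o for o in other if o.size]
    if not other:
        return None, 0, None
    pts = res.coords()
    others = np.vstack(other)
    d = np.linalg.norm(pts[:, None, :] - others[None, :, :], axis=-1)
    return float(d.min()), others.shape[0], None


def _rung_for(d: float, ladder: Sequence[float]) -> float | None:
    for t in sorted(ladder):
        if d <= t:
            return t
    return None


ONE_LETTER = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


def dist_score(
    variant: Variant,
    mappings: Iterable[ResidueMapping],
    structures: dict[str, StructureModel],
    ladder: Sequence[float] = DEFAULT_LADDER,
) -> DistScore:
    """DIST score for one variant: minimum ladder rung across all structures
    containing it.

    Per structure, the rung is the smallest ladder value >= the minimum
    variant-residue-to-other-chain atom distance (<= comparison: a distance
    exactly on a rung qualifies); distances beyond the ladder give no rung.
    Unresolvable mappings and single-chain structures are logged, not fatal;
    if nothing resolves the score is absent.
    """
    out = DistScore(variant_id=variant.variant_id, threshold=None)
    best: tuple[float, str, int] | None = None
    for m in mappings:
        if m.variant_id != variant.variant_id:
            continue
        model = structures.get(m.structure_id)
        if model is None:
            out.log.append(f"structure {m.structure_id} not loaded")
            continue
        res = model.find_residue(m.chain_id, m.residue_number)
        if res is None:
            out.log.append(f"{m.structure_id}/{m.chain_id}:{m.residue_number} not found")
            continue
        if m.match_mode == "naive" and ONE_LETTER.get(res.name) != variant.wt_aa:
            out.log.append(
                f"{m.structure_id}/{m.chain_id}:{m.residue_number} residue "
                f"{res.name} does not match wt {variant.wt_aa}; skipped")
            continue
        dmin, n_other, _ = min_interchain_distance(model, m.chain_id, m.residue_number)
        if dmin is None:
            out.log.append(f"{m.structure_id}: no adjacent chain atoms")
            continue
        rung = _rung_for(dmin, ladder)
        if rung is None:
            out.log.append(f"{m.structure_id}: min distance {dmin:.2f} beyond ladder")
            continue
        # count atom pairs within the winning rung for this structure
        pts = res.coords()
        others = np.vstack([model.chain_coords(c) for c in model.chains
                            if c != m.chain_id])
        pairs = int((np.linalg.norm(pts[:, None, :] - others[None, :, :], axis=-1)
                     <= rung).sum())
        if best is None or rung < best[0]:
            best = (rung, m.structure_id, pairs)
    if best is not None:
        out.threshold, out.structure_id, out.n_contact_pairs = best
    return out


def read_mapping_table(path: str | Path) -> list[ResidueMapping]:
    """Mapping TSV: variant_id, structure_id, chain_id, residue_number
    (+ optional match_mode)."""
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"variant_id", "structure_id", "chain_id", "residue_number"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ConfigError(f"mapping table must have columns {sorted(required)}")
        for row in reader:
            out.append(ResidueMapping(
                variant_id=row["variant_id"], structure_id=row["structure_id"],
                chain_id=row["chain_id"], residue_number=int(row["residue_number"]),
                match_mode=row.get("match_mode") or "explicit"))  # type: ignore[arg-type]
    return out


def write_dist_table(scores: Iterable[DistScore], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["variant_id", "threshold", "structure_id",
                         "n_contact_pairs", "interface_flag"])
        for s in scores:
            writer.writerow([
                s.variant_id,
                "" if s.threshold is None else f"{s.threshold:g}",
                s.structure_id or "", s.n_contact_pairs, int(s.interface_flag)])
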