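"""Reading structures and extracting ligand binding sites.

A binding site is defined, following the convention of the benchmark
studies this package targets, as all protein heavy atoms within 5.3 Å of
any heavy atom of the bound ligand in the crystal structure.  Parsing of
PDB-format text is delegated to Biopython's ``Bio.PDB``; this module flattens
the hierarchy to plain atom records, resolves alternate locations to the
highest-occupancy copy (ties: first in file), and keeps model 1 only.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.Atom import DisorderedAtom
from Bio.PDB.PDBExceptions import PDBConstructionWarning
from scipy.spatial.distance import cdist

from .exceptions import (
    AmbiguousLigandError,
    DegenerateSiteError,
    LigandNotFoundError,
    ParseError,
)

__all__ = [
    "AtomRecord",
    "LigandSelector",
    "BindingSite",
    "parse_structure",
    "extract_binding_site",
    "write_site_table",
    "read_site_table",
]

_HYDROGEN_ELEMENTS = {"H", "D"}
WATER_RESNAMES = {"HOH", "DOD", "WAT"}


@dataclass(frozen=True)
class AtomRecord:
    """One coordinate record from an ATOM/HETATM line (model 1, altloc-resolved)."""

    record_class: str  # "polymer-atom" | "hetero-atom"
    atom_name: str
    element: str
    residue_name: str
    chain_id: str
    residue_seq: int
    altloc: str
    occupancy: float
    coords: np.ndarray
    model_index: int = 1

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in _HYDROGEN_ELEMENTS

    @property
    def is_water(self) -> bool:
        return self.residue_name in WATER_RESNAMES


@dataclass(frozen=True)
class LigandSelector:
    """Identifies a ligand instance: residue name, optionally chain and residue number."""

    residue_name: str
    chain_id: Optional[str] = None
    residue_seq: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.residue_name:
            raise ValueError("residue_name must be non-empty")

    def matches(self, atom: AtomRecord) -> bool:
        if atom.residue_name != self.residue_name:
            return False
        if self.chain_id is not None and atom.chain_id != self.chain_id:
            return False
        if self.residue_seq is not None and atom.residue_seq != self.residue_seq:
            return False
        return True


@dataclass(frozen=True)
class BindingSite:
    """An extracted atom point cloud (n x 3, Å) labelled with its ligand group."""

    site_id: str
    coords: np.ndarray
    ligand_label: str

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must be an n x 3 array")
        if coords.shape[0] < 4:
            raise DegenerateSiteError(
                f"site {self.site_id}: {coords.shape[0]} atoms, need >= 4"
            )
        if not np.all(np.isfinite(coords)):
            raise ValueError("coords must be finite")
        object.__setattr__(self, "coords", coords)

    @property
    def n_atoms(self) -> int:
        return int(self.coords.shape[0])


def _resolve_altlocs(atoms: Iterable) -> list:
    """Pick the highest-occupancy altloc copy; ties go to the first in file."""
    out = []
    for atom in atoms:
        if isinstance(atom, DisorderedAtom):
            children = atom.disordered_get_list()  # file order
            best = max(children, key=lambda a: (a.get_occupancy() or 0.0))
            # max() keeps the first of equal keys, matching the tie rule
            out.append(best)
        else:
            out.append(atom)
    return out


def parse_structure(pdb_text: str, name: str = "<pdb>") -> list[AtomRecord]:
    """Parse PDB-format text to flat atom records (first model only).

    Alternate locations are resolved to the highest-occupancy record; ties
    keep the copy appearing first in the file.  Hydrogens are retained and
    flagged by element so extraction can exclude them.
    """
    if not pdb_text.strip():
        raise ParseError(f"{name}: empty structure file")
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        structure = parser.get_structure("s", io.StringIO(pdb_text))
    models = list(structure)
    if not models:
        raise ParseError(f"{name}: no coordinate records found")
    model = models[0]
    records: list[AtomRecord] = []
    for chain in model:
        for residue in chain:
            hetfield, resseq, _icode = residue.id
            if hetfield == "W" or residue.resname.strip() in WATER_RESNAMES:
                record_class = "hetero-atom"
            elif hetfield.strip():
                record_class = "hetero-atom"
            else:
                record_class = "polymer-atom"
            for atom in _resolve_altlocs(residue.child_list):
                occ = atom.get_occupancy()
                records.append(
                    AtomRecord(
                        record_class=record_class,
                        atom_name=atom.get_name(),
                        element=(atom.element or "").upper(),
                        residue_name=residue.resname.strip(),
                        chain_id=chain.id,
                        residue_seq=int(resseq),
                        altloc=atom.get_altloc().strip(),
                        occupancy=float(occ) if occ is not None else 1.0,
                        coords=np.asarray(atom.get_coord(), dtype=float),
                        model_index=1,
                    )
                )
    if not records:
        raise ParseError(f"{name}: no coordinate records found")
    return records


def _ligand_instances(
    atoms: Sequence[AtomRecord], ligand: LigandSelector
) -> dict[tuple[str, int], list[AtomRecord]]:
    instances: dict[tuple[str, int], list[AtomRecord]] = {}
    for a in atoms:
        if a.record_class == "hetero-atom" and not a.is_water and ligand.matches(a):
            instances.setdefault((a.chain_id, a.residue_seq), []).append(a)
    return instances


def extract_binding_site(
    atoms: Sequence[AtomRecord],
    ligand: LigandSelector,
    cutoff: float = 5.3,
    structure_id: str = "",
    ligand_label: Optional[str] = None,
) -> BindingSite:
    """Extract the binding site: polymer heavy atoms within ``cutoff`` of the ligand.

    Hydrogens, waters and hetero groups other than the selected ligand are
    excluded.  The distance rule is the minimum Euclidean distance to ANY
    ligand heavy atom.  If the selector matches several ligand copies, an
    explicit chain/residue disambiguation is required rather than guessing.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    instances = _ligand_instances(atoms, ligand)
    if not instances:
        raise LigandNotFoundError(
            f"ligand not found: {ligand.residue_name!r} matches no hetero atoms"
        )
    if len(instances) > 1:
        listing = ", ".join(f"chain {c} res {r}" for c, r in sorted(instances))
        raise AmbiguousLigandError(
            f"selector {ligand.residue_name!r} matches {len(instances)} ligand "
            f"instances ({listing}); disambiguate with chain_id/residue_seq"
        )
    (instance_atoms,) = instances.values()
    ligand_xyz = np.array([a.coords for a in instance_atoms if not a.is_hydrogen])
    if ligand_xyz.size == 0:
        raise LigandNotFoundError(
            f"ligand {ligand.residue_name!r} has no heavy atoms"
        )
    candidates = [
        a for a in atoms if a.record_class == "polymer-atom" and not a.is_hydrogen
    ]
    if candidates:
        cand_xyz = np.array([a.coords for a in candidates])
        dmin = cdist(cand_xyz, ligand_xyz).min(axis=1)
        retained = cand_xyz[dmin <= cutoff]
    else:
        retained = np.empty((0, 3))
    if retained.shape[0] < 4:
        raise DegenerateSiteError(
            f"binding site for {ligand.residue_name!r} has only "
            f"{retained.shape[0]} atoms within {cutoff} Å; need >= 4"
        )
    site_id = (
        f"{structure_id}-{ligand.residue_name}" if structure_id else ligand.residue_name
    )
    return BindingSite(
        site_id=site_id,
        coords=retained,
        ligand_label=ligand_label if ligand_label is not None else ligand.residue_name,
    )


def write_site_table(site: BindingSite, path) -> None:
    """Write a site as the package's plain coordinate-table interchange format.

    First line: site_id and ligand_label; then one whitespace-delimited
    x y z row per atom, at full double precision (exact round trip).
    """
    with open(path, "w") as fh:
        fh.write(f"{site.site_id}\t{site.ligand_label}\n")
        for row in site.coords:
            fh.write(f"{row[0]:.17g} {row[1]:.17g} {row[2]:.17g}\n")


def read_site_table(path) -> BindingSite:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ParseError(f"{path}: empty site table")
        parts = header.split("\t")
        if len(parts) != 2:
            raise ParseError(f"{path}: malformed site-table header {header!r}")
        site_id, label = parts
        coords = np.loadtxt(fh, ndmin=2)
    return BindingSite(site_id=site_id, coords=coords, ligand_label=label)
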