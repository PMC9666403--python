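"""Residue-level structure model for an alpha/beta-tubulin heterodimer.

Reads mmCIF/PDB coordinates into a validated, chain-aware residue list,
attaches three-class secondary-structure annotations (helix / sheet / loop),
and computes per-category residue compositions — the proportions that later
serve as the composition-proportional null for variant enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

SS_CLASSES = ("helix", "sheet", "loop")

#: DSSP eight-state to three-class reduction: H/G/I -> helix, E/B -> sheet,
#: everything else (T, S, P, blank, '-') -> loop.
DSSP_TO_SS3 = {
    "H": "helix", "G": "helix", "I": "helix",
    "E": "sheet", "B": "sheet",
}

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


def dssp_to_ss3(code: str) -> str:
    """Reduce a DSSP secondary-structure letter to the three-class scheme."""
    return DSSP_TO_SS3.get(code.strip().upper(), "loop")


@dataclass
class ResidueRecord:
    """One protein residue: identity, author numbering, heavy-atom coordinates.

    ``atoms`` is a list of ``(atom_name, x, y, z)`` tuples in Angstrom;
    hydrogens are never stored. ``ss_class`` is one of helix/sheet/loop and
    may be None until an annotation table is attached.
    """

    chain_id: str
    residue_number: int
    amino_acid: str
    atoms: list[tuple[str, float, float, float]]
    ss_class: str | None = None

    def __post_init__(self) -> None:
        if self.residue_number < 1:
            raise ValueError(
                f"residue_number must be >= 1, got {self.residue_number} "
                f"in chain {self.chain_id}"
            )
        if self.amino_acid not in CANONICAL_AA:
            raise ValueError(f"non-canonical amino acid {self.amino_acid!r}")
        if not self.atoms:
            raise ValueError(
                f"residue {self.chain_id}:{self.residue_number} has no atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(
                f"non-finite coordinates in {self.chain_id}:{self.residue_number}"
            )

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) array of coordinates."""
        return np.array([[x, y, z] for _, x, y, z in self.atoms], dtype=float)

    @property
    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    def side_chain_coords(self) -> np.ndarray:
        """Coordinates of non-backbone atoms; falls back to all atoms."""
        backbone = {"N", "CA", "C", "O", "OXT"}
        sc = [(x, y, z) for name, x, y, z in self.atoms if name not in backbone]
        if not sc:
            return self.coords
        return np.array(sc, dtype=float)


@dataclass
class Ligand:
    """A bound small molecule (here: a guanine nucleotide) with a site tag."""

    name: str
    site: str  # "N-site", "E-site" or "other"
    atoms: list[tuple[str, float, float, float]]

    @property
    def coords(self) -> np.ndarray:
        return np.array([[x, y, z] for _, x, y, z in self.atoms], dtype=float)


@dataclass
class StructureModel:
    """A validated heterodimer: residues per chain plus tagged nucleotides.

    ``chain_roles`` maps each chain id to "alpha" or "beta". The invariants
    (unique (chain, residue_number), residues only in declared chains, unique
    N-/E-site tags) are enforced at construction.
    """

    residues: list[ResidueRecord]
    chain_roles: dict[str, str]
    ligands: list[Ligand] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, int]] = set()
        for r in self.residues:
            if r.chain_id not in self.chain_roles:
                raise ValueError(
                    f"residue in undeclared chain {r.chain_id!r}"
                )
            key = (r.chain_id, r.residue_number)
            if key in seen:
                raise ValueError(f"duplicate residue {key}")
            seen.add(key)
        for role in self.chain_roles.values():
            if role not in ("alpha", "beta"):
                raise ValueError(f"chain role must be alpha/beta, got {role!r}")
        tags = [lg.site for lg in self.ligands if lg.site != "other"]
        if len(tags) != len(set(tags)):
            raise ValueError("N-site/E-site ligand tags must be unique")

    # -- convenience accessors -------------------------------------------------

    def chain(self, chain_id: str) -> list[ResidueRecord]:
        return [r for r in self.residues if r.chain_id == chain_id]

    def chains(self) -> list[str]:
        return list(self.chain_roles)

    def chain_by_role(self, role: str) -> str:
        for cid, r in self.chain_roles.items():
            if r == role:
                return cid
        raise KeyError(f"no chain with role {role!r}")

    def residue(self, chain_id: str, residue_number: int) -> ResidueRecord:
        for r in self.residues:
            if r.chain_id == chain_id and r.residue_number == residue_number:
                return r
        raise KeyError(f"no residue {chain_id}:{residue_number}")

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def all_coords(self) -> np.ndarray:
        return np.vstack([r.coords for r in self.residues])


@dataclass
class CompositionTable:
    """Residue counts and fractions per category — the null proportions f_i."""

    categories: list[str]
    counts: list[int]
    total_residues: int

    def __post_init__(self) -> None:
        if len(self.categories) != len(self.counts):
            raise ValueError("categories/counts length mismatch")
        if any(c < 0 for c in self.counts):
            raise ValueError("negative count")
        if sum(self.counts) != self.total_residues:
            raise ValueError(
                f"counts sum to {sum(self.counts)}, expected {self.total_residues}"
            )

    @property
    def fractions(self) -> np.ndarray:
        return np.array(self.counts, dtype=float) / self.total_residues

    def fraction_of(self, category: str) -> float:
        return self.counts[self.categories.index(category)] / self.total_residues

    def count_of(self, category: str) -> int:
        return self.counts[self.categories.index(category)]

    def as_dict(self) -> dict[str, int]:
        return dict(zip(self.categories, self.counts))


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _best_altloc_atoms(res: "gemmi.Residue") -> list:
    """Keep one conformer per atom name: the highest-occupancy altloc."""
    best: dict[str, object] = {}
    for atom in res:
        if atom.is_hydrogen():
            continue
        prev = best.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            best[atom.name] = atom
    return list(best.values())


def read_structure(
    path: str,
    chain_roles: Mapping[str, str],
    ligand_sites: Mapping[str, str] | None = None,
) -> StructureModel:
    """Read an mmCIF or PDB file into a :class:`StructureModel`.

    Parameters
    ----------
    path
        Coordinate file; format detected from content/extension by gemmi.
    chain_roles
        Mapping of chain id to "alpha" or "beta". Every declared chain must
        be present in the file (hard error otherwise); undeclared chains are
        ignored except when they carry declared ligands.
    ligand_sites
        Mapping from ligand key to site tag ("N-site"/"E-site"/"other").
        Keys may be a residue name ("GTP") or "CHAIN:NAME" ("B:GTP").

    Non-canonical polymer residues are dropped with a warning; hydrogens are
    ignored; only the highest-occupancy altloc conformer is kept; insertion
    codes are rejected.
    """
    ligand_sites = dict(ligand_sites or {})
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    model = st[0]
    present = {ch.name for ch in model}
    for cid in chain_roles:
        if cid not in present:
            raise ValueError(f"chain {cid} absent from {path}")

    residues: list[ResidueRecord] = []
    ligands: list[Ligand] = []
    for ch in model:
        for res in ch:
            key_specific = f"{ch.name}:{res.name}"
            if key_specific in ligand_sites or res.name in ligand_sites:
                tag = ligand_sites.get(key_specific, ligand_sites.get(res.name))
                atoms = [
                    (a.name, a.pos.x, a.pos.y, a.pos.z)
                    for a in _best_altloc_atoms(res)
                ]
                ligands.append(Ligand(name=res.name, site=tag, atoms=atoms))
                continue
            if ch.name not in chain_roles:
                continue
            if res.name == "HOH":
                continue
            aa = THREE_TO_ONE.get(res.name.upper())
            if aa is None:
                log.warning(
                    "dropping non-canonical residue %s %s:%d",
                    res.name, ch.name, res.seqid.num,
                )
                continue
            if res.seqid.icode not in ("", " ", "\x00"):
                raise ValueError(
                    f"insertion code {res.seqid.icode!r} at "
                    f"{ch.name}:{res.seqid.num} is unsupported"
                )
            atoms = [
                (a.name, a.pos.x, a.pos.y, a.pos.z)
                for a in _best_altloc_atoms(res)
            ]
            if not atoms:
                continue
            residues.append(
                ResidueRecord(
                    chain_id=ch.name,
                    residue_number=res.seqid.num,
                    amino_acid=aa,
                    atoms=atoms,
                )
            )
    if not residues:
        raise ValueError(f"{path}: zero canonical residues after filtering")
    return StructureModel(
        residues=residues, chain_roles=dict(chain_roles), ligands=ligands
    )


def write_structure(model: StructureModel, path: str) -> None:
    """Write a StructureModel to mmCIF (readable back by :func:`read_structure`)."""
    st = gemmi.Structure()
    st.name = "tubmap"
    gm = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for cid in model.chain_roles:
        chains[cid] = gemmi.Chain(cid)
    for r in model.residues:
        res = gemmi.Residue()
        res.name = ONE_TO_THREE[r.amino_acid]
        res.seqid = gemmi.SeqId(r.residue_number, " ")
        for name, x, y, z in r.atoms:
            a = gemmi.Atom()
            a.name = name
            a.element = gemmi.Element(name[0])
            a.pos = gemmi.Position(x, y, z)
            a.occ = 1.0
            res.add_atom(a)
        chains[r.chain_id].add_residue(res)
    # one extra chain per ligand, named L1, L2, ... (het entities)
    for i, lg in enumerate(model.ligands, start=1):
        ch = gemmi.Chain(f"L{i}")
        res = gemmi.Residue()
        res.name = lg.name
        res.seqid = gemmi.SeqId(1, " ")
        res.het_flag = "H"
        for name, x, y, z in lg.atoms:
            a = gemmi.Atom()
            a.name = name
            a.element = gemmi.Element("P" if name.startswith("P") else "O")
            a.pos = gemmi.Position(x, y, z)
            a.occ = 1.0
            res.add_atom(a)
        ch.add_residue(res)
        gm.add_chain(ch)
    for ch in chains.values():
        gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    doc = st.make_mmcif_document()
    doc.write_file(str(path))


# ---------------------------------------------------------------------------
# Secondary structure
# ---------------------------------------------------------------------------


def read_ss_table(path: str) -> pd.DataFrame:
    """Read a TSV with columns chain, resnum, ss3 (or DSSP letters in ss3)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chain": str})
    required = {"chain", "resnum", "ss3"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df["ss3"] = [
        s if s in SS_CLASSES else dssp_to_ss3(s) for s in df["ss3"].astype(str)
    ]
    return df


def attach_secondary_structure(
    model: StructureModel, ss_table: pd.DataFrame | Iterable[tuple[str, int, str]]
) -> StructureModel:
    """Attach helix/sheet/loop classes to every residue of the model.

    Annotation rows are (chain, resnum, class). A row that names a residue
    not in the model is a hard error, as is a duplicate row with a
    conflicting class. Residues with no annotation default to loop (logged).
    Returns the same model, mutated.
    """
    if isinstance(ss_table, pd.DataFrame):
        rows = list(
            ss_table[["chain", "resnum", "ss3"]].itertuples(index=False, name=None)
        )
    else:
        rows = list(ss_table)

    index = {(r.chain_id, r.residue_number): r for r in model.residues}
    assigned: dict[tuple[str, int], str] = {}
    for chain, resnum, ss in rows:
        resnum = int(resnum)
        if ss not in SS_CLASSES:
            ss = dssp_to_ss3(str(ss))
        key = (str(chain), resnum)
        if key not in index:
            raise ValueError(
                f"secondary-structure annotation for non-existent residue "
                f"{chain}:{resnum}"
            )
        if key in assigned and assigned[key] != ss:
            raise ValueError(
                f"conflicting secondary-structure annotations for {chain}:{resnum}"
            )
        assigned[key] = ss
    n_default = 0
    for key, res in index.items():
        if key in assigned:
            res.ss_class = assigned[key]
        else:
            res.ss_class = "loop"
            n_default += 1
    if n_default:
        log.warning("%d residues without annotation defaulted to loop", n_default)
    return model


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------


def composition(
    model: StructureModel,
    category_of: Callable[[ResidueRecord], str],
    chains: Sequence[str] | None = None,
    categories: Sequence[str] | None = None,
) -> CompositionTable:
    """Count residues per category over the selected chains.

    ``category_of`` must return exactly one label per residue (None/empty is
    a hard error). ``categories`` fixes the output order and admits
    zero-count categories; otherwise labels appear in first-seen order.
    """
    pool = [
        r for r in model.residues if chains is None or r.chain_id in chains
    ]
    counts: dict[str, int] = {c: 0 for c in (categories or [])}
    for r in pool:
        label = category_of(r)
        if not label:
            raise ValueError(
                f"residue {r.chain_id}:{r.residue_number} received no category"
            )
        if categories is not None and label not in counts:
            raise ValueError(
                f"residue {r.chain_id}:{r.residue_number} labeled {label!r}, "
                f"not in declared categories"
            )
        counts[label] = counts.get(label, 0) + 1
    return CompositionTable(
        categories=list(counts),
        counts=list(counts.values()),
        total_residues=len(pool),
    )


def ss_composition(
    model: StructureModel, chains: Sequence[str] | None = None
) -> CompositionTable:
    """Helix/sheet/loop composition of the (optionally chain-restricted) model."""

    def cat(r: ResidueRecord) -> str:
        if r.ss_class is None:
            raise ValueError(
                f"residue {r.chain_id}:{r.residue_number} has no ss_class; "
                "attach_secondary_structure first"
            )
        return r.ss_class

    return composition(model, cat, chains=chains, categories=list(SS_CLASSES))
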