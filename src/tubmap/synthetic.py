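"""Synthetic inputs with planted ground truth.

Everything the pipeline consumes can be generated here at toy scale: a
cylindrical pseudo-heterodimer lattice whose residues carry known domain
labels, secondary-structure annotation tables with chosen class
proportions, and variant tables with a controllable planted enrichment of
one phenotype in one residue category. The toy geometry mimics the
microtubule wall — concentric luminal/core/outer shells, angular wedges per
protofilament, stacked pseudo-monomers along the axis — without any claim
of structural realism; its purpose is that every downstream rule (contact
detection, burial, radial orientation, ligand proximity, enrichment
statistics) can be checked against construction-time truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .lattice import LatticeSpec, RigidTransform
from .structure import (
    CANONICAL_AA,
    CompositionTable,
    Ligand,
    ResidueRecord,
    StructureModel,
)
from .variants import NOT_AVAILABLE, PHENOTYPES

#: tetrahedral unit offsets for the 4 satellite atoms of a pseudo-residue
_TETRA = np.array(
    [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
) / math.sqrt(3.0)

_ATOM_RADIUS = 0.9  # satellite-atom offset from the residue centroid, A


@dataclass
class ToyLatticeParams:
    """Geometry of the toy cylindrical lattice.

    A pseudo-monomer is a grid of ``n_z`` levels x ``n_theta`` angular
    columns x 3 radial shells (luminal / core / outer) of 5-atom
    pseudo-residues; two stacked monomers form the pseudo-dimer. ``rise`` is
    the monomer height, ``twist`` the angular width of one protofilament
    wedge. ``pocket_residues`` are within-monomer residue numbers that get a
    pseudo-nucleotide planted next to them (defaults to a core-shell pair
    per chain).
    """

    n_theta: int = 6
    n_z: int = 5
    n_shell: int = 3
    radius: float = 50.0
    rise: float = 25.0
    twist: float = 360.0 / 13.0
    shell_gap: float = 6.0
    jitter: float = 0.15
    pocket_residues: tuple[int, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.rise <= 0:
            raise ValueError("radius and rise must be positive")
        if self.n_shell != 3:
            raise ValueError("the toy lattice uses exactly 3 radial shells")
        if self.spacing_z < 2.0:
            raise ValueError(
                "universal clash: rise too small for the residue grid "
                f"(level spacing {self.spacing_z:.2f} A)"
            )
        if self.arc_spacing < 2.0:
            raise ValueError(
                "universal clash: radius/twist give overlapping columns"
            )
        if self.pocket_residues is not None:
            for idx in self.pocket_residues:
                if not 1 <= idx <= self.subunit_size:
                    raise ValueError(
                        f"pocket residue {idx} outside monomer range "
                        f"1..{self.subunit_size}"
                    )

    @property
    def subunit_size(self) -> int:
        return self.n_theta * self.n_z * self.n_shell

    @property
    def spacing_z(self) -> float:
        return self.rise / self.n_z

    @property
    def arc_spacing(self) -> float:
        return 2 * math.pi * self.radius * (self.twist / 360.0) / self.n_theta

    def default_pockets(self) -> tuple[int, ...]:
        """A z-adjacent pair of interior core-shell residues."""
        c, s = self.n_theta // 2, 1
        return (
            self._resnum(1, c, s),
            self._resnum(2, c, s),
        )

    def _resnum(self, k: int, c: int, s: int) -> int:
        return (k * self.n_theta + c) * self.n_shell + s + 1


def _grid_of(params: ToyLatticeParams, resnum: int) -> tuple[int, int, int]:
    idx = resnum - 1
    s = idx % params.n_shell
    c = (idx // params.n_shell) % params.n_theta
    k = idx // (params.n_shell * params.n_theta)
    return k, c, s


def _planted_label(
    params: ToyLatticeParams, role: str, resnum: int, pockets: set[int]
) -> str:
    """Construction-time domain label, mirroring the assignment precedence."""
    k, c, s = _grid_of(params, resnum)
    long_level = 0 if role == "alpha" else params.n_z - 1
    intra_level = params.n_z - 1 if role == "alpha" else 0
    if resnum in pockets:
        return "GTP binding"
    if k == long_level:
        return "longitudinal"
    if c in (0, params.n_theta - 1):
        return "lateral"
    if k == intra_level:
        return "intradimer"
    if s == 2:
        return "MAP binding"
    if s == 0:
        return "lumen"
    return "other"


@dataclass
class ToyLattice:
    """A generated toy lattice: model, planted truth, spec, annotations."""

    model: StructureModel
    ground_truth: pd.DataFrame  # chain, resnum, aa, planted_label, boundary_distance
    spec: LatticeSpec
    ss_table: pd.DataFrame  # chain, resnum, ss3
    params: ToyLatticeParams

    def planted_labels(self) -> dict[tuple[str, int], str]:
        return {
            (row.chain, row.resnum): row.planted_label
            for row in self.ground_truth.itertuples()
        }

    def alpha_labels(self) -> dict[int, str]:
        """resnum -> planted label for the alpha chain (variant positions)."""
        alpha = self.model.chain_by_role("alpha")
        return {
            row.resnum: row.planted_label
            for row in self.ground_truth.itertuples()
            if row.chain == alpha
        }

    def alpha_wt(self) -> dict[int, str]:
        alpha = self.model.chain_by_role("alpha")
        return {
            r.residue_number: r.amino_acid for r in self.model.chain(alpha)
        }

    def alpha_composition(self) -> CompositionTable:
        """Planted domain composition of the alpha chain."""
        from .lattice import DOMAIN_LABELS

        labels = self.alpha_labels()
        counts = {c: 0 for c in DOMAIN_LABELS}
        for lab in labels.values():
            counts[lab] += 1
        return CompositionTable(
            categories=list(counts),
            counts=list(counts.values()),
            total_residues=len(labels),
        )

    def write(self, outdir: str) -> dict[str, Path]:
        """Write structure.cif, ground_truth.tsv, ss.tsv, lattice.json."""
        from .structure import write_structure

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "structure": out / "structure.cif",
            "ground_truth": out / "ground_truth.tsv",
            "ss": out / "ss.tsv",
            "lattice": out / "lattice.json",
        }
        write_structure(self.model, str(paths["structure"]))
        self.ground_truth.to_csv(
            paths["ground_truth"], sep="\t", index=False, float_format="%.4f"
        )
        self.ss_table.to_csv(paths["ss"], sep="\t", index=False)
        self.spec.save(str(paths["lattice"]))
        return paths


def _rot_z(degrees: float) -> np.ndarray:
    t = math.radians(degrees)
    c, s = math.cos(t), math.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def make_toy_lattice(
    params: ToyLatticeParams | None = None, outdir: str | None = None
) -> ToyLattice:
    """Build the toy pseudo-dimer, its lattice spec and planted truth.

    Deterministic given ``params.seed``: repeated calls produce identical
    output (byte-identical files via :meth:`ToyLattice.write`).
    """
    params = params or ToyLatticeParams()
    rng = np.random.default_rng(params.seed)
    pockets = set(params.pocket_residues or params.default_pockets())

    chain_roles = {"A": "alpha", "B": "beta"}
    residues: list[ResidueRecord] = []
    truth_rows = []
    centroids: dict[tuple[str, int], np.ndarray] = {}
    twist_rad = math.radians(params.twist)

    for cid, role in chain_roles.items():
        z0 = 0.0 if role == "alpha" else params.rise
        for resnum in range(1, params.subunit_size + 1):
            k, c, s = _grid_of(params, resnum)
            theta = (c + 0.5) * twist_rad / params.n_theta
            r = params.radius + (s - 1) * params.shell_gap
            z = z0 + (k + 0.5) * params.spacing_z
            base = np.array([r * math.cos(theta), r * math.sin(theta), z])
            pos = base + rng.uniform(-params.jitter, params.jitter, 3)
            aa = rng.choice(list(CANONICAL_AA))
            atoms = [("CA", *pos)]
            for i, off in enumerate(_TETRA, start=1):
                atoms.append((f"CB{i}", *(pos + _ATOM_RADIUS * off)))
            residues.append(
                ResidueRecord(
                    chain_id=cid,
                    residue_number=resnum,
                    amino_acid=str(aa),
                    atoms=[(n, float(x), float(y), float(z_)) for n, x, y, z_ in atoms],
                )
            )
            centroids[(cid, resnum)] = pos

    # pseudo-nucleotides: one per chain at the pocket-pair midpoint
    ligands = []
    lig_midpoints: dict[str, np.ndarray] = {}
    for cid, role in chain_roles.items():
        pk = sorted(pockets)
        mid = np.mean([centroids[(cid, p)] for p in pk], axis=0)
        lig_midpoints[cid] = mid
        site = "N-site" if role == "alpha" else "E-site"
        atoms = [
            ("PG", *mid),
            ("O1", *(mid + np.array([0.3, 0.0, 0.0]))),
            ("O2", *(mid + np.array([0.0, 0.3, 0.0]))),
        ]
        ligands.append(
            Ligand(
                name="GTP",
                site=site,
                atoms=[(n, float(x), float(y), float(z_)) for n, x, y, z_ in atoms],
            )
        )

    model = StructureModel(
        residues=residues, chain_roles=chain_roles, ligands=ligands
    )

    ligand_cutoff = 3.2
    spec = LatticeSpec(
        axis_point=np.zeros(3),
        axis_direction=np.array([0.0, 0.0, 1.0]),
        longitudinal=RigidTransform(
            np.eye(3), np.array([0.0, 0.0, 2 * params.rise])
        ),
        lateral=(
            RigidTransform(_rot_z(params.twist), np.zeros(3)),
            RigidTransform(_rot_z(-params.twist), np.zeros(3)),
        ),
        contact_cutoff=4.5,
        ligand_cutoff=ligand_cutoff,
    )

    # planted truth + distance to the nearest planted category boundary
    for r in model.residues:
        role = chain_roles[r.chain_id]
        label = _planted_label(params, role, r.residue_number, pockets)
        pos = centroids[(r.chain_id, r.residue_number)]
        rad = math.hypot(pos[0], pos[1])
        theta = math.atan2(pos[1], pos[0]) % (2 * math.pi)
        z0 = 0.0 if role == "alpha" else params.rise
        d_shell = min(
            abs(rad - (params.radius - params.shell_gap / 2)),
            abs(rad - (params.radius + params.shell_gap / 2)),
        )
        col_bounds = [
            twist_rad / params.n_theta,
            twist_rad * (params.n_theta - 1) / params.n_theta,
            0.0,
            twist_rad,
        ]
        d_col = min(rad * abs(theta - tb) for tb in col_bounds)
        z_bounds = [
            z0 + params.spacing_z,
            z0 + params.rise - params.spacing_z,
            z0,
            z0 + params.rise,
        ]
        d_z = min(abs(pos[2] - zb) for zb in z_bounds)
        d_pocket = abs(
            float(np.linalg.norm(pos - lig_midpoints[r.chain_id]))
            - ligand_cutoff
        )
        truth_rows.append(
            {
                "chain": r.chain_id,
                "resnum": r.residue_number,
                "aa": r.amino_acid,
                "planted_label": label,
                "boundary_distance": min(d_shell, d_col, d_z, d_pocket),
            }
        )
    truth = pd.DataFrame(truth_rows)

    ss_table = make_ss_table(
        n_residues=params.subunit_size,
        chains=list(chain_roles),
        seed=params.seed,
    )

    toy = ToyLattice(
        model=model, ground_truth=truth, spec=spec,
        ss_table=ss_table, params=params,
    )
    if outdir is not None:
        toy.write(outdir)
    return toy


# ---------------------------------------------------------------------------
# Secondary-structure annotation tables
# ---------------------------------------------------------------------------


def make_ss_table(
    n_residues: int = 451,
    proportions: tuple[float, float, float] = (0.39, 0.12, 0.49),
    chains: list[str] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Annotation table with exact class proportions (largest remainder).

    Residues are laid out as alternating helix / loop / sheet / loop
    segments so the table looks like a real topology file; the per-class
    counts hit the requested helix/sheet/loop proportions as closely as
    integer counts allow. Defaults emulate an alpha-tubulin-like chain of
    451 residues at 39% helix, 12% sheet, 49% loop. ``seed`` is accepted for
    interface symmetry but the layout is deterministic.
    """
    if abs(sum(proportions) - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    chains = chains or ["A"]
    raw = [p * n_residues for p in proportions]
    counts = [int(x) for x in raw]
    while sum(counts) < n_residues:
        rema = [r - c for r, c in zip(raw, counts)]
        counts[int(np.argmax(rema))] += 1
    n_helix, n_sheet, n_loop = counts

    labels: list[str] = []
    rem = {"helix": n_helix, "sheet": n_sheet, "loop": n_loop}
    seg = {"helix": 9, "sheet": 5, "loop": 6}
    order = ["helix", "loop", "sheet", "loop"]
    i = 0
    while sum(rem.values()) > 0:
        cls = order[i % len(order)]
        take = min(seg[cls], rem[cls])
        labels.extend([cls] * take)
        rem[cls] -= take
        i += 1
    rows = [
        {"chain": ch, "resnum": j + 1, "ss3": labels[j]}
        for ch in chains
        for j in range(n_residues)
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Variant tables with planted enrichment
# ---------------------------------------------------------------------------


@dataclass
class PlantedEnrichmentParams:
    """Sampling design for a synthetic variant table.

    Positions are drawn per phenotype with weight ``fold`` on positions of
    ``target_category`` for ``target_phenotype`` and weight 1 elsewhere, so
    ``fold=1`` is the composition-proportional null. Phenotype totals
    default to 30 per clinical label (none unlabeled).
    """

    n_per_phenotype: Mapping[str, int] = field(
        default_factory=lambda: {p: 30 for p in PHENOTYPES}
    )
    target_phenotype: str = PHENOTYPES[2]  # pachygyria
    target_category: str = "MAP binding"
    fold: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fold < 1.0:
            raise ValueError("fold must be >= 1")
        for p, n in self.n_per_phenotype.items():
            if p not in PHENOTYPES and p != NOT_AVAILABLE:
                raise ValueError(f"unknown phenotype {p!r}")
            if n < 0:
                raise ValueError("phenotype counts must be >= 0")


def make_variant_table(
    params: PlantedEnrichmentParams,
    labels: Mapping[int, str],
    wt_of: Mapping[int, str] | None = None,
    out_path: str | None = None,
) -> pd.DataFrame:
    """Draw a variant table over the labeled positions.

    ``labels`` maps alpha-chain positions to their category; ``wt_of`` maps
    positions to wild-type residues (random but seed-stable when omitted).
    The mutant residue is uniform over the 19 alternatives. Deterministic
    given ``params.seed``.
    """
    if not labels:
        raise ValueError("empty label map")
    rng = np.random.default_rng(params.seed)
    positions = sorted(labels)
    if wt_of is None:
        wt_of = {
            pos: str(rng.choice(list(CANONICAL_AA))) for pos in positions
        }
    rows = []
    for pheno in list(PHENOTYPES) + [NOT_AVAILABLE]:
        n = params.n_per_phenotype.get(pheno, 0)
        if n == 0:
            continue
        w = np.array(
            [
                params.fold
                if (
                    pheno == params.target_phenotype
                    and labels[pos] == params.target_category
                )
                else 1.0
                for pos in positions
            ]
        )
        w /= w.sum()
        drawn = rng.choice(positions, size=n, p=w)
        for pos in drawn:
            wt = wt_of[int(pos)]
            alts = [a for a in CANONICAL_AA if a != wt]
            mut = str(rng.choice(alts))
            rows.append(
                {
                    "substitution": f"{wt}{int(pos)}{mut}",
                    "phenotype": pheno,
                }
            )
    df = pd.DataFrame(rows, columns=["substitution", "phenotype"])
    if out_path is not None:
        df.to_csv(out_path, sep="\t", index=False)
    return df


# ---------------------------------------------------------------------------
# Simulation study
# ---------------------------------------------------------------------------


@dataclass
class SimulationSummary:
    """Per-cell rejection rates plus target-cell diagnostics."""

    rejection: pd.DataFrame  # phenotype, category, rejection_rate, n_rejected
    replicates: int
    alpha: float
    fold: float
    target: tuple[str, str]
    target_min_p_fraction: float


def run_simulation_study(
    labels: Mapping[int, str],
    composition: CompositionTable,
    params: PlantedEnrichmentParams | None = None,
    replicates: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
    mode: str = "residues",
    wt_of: Mapping[int, str] | None = None,
) -> SimulationSummary:
    """Repeatedly draw variant tables and scan them for enrichment.

    Reports, per (phenotype, category) cell, the fraction of replicates
    whose Fisher p fell below ``alpha``, and the fraction of replicates in
    which the planted target cell attained the scan's minimum p.
    """
    from io import StringIO

    from .stats import enrichment_scan
    from .variants import load_variant_table

    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    params = params or PlantedEnrichmentParams()
    rng = np.random.default_rng(seed)
    getter = labels.get
    cells: dict[tuple[str, str], int] = {}
    n_target_min = 0
    cache: dict = {}
    for _ in range(replicates):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        rep_params = PlantedEnrichmentParams(
            n_per_phenotype=dict(params.n_per_phenotype),
            target_phenotype=params.target_phenotype,
            target_category=params.target_category,
            fold=params.fold,
            seed=rep_seed,
        )
        df = make_variant_table(rep_params, labels, wt_of=wt_of)
        table = load_variant_table(StringIO(df.to_csv(sep="\t", index=False)))
        report = enrichment_scan(
            table, getter, composition, mode=mode, alpha=alpha,
            gof=False, _fisher_cache=cache,
        )
        p_min = min(r.p_value for r in report.rows)
        for r in report.rows:
            key = (r.phenotype, r.category)
            cells.setdefault(key, 0)
            if r.p_value < alpha:
                cells[key] += 1
            if (
                key == (params.target_phenotype, params.target_category)
                and r.p_value <= p_min * (1 + 1e-12)
            ):
                n_target_min += 1
    rows = [
        {
            "phenotype": m,
            "category": s,
            "n_rejected": k,
            "rejection_rate": k / replicates,
        }
        for (m, s), k in cells.items()
    ]
    return SimulationSummary(
        rejection=pd.DataFrame(rows),
        replicates=replicates,
        alpha=alpha,
        fold=params.fold,
        target=(params.target_phenotype, params.target_category),
        target_min_p_fraction=n_target_min / replicates,
    )
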