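"""Missense-variant tables and amino-acid-property change classification.

Heterozygous missense substitutions in the alpha-tubulin chain are parsed
from compact ("R402C") or protein-HGVS-like ("p.Arg402Cys") notation,
validated against the structure's sequence, tagged with one predominant
cortical-malformation label, and sorted into four side-chain-change
categories: loss of charge or charge swap, gain of charge, loss or gain of
hydrophobicity, and no change in either property. The categories are not
mutually exclusive — a single substitution may both lose a charge and gain
hydrophobicity.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd
from Bio.Data.IUPACData import protein_letters_3to1

from .structure import CANONICAL_AA, StructureModel

PHENOTYPES = (
    "lissencephaly",
    "microlissencephaly",
    "pachygyria",
    "polymicrogyria",
)
NOT_AVAILABLE = "not_available"
PHENOTYPE_VOCAB = PHENOTYPES + (NOT_AVAILABLE,)

CHANGE_FLAGS = (
    "charge_loss_or_swap",
    "charge_gain",
    "hydrophobicity_change",
    "no_change",
)

#: Kyte-Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


@dataclass
class PropertyTable:
    """Side-chain charge and hydrophobicity conventions.

    Charged residues default to D/E (negative) and K/R (positive); histidine
    is neutral by default (side-chain pKa ~ 6) but can be counted positive
    with ``histidine_positive``. The hydrophobic set is every residue with
    positive hydropathy on the Kyte-Doolittle scale: {A, C, F, I, L, M, V}.
    """

    histidine_positive: bool = False
    hydropathy_of: dict[str, float] = field(
        default_factory=lambda: dict(KYTE_DOOLITTLE)
    )

    def __post_init__(self) -> None:
        missing = set(CANONICAL_AA) - set(self.hydropathy_of)
        if missing:
            raise ValueError(f"hydropathy scale missing {sorted(missing)}")

    def charge_of(self, aa: str) -> str:
        if aa in ("D", "E"):
            return "negative"
        if aa in ("K", "R") or (aa == "H" and self.histidine_positive):
            return "positive"
        return "neutral"

    @property
    def hydrophobic_set(self) -> frozenset[str]:
        return frozenset(a for a, h in self.hydropathy_of.items() if h > 0)

    def is_hydrophobic(self, aa: str) -> bool:
        return self.hydropathy_of[aa] > 0

    def describe(self) -> str:
        return (
            f"charge: D,E negative; K,R{',H' if self.histidine_positive else ''} "
            f"positive | hydrophobic: {''.join(sorted(self.hydrophobic_set))}"
        )


@dataclass
class MutationRecord:
    """One missense substitution with phenotype and change flags."""

    wt_aa: str
    position: int
    mut_aa: str
    phenotype: str
    change_flags: frozenset[str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.wt_aa == self.mut_aa:
            raise ValueError(f"silent substitution at {self.position}")
        if self.phenotype not in PHENOTYPE_VOCAB:
            raise ValueError(f"unknown phenotype {self.phenotype!r}")
        if not self.change_flags:
            raise ValueError("change_flags must be non-empty")
        if "no_change" in self.change_flags and len(self.change_flags) > 1:
            raise ValueError("no_change excludes every other flag")

    @property
    def substitution(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mut_aa}"


@dataclass
class MutationTable:
    records: list[MutationRecord]

    @property
    def count(self) -> int:
        return len(self.records)

    def clinically_labeled(self) -> "MutationTable":
        return MutationTable(
            [r for r in self.records if r.phenotype != NOT_AVAILABLE]
        )

    def n_dropped(self) -> int:
        return sum(1 for r in self.records if r.phenotype == NOT_AVAILABLE)

    def phenotype_counts(self) -> dict[str, int]:
        out = {p: 0 for p in PHENOTYPE_VOCAB}
        for r in self.records:
            out[r.phenotype] += 1
        return out


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_ONE = re.compile(r"^(?:p\.)?([A-Z])(\d+)([A-Z])$")
_THREE = re.compile(r"^(?:p\.)?([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2})$")

_3TO1 = {k.upper(): v for k, v in protein_letters_3to1.items()}


def parse_substitution(text: str) -> tuple[str, int, str]:
    """Parse "R402C" or "p.Arg402Cys" into a (wt, position, mut) triple."""
    token = text.strip()
    if not token:
        raise ValueError("empty substitution string")
    m = _ONE.match(token)
    if m:
        wt, pos, mut = m.group(1), int(m.group(2)), m.group(3)
    else:
        m = _THREE.match(token)
        if not m:
            raise ValueError(f"malformed substitution {token!r}")
        try:
            wt = _3TO1[m.group(1).upper()]
            mut = _3TO1[m.group(3).upper()]
        except KeyError as e:
            raise ValueError(
                f"unknown residue code {e.args[0]!r} in {token!r}"
            ) from None
        pos = int(m.group(2))
    for aa in (wt, mut):
        if aa not in CANONICAL_AA:
            raise ValueError(f"unknown residue code {aa!r} in {token!r}")
    if wt == mut:
        raise ValueError(f"silent substitution {token!r}")
    if pos < 1:
        raise ValueError(f"position must be >= 1 in {token!r}")
    return wt, pos, mut


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


def classify_substitution(
    wt_aa: str, mut_aa: str, props: PropertyTable | None = None
) -> frozenset[str]:
    """Flag the property changes of one substitution.

    * ``charge_loss_or_swap`` — wild type charged, mutant neutral or of the
      opposite charge;
    * ``charge_gain`` — wild type neutral, mutant charged;
    * ``hydrophobicity_change`` — exactly one of the two is hydrophobic;
    * ``no_change`` — none of the above (and then nothing else).
    """
    props = props or PropertyTable()
    for aa in (wt_aa, mut_aa):
        if aa not in CANONICAL_AA:
            raise ValueError(f"non-canonical amino acid {aa!r}")
    cw, cm = props.charge_of(wt_aa), props.charge_of(mut_aa)
    flags = set()
    if cw != "neutral" and cm != cw:
        flags.add("charge_loss_or_swap")
    if cw == "neutral" and cm != "neutral":
        flags.add("charge_gain")
    if props.is_hydrophobic(wt_aa) != props.is_hydrophobic(mut_aa):
        flags.add("hydrophobicity_change")
    if not flags:
        flags.add("no_change")
    return frozenset(flags)


# ---------------------------------------------------------------------------
# Table IO
# ---------------------------------------------------------------------------


def _normalize_phenotype(raw: str) -> str:
    p = str(raw).strip().lower().replace(" ", "_")
    if p in ("na", "n/a", "none", "not_available", "unknown", ""):
        return NOT_AVAILABLE
    if p not in PHENOTYPE_VOCAB:
        raise ValueError(f"unknown phenotype label {raw!r}")
    return p


def load_variant_table(
    path: str,
    model: StructureModel | None = None,
    props: PropertyTable | None = None,
) -> MutationTable:
    """Load and classify a TSV of substitutions.

    Requires columns ``substitution`` and ``phenotype``; any extra columns
    are preserved per record as metadata. When a structure is supplied, each
    wild-type residue is cross-checked against the alpha-chain sequence at
    the author-numbered position (hard error on mismatch).
    """
    props = props or PropertyTable()
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("substitution", "phenotype"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    extra = [c for c in df.columns if c not in ("substitution", "phenotype")]

    alpha_seq: dict[int, str] = {}
    if model is not None:
        alpha = model.chain_by_role("alpha")
        alpha_seq = {
            r.residue_number: r.amino_acid for r in model.chain(alpha)
        }

    records = []
    for row in df.itertuples(index=False):
        wt, pos, mut = parse_substitution(str(row.substitution))
        if model is not None:
            found = alpha_seq.get(pos)
            if found is None:
                raise ValueError(
                    f"position {pos}: no residue in the alpha chain"
                )
            if found != wt:
                raise ValueError(
                    f"position {pos}: variant says wild type {wt}, "
                    f"structure has {found}"
                )
        records.append(
            MutationRecord(
                wt_aa=wt,
                position=pos,
                mut_aa=mut,
                phenotype=_normalize_phenotype(row.phenotype),
                change_flags=classify_substitution(wt, mut, props),
                metadata={c: getattr(row, c) for c in extra},
            )
        )
    return MutationTable(records)


def tabulate(
    table: MutationTable,
    label_of,
    restrict: str | None = None,
    categories: list[str] | None = None,
) -> dict[str, int]:
    """Count variants per category.

    ``label_of`` maps an alpha-chain position to its category (a callable or
    mapping). ``restrict="labeled"`` first drops records without clinical
    imaging data (phenotype ``not_available``). A position with no category
    is a hard error.
    """
    if restrict not in (None, "labeled"):
        raise ValueError(f"unknown restrict mode {restrict!r}")
    pool = table.clinically_labeled() if restrict == "labeled" else table
    getter = label_of if callable(label_of) else label_of.get
    counts: dict[str, int] = {c: 0 for c in (categories or [])}
    for rec in pool.records:
        label = getter(rec.position)
        if label is None:
            raise ValueError(f"position {rec.position} has no category label")
        counts[label] = counts.get(label, 0) + 1
    return counts


def classified_frame(table: MutationTable) -> pd.DataFrame:
    """Long-form DataFrame of the table with one boolean column per flag."""
    rows = []
    for r in table.records:
        d = {
            "substitution": r.substitution,
            "wt_aa": r.wt_aa,
            "position": r.position,
            "mut_aa": r.mut_aa,
            "phenotype": r.phenotype,
        }
        for flag in CHANGE_FLAGS:
            d[flag] = flag in r.change_flags
        d.update(r.metadata)
        rows.append(d)
    return pd.DataFrame(rows)
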