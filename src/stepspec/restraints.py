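"""Compilation of NMR-derived distance restraints for restrained MD.

Two restraint families are produced:

* **NOE restraints** — intermolecular NOESY crosspeaks between ligand
  and DNA protons, classified weak/medium/strong.  Only correlations of
  the ligand's *aromatic* protons are compiled (the flexible aliphatic
  sidechain samples multiple orientations, so its NOEs cannot all be
  satisfied by one structure).  Crosspeaks that are superimposed in the
  spectrum are merged into a single restraint carrying several atom
  pairs with averaged-distance semantics.
* **Watson–Crick restraints** — donor–acceptor heavy-atom distances
  holding the hydrogen bonds of retained base pairs (3 per G·C, 2 per
  A·T); terminal pairs, whose imino protons exchange too fast to be
  observed, are excluded by default.

Intensity classes map to distance bounds through a configurable
calibration table; bounds are kept in Å and converted to nm only when
serializing to the GROMACS ``[ distance_restraints ]`` dialect.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from stepspec.duplex import DuplexSequence

AROMATIC = "aromatic"
SIDECHAIN = "sidechain"

#: Default ligand-proton catalog: ring protons vs aliphatic sidechain.
DEFAULT_CATALOG: dict[str, str] = {
    "LH3": AROMATIC,
    "LH4": AROMATIC,
    "LH7": AROMATIC,
    "LH9": AROMATIC,
    "LH10": AROMATIC,
    "LH15": SIDECHAIN,
    "LH17": SIDECHAIN,
    "LH18": SIDECHAIN,
}

_INTENSITIES = ("strong", "medium", "weak")

_CONTACT_RE = re.compile(
    r"^(?P<ligand>L\w+?)(?P<strand>[AB])-(?P<base>[ACGT])(?P<residue>\d+)(?P<proton>\S+)$"
)


class ContactParseError(ValueError):
    """A contact string does not follow <ligand><strand>-<residue><atom>."""


class CalibrationError(KeyError):
    """No calibration entry for an intensity class."""


class AtomMapError(KeyError):
    """Atom descriptors missing from a topology index map."""


@dataclass(frozen=True)
class Atom:
    """One restrained atom: either a DNA proton/heavy atom or a ligand
    proton."""

    molecule: str  # "dna" | "ligand"
    name: str
    strand: str | None = None  # "A"/"B" for DNA
    base: str | None = None
    residue: int | None = None

    @property
    def descriptor(self) -> str:
        if self.molecule == "ligand":
            return f"ligand:{self.name}"
        return f"dna:{self.strand}:{self.base}{self.residue}:{self.name}"

    @classmethod
    def from_descriptor(cls, desc: str) -> "Atom":
        parts = desc.split(":")
        if parts[0] == "ligand" and len(parts) == 2:
            return cls("ligand", parts[1])
        if parts[0] == "dna" and len(parts) == 4:
            m = re.match(r"([ACGT])(\d+)$", parts[2])
            if m:
                return cls(
                    "dna", parts[3], strand=parts[1],
                    base=m.group(1), residue=int(m.group(2)),
                )
        raise ValueError(f"malformed atom descriptor {desc!r}")


@dataclass(frozen=True)
class NoePeak:
    """A classified intermolecular NOESY crosspeak in one complex."""

    row_no: int
    ligand_proton: str
    dna_strand: str
    dna_base: str
    dna_residue: int
    dna_proton: str
    intensity: str
    complex_id: str
    category: str
    superimposed_group: str | None = None

    @property
    def contact(self) -> str:
        return (
            f"{self.ligand_proton}{self.dna_strand}-"
            f"{self.dna_base}{self.dna_residue}{self.dna_proton}"
        )

    @property
    def atoms(self) -> tuple[Atom, Atom]:
        return (
            Atom("ligand", self.ligand_proton),
            Atom(
                "dna",
                self.dna_proton,
                strand=self.dna_strand,
                base=self.dna_base,
                residue=self.dna_residue,
            ),
        )


@dataclass(frozen=True)
class CalibrationTable:
    """Intensity class -> (lower, upper1, upper2) bounds in Å.

    The defaults are conventional NOE distance classes; upper bounds
    must strictly increase from strong to weak.
    """

    bounds: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "strong": (1.8, 3.5, 4.5),
            "medium": (1.8, 4.5, 5.5),
            "weak": (1.8, 6.0, 7.0),
        }
    )

    def __post_init__(self) -> None:
        uppers = [
            self.bounds[c][1] for c in _INTENSITIES if c in self.bounds
        ]
        if sorted(uppers) != uppers or len(set(uppers)) != len(uppers):
            raise ValueError(
                "upper bounds must strictly increase from strong to weak"
            )
        for cls, (lo, u1, u2) in self.bounds.items():
            if not 0 < lo <= u1 <= u2:
                raise ValueError(f"{cls}: bounds must satisfy 0 < lo <= u1 <= u2")

    def lookup(self, intensity: str) -> tuple[float, float, float]:
        try:
            return self.bounds[intensity]
        except KeyError:
            raise CalibrationError(
                f"no calibration for intensity {intensity!r}"
            ) from None


DEFAULT_CALIBRATION = CalibrationTable()
DEFAULT_FORCE_CONSTANT = 1000.0  # kJ mol^-1 nm^-2

#: Donor–acceptor heavy-atom pairs per Watson–Crick pair, keyed by the
#: purine; (purine atom, pyrimidine atom).
_WC_PAIRS = {
    "G": (("N1", "N3"), ("N2", "O2"), ("O6", "N4")),
    "A": (("N1", "N3"), ("N6", "O4")),
}
_WC_BOUNDS = (2.7, 3.1, 3.3)  # Å, canonical B-DNA H-bond window


@dataclass(frozen=True)
class DistanceRestraint:
    """An atom-pair distance restraint with flat-bottom quadratic walls.

    ``pairs`` holds one pair normally, several for merged/ambiguous
    restraints sharing one restraint index (averaged-distance
    semantics).  Bounds in Å, force constant in kJ·mol⁻¹·nm⁻².
    """

    pairs: tuple[tuple[Atom, Atom], ...]
    lower: float
    upper1: float
    upper2: float
    force_constant: float = DEFAULT_FORCE_CONSTANT
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("restraint needs at least one atom pair")
        if not 0 < self.lower <= self.upper1 <= self.upper2:
            raise ValueError(
                f"bounds must satisfy 0 < lower <= upper1 <= upper2, got "
                f"({self.lower}, {self.upper1}, {self.upper2})"
            )
        if self.force_constant <= 0:
            raise ValueError("force constant must be positive")


def parse_noe_table(
    path: str | Path | io.StringIO,
    catalog: Mapping[str, str] | None = None,
) -> list[NoePeak]:
    """Parse an NOE contact table CSV into per-complex peaks.

    The table has columns ``no``, ``contact`` (e.g. ``LH3B-A5H1'``),
    one intensity column per complex ('-' marks absence) and optional
    ``<complex>_group`` columns flagging superimposed crosspeaks.
    """
    catalog = dict(DEFAULT_CATALOG if catalog is None else catalog)
    df = pd.read_csv(path, dtype=str).fillna("")
    complexes = [
        c for c in df.columns
        if c not in ("no", "contact") and not c.endswith("_group")
    ]
    peaks: list[NoePeak] = []
    for row in df.to_dict("records"):
        m = _CONTACT_RE.match(row["contact"].strip())
        if not m:
            raise ContactParseError(
                f"row {row['no']}: cannot parse contact {row['contact']!r}"
            )
        ligand = m.group("ligand")
        if ligand not in catalog:
            raise KeyError(
                f"row {row['no']}: ligand proton {ligand!r} not in catalog"
            )
        for cid in complexes:
            cell = row[cid].strip()
            if cell in ("-", "", "−"):
                continue
            if cell not in _INTENSITIES:
                raise ValueError(
                    f"row {row['no']}: unknown intensity {cell!r}"
                )
            group = row.get(f"{cid}_group", "").strip() or None
            peaks.append(
                NoePeak(
                    row_no=int(row["no"]),
                    ligand_proton=ligand,
                    dna_strand=m.group("strand"),
                    dna_base=m.group("base"),
                    dna_residue=int(m.group("residue")),
                    dna_proton=m.group("proton"),
                    intensity=cell,
                    complex_id=cid,
                    category=catalog[ligand],
                    superimposed_group=group,
                )
            )
    return peaks


def select_restraint_peaks(
    peaks: Sequence[NoePeak], complex_id: str
) -> list[list[NoePeak]]:
    """Aromatic-proton peaks of one complex, superimposed peaks grouped.

    Each returned group becomes one distance restraint.
    """
    selected = [
        p for p in peaks
        if p.complex_id == complex_id and p.category == AROMATIC
    ]
    groups: dict[str, list[NoePeak]] = {}
    order: list[str] = []
    for p in selected:
        key = (
            f"grp:{p.superimposed_group}"
            if p.superimposed_group
            else f"row:{p.row_no}:{p.contact}"
        )
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(p)
    return [groups[k] for k in order]


def calibrate(
    group: Sequence[NoePeak],
    table: CalibrationTable = DEFAULT_CALIBRATION,
    force_constant: float = DEFAULT_FORCE_CONSTANT,
) -> DistanceRestraint:
    """Turn one peak group into a restraint via the calibration table."""
    if not group:
        raise ValueError("empty peak group")
    intensities = {p.intensity for p in group}
    if len(intensities) > 1:
        raise ValueError(
            f"superimposed peaks with mixed intensities: {sorted(intensities)}"
        )
    lo, u1, u2 = table.lookup(group[0].intensity)
    provenance = tuple(f"{p.complex_id}:row{p.row_no}:{p.contact}" for p in group)
    if len(group) > 1:
        provenance += ("merged-superimposed",)
    return DistanceRestraint(
        pairs=tuple(p.atoms for p in group),
        lower=lo,
        upper1=u1,
        upper2=u2,
        force_constant=force_constant,
        provenance=provenance,
    )


def compile_noe_restraints(
    peaks: Sequence[NoePeak],
    complex_id: str,
    table: CalibrationTable = DEFAULT_CALIBRATION,
    force_constant: float = DEFAULT_FORCE_CONSTANT,
) -> list[DistanceRestraint]:
    """Select, merge and calibrate the NOE restraints of one complex."""
    return [
        calibrate(g, table, force_constant)
        for g in select_restraint_peaks(peaks, complex_id)
    ]


def wc_restraints(
    duplex: DuplexSequence,
    exclude: str | Callable[[int, int], bool] = "terminal",
    bounds: tuple[float, float, float] = _WC_BOUNDS,
    force_constant: float = DEFAULT_FORCE_CONSTANT,
) -> list[DistanceRestraint]:
    """Watson–Crick hydrogen-bond restraints for retained base pairs.

    ``exclude`` is ``"terminal"`` (drop pairs 1 and L — their imino
    protons are unobservable), ``"none"``, or a predicate
    ``(pair_index, L) -> bool`` returning True to drop a pair.
    Each retained G·C pair yields 3 restraints, each A·T pair 2.
    """
    L = duplex.length
    if exclude == "terminal":
        drop = lambda i, L: i == 1 or i == L  # noqa: E731
    elif exclude == "none":
        drop = lambda i, L: False  # noqa: E731
    elif callable(exclude):
        drop = exclude
    else:
        raise ValueError(f"unknown exclusion rule {exclude!r}")

    restraints: list[DistanceRestraint] = []
    for i in range(1, L + 1):
        if drop(i, L):
            continue
        top = duplex.top_strand[i - 1]
        j = L + 1 - i  # partner residue on strand B
        bottom = duplex.bottom_strand[j - 1]
        # orient as (purine, pyrimidine)
        if top in "GA":
            pur = Atom("dna", "", strand="A", base=top, residue=i)
            pyr = Atom("dna", "", strand="B", base=bottom, residue=j)
            key = top
        else:
            pur = Atom("dna", "", strand="B", base=bottom, residue=j)
            pyr = Atom("dna", "", strand="A", base=top, residue=i)
            key = bottom
        for pur_atom, pyr_atom in _WC_PAIRS[key]:
            a1 = Atom("dna", pur_atom, strand=pur.strand, base=pur.base, residue=pur.residue)
            a2 = Atom("dna", pyr_atom, strand=pyr.strand, base=pyr.base, residue=pyr.residue)
            restraints.append(
                DistanceRestraint(
                    pairs=((a1, a2),),
                    lower=bounds[0],
                    upper1=bounds[1],
                    upper2=bounds[2],
                    force_constant=force_constant,
                    provenance=("WC", f"pair{i}"),
                )
            )
    return restraints


def write_restraints(
    restraints: Sequence[DistanceRestraint],
    format: str = "csv",
    atom_index_map: Mapping[str, int] | None = None,
) -> str:
    """Serialize restraints to the generic CSV or GROMACS itp dialect.

    The itp writer emits a ``[ distance_restraints ]`` block (topology
    indices from ``atom_index_map``, distances in nm, merged pairs
    sharing one restraint ``index``).
    """
    if format == "csv":
        rows = []
        for idx, r in enumerate(restraints, start=1):
            for a1, a2 in r.pairs:
                rows.append(
                    {
                        "index": idx,
                        "atom1": a1.descriptor,
                        "atom2": a2.descriptor,
                        "lower": r.lower,
                        "upper1": r.upper1,
                        "upper2": r.upper2,
                        "force_constant": r.force_constant,
                        "provenance": "|".join(r.provenance),
                    }
                )
        buf = io.StringIO()
        pd.DataFrame(rows).to_csv(buf, index=False)
        return buf.getvalue()

    if format == "gromacs_itp":
        if atom_index_map is None:
            raise ValueError("gromacs_itp output requires an atom_index_map")
        missing = sorted(
            {
                a.descriptor
                for r in restraints
                for pair in r.pairs
                for a in pair
                if a.descriptor not in atom_index_map
            }
        )
        if missing:
            raise AtomMapError(
                f"unmapped atom descriptors: {', '.join(missing)}"
            )
        lines = [
            "[ distance_restraints ]",
            ";  ai    aj  type  index  type'      low      up1      up2      fac",
        ]
        for idx, r in enumerate(restraints, start=1):
            for a1, a2 in r.pairs:
                lines.append(
                    f"{atom_index_map[a1.descriptor]:>5d} "
                    f"{atom_index_map[a2.descriptor]:>5d} "
                    f"    1 {idx:>6d}      1 "
                    f"{r.lower / 10.0:8.3f} {r.upper1 / 10.0:8.3f} "
                    f"{r.upper2 / 10.0:8.3f} {r.force_constant:8.1f}"
                )
        return "\n".join(lines) + "\n"

    raise ValueError(f"unknown format {format!r}")


def parse_restraints_csv(text: str) -> list[DistanceRestraint]:
    """Inverse of the CSV writer (exact round-trip of bounds and atoms)."""
    df = pd.read_csv(io.StringIO(text)).fillna("")
    restraints = []
    for idx, sub in df.groupby("index", sort=True):
        first = sub.iloc[0]
        pairs = tuple(
            (Atom.from_descriptor(r.atom1), Atom.from_descriptor(r.atom2))
            for r in sub.itertuples(index=False)
        )
        provenance = (
            tuple(str(first.provenance).split("|"))
            if str(first.provenance)
            else ()
        )
        restraints.append(
            DistanceRestraint(
                pairs=pairs,
                lower=float(first.lower),
                upper1=float(first.upper1),
                upper2=float(first.upper2),
                force_constant=float(first.force_constant),
                provenance=provenance,
            )
        )
    return restraints


def packaged_noe_table() -> Path:
    """Path to the packaged two-complex NOE contact fixture."""
    return Path(__file__).parent / "data" / "table1.csv"


def packaged_panel() -> Path:
    """Path to the packaged 13-duplex binding-panel fixture."""
    return Path(__file__).parent / "data" / "table2.csv"
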