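"""Conformer-ensemble analysis: superposition, RMSD and Daura clustering.

An MD trajectory of a DNA:ligand complex is summarized as an ordered
set of same-topology frames.  Frames are compared by least-squares
(Kabsch) superposition followed by RMSD over a selectable atom mask —
e.g. only the central residues plus the ligand, so that floppy duplex
termini do not inflate the structural spread.  The Daura (GROMOS)
algorithm then partitions frames greedily: the frame with the most
neighbors within an RMSD cutoff founds a cluster with those neighbors,
the cluster is removed, and the count is repeated on the remainder.
Cluster occupancies (fractions of simulation time) and representative
frames are the primary readout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from Bio.PDB import PDBIO, PDBParser
from Bio.PDB.Atom import Atom as PDBAtom
from Bio.PDB.Chain import Chain
from Bio.PDB.Model import Model
from Bio.PDB.Residue import Residue
from Bio.PDB.Structure import Structure

LIGAND_RESNAME = "LIG"


class GeometryError(ValueError):
    """Superposition attempted on a degenerate atom selection."""


@dataclass(frozen=True)
class AtomInfo:
    """Metadata of one ensemble atom."""

    molecule: str  # "dna" | "ligand"
    strand: str | None  # chain id for DNA ("A"/"B"), None for ligand
    residue: int
    name: str
    base: str = ""

    @property
    def is_hydrogen(self) -> bool:
        # ligand pseudo-protons are labelled LH<n>
        return self.name.lstrip("0123456789L").startswith("H")


@dataclass
class ConformerEnsemble:
    """F frames × N atoms × 3 coordinates (Å) with atom metadata."""

    coords: np.ndarray
    atoms: list[AtomInfo]
    frame_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(f"coords must be (F, N, 3), got {self.coords.shape}")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError(
                f"{self.coords.shape[1]} coordinate rows vs "
                f"{len(self.atoms)} atom records"
            )
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite coordinates")
        if not self.frame_ids:
            self.frame_ids = list(range(self.coords.shape[0]))

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


@dataclass(frozen=True)
class AtomMask:
    """Composable predicate over atom metadata.

    Built from primitives (:meth:`residues`, :meth:`ligand`, ...) or
    parsed from a selection string like ``"resid 3-6 or ligand"``.
    """

    predicate: Callable[[AtomInfo], bool]
    label: str = "custom"

    def apply(self, ensemble: ConformerEnsemble) -> np.ndarray:
        return np.array([self.predicate(a) for a in ensemble.atoms], dtype=bool)

    def indices(self, ensemble: ConformerEnsemble) -> np.ndarray:
        return np.flatnonzero(self.apply(ensemble))

    def __or__(self, other: "AtomMask") -> "AtomMask":
        p1, p2 = self.predicate, other.predicate
        return AtomMask(
            lambda a: p1(a) or p2(a), f"({self.label} or {other.label})"
        )

    def __and__(self, other: "AtomMask") -> "AtomMask":
        p1, p2 = self.predicate, other.predicate
        return AtomMask(
            lambda a: p1(a) and p2(a), f"({self.label} and {other.label})"
        )

    @classmethod
    def all(cls) -> "AtomMask":
        return cls(lambda a: True, "all")

    @classmethod
    def heavy(cls) -> "AtomMask":
        return cls(lambda a: not a.is_hydrogen, "heavy")

    @classmethod
    def ligand(cls) -> "AtomMask":
        return cls(lambda a: a.molecule == "ligand", "ligand")

    @classmethod
    def dna(cls) -> "AtomMask":
        return cls(lambda a: a.molecule == "dna", "dna")

    @classmethod
    def strand(cls, strand: str) -> "AtomMask":
        return cls(
            lambda a: a.molecule == "dna" and a.strand == strand,
            f"strand {strand}",
        )

    @classmethod
    def residues(cls, lo: int, hi: int) -> "AtomMask":
        """DNA residues lo..hi inclusive, on both strands."""
        return cls(
            lambda a: a.molecule == "dna" and lo <= a.residue <= hi,
            f"resid {lo}-{hi}",
        )

    @classmethod
    def parse(cls, expr: str) -> "AtomMask":
        """Parse a selection: or-combination of and-terms over the
        keywords ``all``, ``heavy``, ``dna``, ``ligand``, ``strand X``,
        ``resid a-b``."""

        def parse_atom(tok: str) -> "AtomMask":
            tok = tok.strip().lower()
            if tok == "all":
                return cls.all()
            if tok == "heavy":
                return cls.heavy()
            if tok == "dna":
                return cls.dna()
            if tok == "ligand":
                return cls.ligand()
            m = re.fullmatch(r"strand\s+([ab])", tok)
            if m:
                return cls.strand(m.group(1).upper())
            m = re.fullmatch(r"resid\s+(\d+)(?:\s*-\s*(\d+))?", tok)
            if m:
                lo = int(m.group(1))
                hi = int(m.group(2)) if m.group(2) else lo
                return cls.residues(lo, hi)
            raise ValueError(f"cannot parse mask term {tok!r}")

        terms = []
        for disjunct in re.split(r"\s+or\s+", expr.strip(), flags=re.I):
            atoms = [
                parse_atom(t)
                for t in re.split(r"\s+and\s+", disjunct, flags=re.I)
            ]
            term = atoms[0]
            for a in atoms[1:]:
                term = term & a
            terms.append(term)
        mask = terms[0]
        for t in terms[1:]:
            mask = mask | t
        return AtomMask(mask.predicate, expr.strip())


def _check_selection(x: np.ndarray) -> None:
    if x.shape[0] < 3:
        raise GeometryError(f"superposition needs >= 3 atoms, got {x.shape[0]}")
    centered = x - x.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise GeometryError("selected atoms are collinear")


def kabsch_superpose(
    ref: np.ndarray,
    mov: np.ndarray,
    mask: np.ndarray | None = None,
    score_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mov`` onto ``ref``.

    Returns (rotation, translation, rmsd) with the proper rotation
    (det = +1, reflections forbidden) and translation minimizing the
    RMSD over the fit ``mask``; the reported RMSD is evaluated over
    ``score_mask`` (default: the fit mask) after the fit.
    """
    ref = np.asarray(ref, dtype=float)
    mov = np.asarray(mov, dtype=float)
    if ref.shape != mov.shape:
        raise ValueError("frames must have identical shapes")
    if mask is None:
        mask = np.ones(ref.shape[0], dtype=bool)
    rf, mv = ref[mask], mov[mask]
    _check_selection(rf)
    _check_selection(mv)

    rc, mc = rf.mean(axis=0), mv.mean(axis=0)
    H = (mv - mc).T @ (rf - rc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = rc - R @ mc

    fitted = mov @ R.T + t
    sm = mask if score_mask is None else score_mask
    diff = ref[sm] - fitted[sm]
    rmsd = float(np.sqrt((diff**2).sum() / sm.sum()))
    return R, t, rmsd


def rmsd_matrix(
    ensemble: ConformerEnsemble,
    mask: AtomMask | None = None,
    score_mask: AtomMask | None = None,
) -> np.ndarray:
    """Symmetric F×F matrix of post-fit masked RMSDs."""
    m = (mask or AtomMask.all()).apply(ensemble)
    sm = None if score_mask is None else score_mask.apply(ensemble)
    F = ensemble.n_frames
    out = np.zeros((F, F))
    for i in range(F):
        for j in range(i + 1, F):
            _, _, r = kabsch_superpose(
                ensemble.coords[i], ensemble.coords[j], m, sm
            )
            out[i, j] = out[j, i] = r
    return out


@dataclass(frozen=True)
class Cluster:
    members: tuple[int, ...]  # frame indices, representative first
    representative: int

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class Clustering:
    """Ordered Daura clusters (largest first) over an RMSD matrix."""

    clusters: list[Cluster]
    cutoff: float
    n_frames: int

    @property
    def occupancies(self) -> list[float]:
        return [c.size / self.n_frames for c in self.clusters]

    def labels(self) -> np.ndarray:
        lab = np.empty(self.n_frames, dtype=int)
        for k, c in enumerate(self.clusters):
            lab[list(c.members)] = k
        return lab


def daura_cluster(matrix: np.ndarray, cutoff: float) -> Clustering:
    """Greedy neighbor-count clustering of frames under an RMSD cutoff.

    Each round counts, for every unassigned frame, its unassigned
    neighbors within the cutoff (the frame itself included in the
    cluster); the frame with the most neighbors — ties broken toward
    the lowest frame index — founds a cluster, which is removed.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("square matrix required")
    if np.isnan(matrix).any():
        raise ValueError("NaN in RMSD matrix")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    F = matrix.shape[0]
    unassigned = list(range(F))
    clusters: list[Cluster] = []
    while unassigned:
        best_center, best_members = None, None
        for i in unassigned:
            members = [j for j in unassigned if matrix[i, j] <= cutoff]
            if best_members is None or len(members) > len(best_members):
                best_center, best_members = i, members
        members = sorted(best_members)
        ordered = (best_center, *[m for m in members if m != best_center])
        clusters.append(Cluster(members=ordered, representative=best_center))
        unassigned = [u for u in unassigned if u not in set(members)]
    return Clustering(clusters=clusters, cutoff=cutoff, n_frames=F)


@dataclass
class ClusterSummary:
    occupancy_percent: float
    representative: int
    size: int
    mean_rmsd_to_representative: float
    rescored_mean_rmsd: float | None = None


@dataclass
class ClusterReport:
    clusters: list[ClusterSummary]
    cutoff: float

    @property
    def top_occupancy_percent(self) -> float:
        return self.clusters[0].occupancy_percent


def cluster_report(
    ensemble: ConformerEnsemble,
    clustering: Clustering,
    mask: AtomMask | None = None,
    score_mask: AtomMask | None = None,
) -> ClusterReport:
    """Per-cluster occupancy and within-cluster spread.

    ``score_mask`` optionally re-scores the within-cluster RMSD on a
    second selection (e.g. the central residues plus ligand) so the
    contribution of unrestrained terminal regions can be separated out.
    """
    if clustering.n_frames != ensemble.n_frames:
        raise ValueError("clustering does not match ensemble")
    m = (mask or AtomMask.all()).apply(ensemble)
    sm = None if score_mask is None else score_mask.apply(ensemble)
    summaries = []
    for c in clustering.clusters:
        rep = ensemble.coords[c.representative]
        rmsds, rescored = [], []
        for idx in c.members:
            if idx == c.representative:
                continue
            _, _, r = kabsch_superpose(rep, ensemble.coords[idx], m)
            rmsds.append(r)
            if sm is not None:
                _, _, r2 = kabsch_superpose(rep, ensemble.coords[idx], sm)
                rescored.append(r2)
        summaries.append(
            ClusterSummary(
                occupancy_percent=100.0 * c.size / clustering.n_frames,
                representative=ensemble.frame_ids[c.representative],
                size=c.size,
                mean_rmsd_to_representative=(
                    float(np.mean(rmsds)) if rmsds else 0.0
                ),
                rescored_mean_rmsd=(
                    float(np.mean(rescored)) if rescored else
                    (0.0 if sm is not None else None)
                ),
            )
        )
    return ClusterReport(clusters=summaries, cutoff=clustering.cutoff)


# ---------------------------------------------------------------------------
# Multi-model PDB I/O


def write_multimodel_pdb(ensemble: ConformerEnsemble, path: str | Path) -> None:
    """Write the ensemble as a MODEL/ENDMDL-delimited PDB file.

    DNA strands map to chains A/B; the ligand becomes chain L with
    residue name ``LIG``.
    """
    structure = Structure("ensemble")
    for f in range(ensemble.n_frames):
        model = Model(f, serial_num=f + 1)
        chains: dict[str, Chain] = {}
        residues: dict[tuple[str, int], Residue] = {}
        for a, info in enumerate(ensemble.atoms):
            chain_id = "L" if info.molecule == "ligand" else (info.strand or "A")
            if chain_id not in chains:
                chains[chain_id] = Chain(chain_id)
                model.add(chains[chain_id])
            rkey = (chain_id, info.residue)
            if rkey not in residues:
                resname = (
                    LIGAND_RESNAME
                    if info.molecule == "ligand"
                    else f"D{info.base}" if info.base else "DN"
                )
                res = Residue((" ", info.residue, " "), resname, "")
                residues[rkey] = res
                chains[chain_id].add(res)
            element = "H" if info.is_hydrogen else (info.name[0] or "C")
            atom = PDBAtom(
                info.name,
                ensemble.coords[f, a],
                0.0,
                1.0,
                " ",
                info.name,
                a + 1,
                element=element,
            )
            residues[rkey].add(atom)
        structure.add(model)
    io = PDBIO()
    io.set_structure(structure)
    io.save(str(path))


def read_multimodel_pdb(path: str | Path) -> ConformerEnsemble:
    """Read a MODEL-delimited PDB into an ensemble.

    Chain L (or residue name ``LIG``) is the ligand; other chains are
    DNA strands.  Atom counts and ordering must be consistent across
    models.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("ensemble", str(path))
    frames = []
    atoms_meta: list[AtomInfo] | None = None
    for model in structure:
        coords, meta = [], []
        for chain in model:
            for res in chain:
                is_ligand = (
                    chain.id == "L" or res.get_resname().strip() == LIGAND_RESNAME
                )
                resname = res.get_resname().strip()
                base = resname[-1] if resname.startswith("D") and len(resname) == 2 else ""
                for atom in res:
                    coords.append(atom.get_coord())
                    meta.append(
                        AtomInfo(
                            molecule="ligand" if is_ligand else "dna",
                            strand=None if is_ligand else chain.id,
                            residue=res.get_id()[1],
                            name=atom.get_name(),
                            base=base,
                        )
                    )
        if atoms_meta is None:
            atoms_meta = meta
        elif meta != atoms_meta:
            raise ValueError(
                f"model {model.id}: inconsistent atoms across models"
            )
        frames.append(np.array(coords, dtype=float))
    if not frames:
        raise ValueError(f"no models found in {path}")
    return ConformerEnsemble(coords=np.stack(frames), atoms=atoms_meta)
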