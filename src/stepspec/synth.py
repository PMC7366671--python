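"""Synthetic-data generators for end-to-end pipeline testing.

Each generator emits inputs with the statistical or geometric structure
the corresponding analysis stage assumes, together with the hidden
ground truth, so recovery can be verified without any external data:

* binding panels with planted per-step affinities (the observation
  process behind a titration table);
* NOE contact tables derived from planted ligand positions on an
  idealized B-form helix scaffold (rise 3.4 Å, twist 36°/step);
* free/bound chemical-shift tables with a localized, distance-decaying
  perturbation at a planted intercalation step;
* multi-model conformer ensembles drawn from k planted conformers with
  within-cluster jitter far below the between-cluster separation.

Every generator is deterministic for a fixed seed.  The ensembles are
scrambled by a random rigid motion per frame, so clustering tests
genuinely exercise superposition rather than raw-coordinate proximity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from stepspec.cluster import AtomInfo, ConformerEnsemble
from stepspec.duplex import (
    DuplexSequence,
    StepClass,
    duplex_steps,
    reverse_complement,
    validate_palindrome,
)
from stepspec.inference import AffinityLevel, BindingObservation, predict_stoichiometry

_RNG = np.random.Generator


def _rng(seed: int | _RNG) -> _RNG:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def random_palindrome(length: int, seed: int | _RNG = 0) -> DuplexSequence:
    """Uniformly random self-complementary duplex of even ``length``."""
    if length < 4 or length % 2:
        raise ValueError(f"even length >= 4 required, got {length}")
    rng = _rng(seed)
    half = "".join(rng.choice(list("ACGT"), size=length // 2))
    return validate_palindrome(half + reverse_complement(half), require=True)


# ---------------------------------------------------------------------------
# Binding panels


@dataclass
class PanelSpec:
    """Planted ground truth for a simulated binding panel.

    ``truth`` maps step classes to their true affinity level (classes
    absent from the map do not bind); ``epsilon`` is the probability of
    a ±1-level misclassification of the observed affinity.
    """

    truth: dict[StepClass, AffinityLevel]
    duplexes: list[DuplexSequence]
    epsilon: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.duplexes:
            raise ValueError("at least one duplex required")
        if not 0 <= self.epsilon < 0.5:
            raise ValueError("epsilon must lie in [0, 0.5)")


def simulate_panel(
    spec: PanelSpec,
) -> tuple[list[BindingObservation], dict[StepClass, AffinityLevel]]:
    """Simulate the panel observation process.

    Per duplex the observed affinity is the (noise-perturbed) maximum
    of the true affinities of its step classes.  The binding site is
    disclosed as a direct site only when the maximum is attained by a
    unique step class sitting at the duplex centre — the situation in
    which a single, well-resolved complex makes the site NMR-readable.
    """
    rng = _rng(spec.seed)
    observations = []
    for duplex in spec.duplexes:
        sites, classes = duplex_steps(duplex)
        true_max = max(
            (spec.truth.get(c, AffinityLevel.NONE) for c in classes),
            default=AffinityLevel.NONE,
        )
        level = int(true_max)
        if spec.epsilon and rng.random() < spec.epsilon:
            level += int(rng.choice([-1, 1]))
        level = AffinityLevel(min(max(level, 0), 6))

        winners = {
            c for c in classes
            if spec.truth.get(c, AffinityLevel.NONE) == true_max
        }
        direct: frozenset[StepClass] = frozenset()
        stoich: frozenset[str] = frozenset()
        if level > AffinityLevel.NONE and true_max > AffinityLevel.NONE and len(winners) == 1:
            (winner,) = winners
            central = any(s.central and s.step == winner for s in sites)
            if central:
                direct = frozenset({winner})
            stoich = frozenset(predict_stoichiometry(duplex, winner))
        observations.append(
            BindingObservation(
                duplex=duplex,
                affinity=level,
                direct_sites=direct if level > AffinityLevel.NONE else frozenset(),
                stoichiometry=stoich,
            )
        )
    return observations, dict(spec.truth)


# ---------------------------------------------------------------------------
# Idealized helix scaffold

#: (atom name, radius Å, angular offset deg, z offset Å, heavy?) of the
#: pseudo-atoms placed per residue.  Geometry is schematic: radii and
#: offsets give plausible inter-proton distances, nothing more.
_RESIDUE_ATOMS: list[tuple[str, float, float, float, bool]] = [
    ("P", 8.9, -95.0, -1.0, True),
    ("C1'", 5.8, -70.0, 0.0, True),
    ("H1'", 6.3, -72.0, -0.3, False),
    ("H2'", 6.6, -85.0, -0.8, False),
    ("H2''", 6.9, -78.0, -1.2, False),
    ("H3'", 7.6, -90.0, -0.5, False),
]

_BASE_PROTONS = {
    "A": [("H8", 4.6, -45.0, 0.0), ("H2", 2.0, 10.0, 0.0)],
    "G": [("H8", 4.6, -45.0, 0.0)],
    "T": [("H6", 4.6, -45.0, 0.0), ("CH3", 5.2, -25.0, 0.4)],
    "C": [("H6", 4.6, -45.0, 0.0), ("H5", 5.2, -30.0, 0.2)],
}


@dataclass
class GeometrySpec:
    """Idealized helix plus planted ligand pseudo-atom positions."""

    rise: float = 3.4  # Å per step
    twist: float = 36.0  # deg per step
    ligand_atoms: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    thresholds: tuple[float, float, float] = (3.2, 4.2, 6.0)  # strong/medium/weak
    min_approach: float = 1.8  # Å, closest physically sensible contact
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rise <= 0:
            raise ValueError("rise must be positive")
        t = self.thresholds
        if not t[0] < t[1] < t[2]:
            raise ValueError("thresholds must strictly increase")


def helix_scaffold(
    duplex: DuplexSequence,
    rise: float = 3.4,
    twist: float = 36.0,
    ligand_atoms: dict[str, tuple[float, float, float]] | None = None,
) -> ConformerEnsemble:
    """Single-frame pseudo-atom model of the duplex on an ideal helix.

    Strand B runs antiparallel: its residue j shares the rung of pair
    index L+1-j, rotated across the helix axis.
    """
    L = duplex.length
    atoms: list[AtomInfo] = []
    coords: list[list[float]] = []

    def place(strand: str, residue: int, base: str, rung: int, flip: float) -> None:
        theta0 = math.radians(twist) * (rung - 1)
        z0 = rise * (rung - 1)
        entries = [
            (name, r, phi, dz, heavy)
            for name, r, phi, dz, heavy in _RESIDUE_ATOMS
        ] + [
            (name, r, phi, dz, False)
            for name, r, phi, dz in _BASE_PROTONS[base]
        ]
        for name, r, phi, dz, heavy in entries:
            ang = theta0 + flip * math.radians(phi) + (math.pi if flip < 0 else 0.0)
            coords.append(
                [r * math.cos(ang), r * math.sin(ang), z0 + flip * dz]
            )
            atoms.append(
                AtomInfo(
                    molecule="dna", strand=strand, residue=residue,
                    name=name, base=base,
                )
            )

    for i in range(1, L + 1):
        place("A", i, duplex.top_strand[i - 1], rung=i, flip=1.0)
    for j in range(1, L + 1):
        place("B", j, duplex.bottom_strand[j - 1], rung=L + 1 - j, flip=-1.0)
    for name, xyz in (ligand_atoms or {}).items():
        coords.append(list(xyz))
        atoms.append(AtomInfo(molecule="ligand", strand=None, residue=1, name=name))

    return ConformerEnsemble(
        coords=np.asarray(coords)[None, :, :], atoms=atoms
    )


def default_ligand_atoms(
    duplex: DuplexSequence,
    step_position: int | None = None,
    rise: float = 3.4,
) -> dict[str, tuple[float, float, float]]:
    """Planted aromatic ligand pseudo-atoms inside a step cavity.

    Five ring pseudo-protons spanning the cavity between the base pairs
    of the step at ``step_position`` (default: the central step).
    """
    L = duplex.length
    p = step_position if step_position is not None else L // 2
    z = rise * (p - 0.5)  # mid-plane between rungs p and p+1
    return {
        "LH3": (3.2, -2.0, z),
        "LH4": (3.6, 0.0, z + 0.3),
        "LH7": (-3.0, 2.2, z),
        "LH9": (-3.5, 0.2, z - 0.3),
        "LH10": (-2.5, -1.8, z),
    }


def simulate_noe_table(
    spec: GeometrySpec,
    duplex: DuplexSequence,
    complex_id: str = "SYN",
) -> tuple[pd.DataFrame, list[dict]]:
    """Emit an NOE contact table from planted ligand geometry.

    Every ligand/DNA proton pair closer than the weak threshold yields
    one peak, classified by the distance thresholds.  Returns the table
    (in the same dialect the compiler parses) and the true distances.
    """
    if not spec.ligand_atoms:
        raise ValueError("GeometrySpec.ligand_atoms is empty")
    scaffold = helix_scaffold(
        duplex, spec.rise, spec.twist, ligand_atoms=spec.ligand_atoms
    )
    xyz = scaffold.coords[0]
    dna_protons = [
        (i, a) for i, a in enumerate(scaffold.atoms)
        if a.molecule == "dna" and (a.is_hydrogen or a.name == "CH3")
    ]
    lig = [
        (i, a) for i, a in enumerate(scaffold.atoms) if a.molecule == "ligand"
    ]
    s, m, w = spec.thresholds
    rows, truth = [], []
    no = 0
    for li, la in lig:
        for di, da in dna_protons:
            d = float(np.linalg.norm(xyz[li] - xyz[di]))
            if d > w:
                continue
            if d < spec.min_approach:
                raise ValueError(
                    f"ligand atom {la.name} within {d:.2f} Å of "
                    f"{da.strand}{da.base}{da.residue}{da.name}: "
                    "placement unphysical"
                )
            intensity = "strong" if d <= s else "medium" if d <= m else "weak"
            no += 1
            contact = f"{la.name}{da.strand}-{da.base}{da.residue}{da.name}"
            rows.append(
                {"no": no, "contact": contact, complex_id: intensity}
            )
            truth.append(
                {"contact": contact, "distance": d, "intensity": intensity}
            )
    if not rows:
        import warnings

        warnings.warn("no ligand/DNA proton pair under the weak threshold")
    df = pd.DataFrame(rows, columns=["no", "contact", complex_id])
    return df, truth


# ---------------------------------------------------------------------------
# Chemical shift tables

#: Plausible per-atom-type baseline shifts (ppm).  Values are cosmetic:
#: only shift *differences* matter to perturbation mapping.
_BASELINE_1H = {
    "H1'": 5.9, "H2'": 2.2, "H2''": 2.5, "H3'": 4.8,
    "H6": 7.4, "H8": 8.1, "H2": 7.6, "H5": 5.5, "CH3": 1.4,
}
_BASELINE_31P = {"P": -1.0}


def simulate_shift_tables(
    duplex: DuplexSequence,
    site: int,
    magnitude: float,
    decay: float,
    noise: float,
    seed: int | _RNG = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Free/bound shift tables with a perturbation planted at ``site``.

    The free duplex is dyad-symmetric ("sym" strand).  On binding every
    atom of residue r moves by m·exp(−d(r)/λ) with a random sign plus
    Normal(0, σ) noise, where d(r) is the residue's distance to the
    step residues {site, site+1}; both strands are perturbed with
    independent noise (symmetry broken by complex formation).
    """
    L = duplex.length
    if not 1 <= site <= L - 1:
        raise ValueError(f"site must lie in 1..{L - 1}")
    rng = _rng(seed)

    def residue_atoms(base: str) -> list[tuple[str, str, float]]:
        out = [(a, "1H", ppm) for a, ppm in _BASELINE_1H.items()
               if a in ("H1'", "H2'", "H2''", "H3'")]
        for name, *_ in _BASE_PROTONS[base]:
            out.append((name, "1H", _BASELINE_1H[name]))
        out.append(("P", "31P", _BASELINE_31P["P"]))
        return out

    free_rows, bound_rows = [], []
    for r in range(1, L + 1):
        dist = min(abs(r - site), abs(r - (site + 1)))
        for strand in ("A", "B"):
            base = duplex.base(strand, r)
            for atom, nucleus, ppm in residue_atoms(base):
                if strand == "A":
                    free_rows.append(
                        {"strand": "sym", "residue": r, "atom": atom,
                         "nucleus": nucleus, "ppm": ppm}
                    )
                sign = 1.0 if rng.random() < 0.5 else -1.0
                shift = magnitude * math.exp(-dist / decay) if decay > 0 else (
                    magnitude if dist == 0 else 0.0
                )
                bound_rows.append(
                    {"strand": strand, "residue": r, "atom": atom,
                     "nucleus": nucleus,
                     "ppm": ppm + sign * shift + rng.normal(0.0, noise)}
                )
    return pd.DataFrame(free_rows), pd.DataFrame(bound_rows)


# ---------------------------------------------------------------------------
# Conformer ensembles


def _largest_remainder_counts(weights: np.ndarray, n: int) -> np.ndarray:
    """Deterministic apportionment of n frames proportional to weights."""
    quota = weights * n
    counts = np.floor(quota).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(quota - counts), kind="stable")
    counts[order[:remainder]] += 1
    return counts


def _random_rotation(rng: _RNG) -> np.ndarray:
    """Uniform random rotation via a normalized quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def simulate_ensemble(
    k: int,
    weights: list[float],
    spread: float,
    separation: float,
    n_frames: int,
    scaffold: ConformerEnsemble | None = None,
    seed: int = 0,
) -> tuple[ConformerEnsemble, np.ndarray]:
    """Ensemble of ``n_frames`` drawn from ``k`` planted conformers.

    Conformer 0 is the scaffold; each further conformer adds a fixed
    random deformation field of per-atom RMS amplitude ``separation``.
    Frames get isotropic Gaussian jitter of ``spread`` Å per coordinate
    and an independent random rigid motion, so any clustering recovery
    must superpose first.  Frame counts per conformer follow the
    weights by largest-remainder apportionment, shuffled in time.
    Returns the ensemble and the planted cluster label per frame.
    """
    weights_arr = np.asarray(weights, dtype=float)
    if len(weights_arr) != k or weights_arr.min() < 0 or abs(weights_arr.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be k nonnegative values summing to 1")
    if separation <= 2.0 * math.sqrt(2.0) * spread:
        raise ValueError(
            "separation too small relative to spread: clusters would "
            f"not be separable (need > {2.0 * math.sqrt(2.0) * spread:.3f})"
        )
    rng = np.random.default_rng(seed)
    if scaffold is None:
        duplex = validate_palindrome("CCCTAGGG")
        scaffold = helix_scaffold(
            duplex, ligand_atoms=default_ligand_atoms(duplex)
        )
    base = scaffold.coords[0]
    N = base.shape[0]

    conformers = [base]
    for _ in range(1, k):
        field_ = rng.normal(size=(N, 3))
        field_ *= separation / math.sqrt((field_**2).sum() / N)
        conformers.append(base + field_)

    counts = _largest_remainder_counts(weights_arr, n_frames)
    labels = np.repeat(np.arange(k), counts)
    rng.shuffle(labels)

    frames = np.empty((n_frames, N, 3))
    for f in range(n_frames):
        conf = conformers[labels[f]] + rng.normal(scale=spread, size=(N, 3))
        R = _random_rotation(rng)
        t = rng.uniform(-20.0, 20.0, size=3)
        frames[f] = conf @ R.T + t

    return (
        ConformerEnsemble(coords=frames, atoms=list(scaffold.atoms)),
        labels,
    )
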