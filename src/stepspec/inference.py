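"""Inference of per-step binding verdicts from a duplex binding panel.

An NMR titration panel reports, per palindromic duplex, a relative
affinity of the intercalator, sometimes the directly resolved
intercalation site(s), and the observed duplex:ligand stoichiometry.
Because every duplex exposes several dinucleotide steps at once, single
observations are ambiguous; the engine combines the whole panel:

* **exclusion** — a duplex with no detectable intercalation rules out
  every step it contains, at all affinity levels;
* **direct / unique attribution** — a resolved site, or a positive
  duplex whose only non-excluded step is one candidate, establishes a
  binder;
* **dominant attribution** — a positive duplex containing an already
  established binder is attributed to the strongest such binder, giving
  no verdict (positive or negative) on its co-present steps.

The result is a three-way partition of the 10 step classes into
binders (with an ordinal affinity estimate), excluded steps, and steps
the panel cannot settle.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from stepspec.duplex import (
    DuplexSequence,
    StepClass,
    duplex_steps,
    enumerate_step_classes,
    sites_of,
    validate_palindrome,
)


class InconsistencyError(ValueError):
    """A positive observation is left with no candidate binding step."""


class ContradictionError(ValueError):
    """A step is simultaneously established as binder and excluded."""


class AffinityLevel(enum.IntEnum):
    """Ordinal relative-affinity scale used by the titration readout."""

    NONE = 0
    VERY_WEAK = 1
    WEAK = 2
    MEDIUM = 3
    MEDIUM_STRONG = 4
    STRONG = 5
    VERY_STRONG = 6

    @classmethod
    def parse(cls, label: str) -> "AffinityLevel":
        key = label.strip().lower().replace("-", "_").replace(" ", "_")
        try:
            return cls[key.upper()]
        except KeyError:
            raise ValueError(f"unknown affinity level {label!r}") from None

    @property
    def label(self) -> str:
        return self.name.lower().replace("_", "-")


#: Verdict states.
BINDER = "binder"
EXCLUDED = "excluded"
UNDETERMINED = "undetermined"

#: Confidence tags, strongest first.
DIRECT = "direct"
UNIQUE = "unique_attribution"
DOMINANT = "dominant_attribution"


@dataclass(frozen=True)
class Evidence:
    rule: str
    duplex: str
    level: AffinityLevel


@dataclass(frozen=True)
class BindingObservation:
    """One duplex's panel readout."""

    duplex: DuplexSequence
    affinity: AffinityLevel
    direct_sites: frozenset[StepClass] = frozenset()
    stoichiometry: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        _, classes = duplex_steps(self.duplex)
        if not self.direct_sites <= classes:
            extra = {s.display_name for s in self.direct_sites - classes}
            raise ValueError(
                f"{self.duplex.codename or self.duplex.top_strand}: direct "
                f"sites {sorted(extra)} absent from duplex"
            )
        if self.direct_sites and self.affinity == AffinityLevel.NONE:
            raise ValueError(
                f"{self.duplex.codename}: direct sites with zero affinity"
            )
        bad = self.stoichiometry - {"1:1", "1:2"}
        if bad:
            raise ValueError(f"unknown stoichiometry {sorted(bad)}")

    @property
    def step_classes(self) -> set[StepClass]:
        return duplex_steps(self.duplex)[1]


@dataclass
class StepKnowledge:
    """Per-step verdict table accumulated over a panel."""

    status: dict[StepClass, str] = field(default_factory=dict)
    affinity_estimate: dict[StepClass, AffinityLevel] = field(default_factory=dict)
    confidence: dict[StepClass, str] = field(default_factory=dict)
    evidence: dict[StepClass, list[Evidence]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for step in enumerate_step_classes():
            self.status.setdefault(step, UNDETERMINED)
            self.evidence.setdefault(step, [])

    def binders(self) -> set[StepClass]:
        return {s for s, v in self.status.items() if v == BINDER}

    def excluded(self) -> set[StepClass]:
        return {s for s, v in self.status.items() if v == EXCLUDED}

    def undetermined(self) -> set[StepClass]:
        return {s for s, v in self.status.items() if v == UNDETERMINED}

    def ranking(self) -> list[StepClass]:
        """Binders ordered by decreasing affinity estimate."""
        return sorted(
            self.binders(),
            key=lambda s: (-self.affinity_estimate[s], s.canonical_id),
        )

    def _mark_excluded(self, step: StepClass, duplex: str) -> None:
        if self.status[step] == BINDER:
            raise ContradictionError(
                f"step {step.display_name} both binder and excluded "
                f"(exclusion from {duplex})"
            )
        self.status[step] = EXCLUDED
        self.evidence[step].append(Evidence("exclusion", duplex, AffinityLevel.NONE))

    def _mark_binder(
        self,
        step: StepClass,
        level: AffinityLevel,
        confidence: str,
        duplex: str,
        rule: str,
    ) -> None:
        if self.status[step] == EXCLUDED:
            raise ContradictionError(
                f"step {step.display_name} both excluded and attributed "
                f"as binder by {duplex}"
            )
        self.status[step] = BINDER
        current = self.affinity_estimate.get(step, AffinityLevel.NONE)
        self.affinity_estimate[step] = max(current, level)
        order = [DIRECT, UNIQUE, DOMINANT]
        prev = self.confidence.get(step)
        if prev is None or order.index(confidence) < order.index(prev):
            self.confidence[step] = confidence
        self.evidence[step].append(Evidence(rule, duplex, level))

    def to_dict(self) -> dict:
        out = {}
        for step in sorted(self.status, key=lambda s: s.canonical_id):
            entry: dict = {"status": self.status[step]}
            if self.status[step] == BINDER:
                entry["affinity"] = self.affinity_estimate[step].label
                entry["confidence"] = self.confidence[step]
            entry["evidence"] = [
                {"rule": e.rule, "duplex": e.duplex, "level": e.level.label}
                for e in self.evidence[step]
            ]
            out[step.display_name] = entry
        return out

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def apply_exclusion(observations: Sequence[BindingObservation]) -> set[StepClass]:
    """Union of step classes of all zero-affinity duplexes."""
    excluded: set[StepClass] = set()
    for obs in observations:
        if obs.affinity == AffinityLevel.NONE:
            excluded |= obs.step_classes
    return excluded


def attribute_binding(
    observation: BindingObservation, knowledge: StepKnowledge
) -> tuple[frozenset[StepClass], str] | None:
    """Attribute one positive observation against current knowledge.

    Returns the attributed step(s) with a confidence tag, or ``None``
    when the observation cannot (yet) be resolved.
    """
    if observation.affinity == AffinityLevel.NONE:
        raise ValueError("attribution requires a positive observation")
    name = observation.duplex.codename or observation.duplex.top_strand
    candidates = observation.step_classes - knowledge.excluded()
    if not candidates:
        raise InconsistencyError(
            f"{name}: positive affinity but every contained step is excluded"
        )
    if observation.direct_sites:
        return observation.direct_sites, DIRECT
    if len(candidates) == 1:
        return frozenset(candidates), UNIQUE
    known = candidates & knowledge.binders()
    if known:
        best = max(
            known,
            key=lambda s: (
                knowledge.affinity_estimate.get(s, AffinityLevel.NONE),
                # reversed-id tiebreak so max() picks the smaller canonical_id
                tuple(-ord(c) for c in s.canonical_id),
            ),
        )
        return frozenset({best}), DOMINANT
    return None


def infer_preferences(
    observations: Sequence[BindingObservation],
) -> StepKnowledge:
    """Fixpoint inference over a whole panel.

    Exclusions are applied first, then direct and unique attributions,
    then dominant attributions iterated to a fixpoint.  The dominant
    phase is evaluated against a snapshot of the affinity estimates in
    each round (rather than in panel order), so the result is
    independent of the ordering of the observation list.
    """
    if not observations:
        raise ValueError("at least one observation required")
    knowledge = StepKnowledge()

    for obs in observations:
        name = obs.duplex.codename or obs.duplex.top_strand
        for step in sorted(
            obs.step_classes if obs.affinity == AffinityLevel.NONE else (),
            key=lambda s: s.canonical_id,
        ):
            if knowledge.status[step] != EXCLUDED:
                knowledge._mark_excluded(step, name)

    positives = sorted(
        (o for o in observations if o.affinity > AffinityLevel.NONE),
        key=lambda o: o.duplex.codename or o.duplex.top_strand,
    )

    # Direct + unique attributions: neither depends on other verdicts
    # (the exclusion set is already final), so one pass is stable.
    pending: list[BindingObservation] = []
    for obs in positives:
        name = obs.duplex.codename or obs.duplex.top_strand
        result = attribute_binding(obs, knowledge)
        if result is None or result[1] == DOMINANT:
            pending.append(obs)
            continue
        steps, conf = result
        rule = "direct_site" if conf == DIRECT else "unique_candidate"
        for step in sorted(steps, key=lambda s: s.canonical_id):
            knowledge._mark_binder(step, obs.affinity, conf, name, rule)

    # Dominant attributions, Jacobi-style: each round resolves every
    # pending observation against the same estimate snapshot, then all
    # resulting maxima are applied at once.  Estimates only increase, so
    # the iteration terminates; the binder set never changes here.
    while True:
        snapshot = dict(knowledge.affinity_estimate)
        assignments: list[tuple[BindingObservation, StepClass]] = []
        for obs in pending:
            result = attribute_binding(obs, knowledge)
            if result is not None:
                (step,) = result[0]
                assignments.append((obs, step))
        new_estimates = dict(snapshot)
        for obs, step in assignments:
            new_estimates[step] = max(
                new_estimates.get(step, AffinityLevel.NONE), obs.affinity
            )
        if new_estimates == snapshot:
            for obs, step in assignments:
                name = obs.duplex.codename or obs.duplex.top_strand
                knowledge._mark_binder(
                    step, obs.affinity, DOMINANT, name, "dominant_binder"
                )
            break
        knowledge.affinity_estimate.update(new_estimates)

    return knowledge


def predict_stoichiometry(
    duplex: DuplexSequence,
    step: StepClass,
    min_gap: int = 2,
) -> set[str]:
    """Admissible duplex:ligand ratios for intercalation at ``step``.

    A central singleton site admits a single ligand.  A dyad-related
    pair of sites admits double occupancy when the two cavities do not
    overlap and are at least ``min_gap`` steps apart (a neighbor-
    exclusion-like spacing).
    """
    orbits = sites_of(duplex, step)
    if not orbits:
        raise ValueError(
            f"step {step.display_name} absent from "
            f"{duplex.codename or duplex.top_strand}"
        )
    admissible = {"1:1"}
    for orbit in orbits:
        if len(orbit) == 2:
            p1, p2 = sorted(s.position for s in orbit)
            if p2 - p1 >= max(2, min_gap):
                admissible.add("1:2")
    return admissible


def predict_spectral_forms(
    duplex: DuplexSequence, step: StepClass
) -> dict[int, int]:
    """Distinguishable bound NMR species per site of ``step``.

    At the centre of a palindrome the ligand's two ring orientations
    ('up'/'down') are dyad-equivalent, collapsing to a single form; any
    off-centre site yields two.  Only palindromic duplexes have the
    symmetry this argument relies on.
    """
    if not duplex.palindromic:
        raise ValueError(
            "spectral-form counting requires a palindromic duplex"
        )
    orbits = sites_of(duplex, step)
    if not orbits:
        raise ValueError(
            f"step {step.display_name} absent from "
            f"{duplex.codename or duplex.top_strand}"
        )
    return {
        site.position: 1 if site.central else 2
        for orbit in orbits
        for site in orbit
    }


def read_observations(path: str | Path) -> list[BindingObservation]:
    """Load a panel CSV (codename, sequence, affinity, direct_sites,
    stoichiometry; extra columns ignored)."""
    df = pd.read_csv(path, dtype=str).fillna("")
    observations = []
    for row in df.itertuples(index=False):
        duplex = validate_palindrome(row.sequence, codename=row.codename)
        direct = frozenset(
            StepClass.parse(tok)
            for tok in getattr(row, "direct_sites", "").split(";")
            if tok.strip()
        )
        stoich = frozenset(
            tok.strip()
            for tok in getattr(row, "stoichiometry", "").split(";")
            if tok.strip()
        )
        observations.append(
            BindingObservation(
                duplex=duplex,
                affinity=AffinityLevel.parse(row.affinity or "none"),
                direct_sites=direct,
                stoichiometry=stoich,
            )
        )
    return observations


def write_observations(
    observations: Iterable[BindingObservation], path: str | Path
) -> None:
    rows = []
    for obs in observations:
        rows.append(
            {
                "codename": obs.duplex.codename,
                "sequence": obs.duplex.top_strand,
                "affinity": obs.affinity.label,
                "direct_sites": ";".join(
                    sorted(s.display_name for s in obs.direct_sites)
                ),
                "stoichiometry": ";".join(sorted(obs.stoichiometry)),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
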