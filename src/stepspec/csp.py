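"""Chemical-shift perturbation (Δδ) mapping of intercalation sites.

Intercalation perturbs the magnetic environment of the nucleotides
flanking the binding cavity, so resonances of those residues shift
most upon complex formation, while remote residues move little.
Comparing the assignments of the free duplex with those of the complex
therefore localizes the binding step without any structural model.

Δδ is computed as bound − free (downfield positive); ¹H and ³¹P
channels are handled independently and never mixed in one aggregate.
The free duplex is dyad-symmetric, so its table may carry a single
"sym" strand whose records match both strands of the complex (ligand
binding breaks the symmetry and doubles the resonances).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

_KEY = ["strand", "residue", "atom", "nucleus"]
_MATCH_KEY = ["residue", "atom", "nucleus"]


class EmptyProfileError(ValueError):
    """Free and bound tables share no assignment keys."""


def validate_shift_table(df: pd.DataFrame, name: str = "table") -> pd.DataFrame:
    """Check a shift table: required columns, unique keys, finite ppm."""
    required = set(_KEY + ["ppm"])
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{name}: missing columns {sorted(missing)}")
    df = df.copy()
    df["residue"] = df["residue"].astype(int)
    df["ppm"] = df["ppm"].astype(float)
    if not np.isfinite(df["ppm"]).all():
        raise ValueError(f"{name}: non-finite chemical shifts")
    if df.duplicated(_KEY).any():
        dup = df[df.duplicated(_KEY, keep=False)].head(3)
        raise ValueError(f"{name}: duplicate assignment keys\n{dup}")
    return df


def read_shift_table(path: str | Path) -> pd.DataFrame:
    """Load a shift CSV (strand, residue, atom, nucleus, ppm)."""
    return validate_shift_table(pd.read_csv(path), str(path))


@dataclass
class CspProfile:
    """Per-atom Δδ with bookkeeping of unmatched assignments."""

    data: pd.DataFrame  # strand, residue, atom, nucleus, delta, abs_delta
    unmatched_bound: pd.DataFrame = field(default_factory=pd.DataFrame)
    unmatched_free: pd.DataFrame = field(default_factory=pd.DataFrame)

    def channel(self, nucleus: str) -> pd.DataFrame:
        return self.data[self.data["nucleus"] == nucleus]

    def residue_aggregate(
        self, nucleus: str = "1H", how: str = "max"
    ) -> pd.DataFrame:
        """Per (strand, residue) aggregate of |Δδ| on one channel."""
        sub = self.channel(nucleus)
        if sub.empty:
            raise EmptyProfileError(f"no Δδ entries on channel {nucleus!r}")
        agg = getattr(sub.groupby(["strand", "residue"])["abs_delta"], how)()
        return agg.reset_index(name="aggregate")


@dataclass
class SiteRanking:
    """Step positions ranked by descending perturbation score."""

    scores: list[tuple[int, float]]  # (position, score), best first
    ambiguous: bool

    @property
    def top(self) -> int:
        return self.scores[0][0]


def compute_csp(free: pd.DataFrame, bound: pd.DataFrame) -> CspProfile:
    """Δδ = δ(bound) − δ(free), matched on (residue, atom, nucleus).

    "sym" records in the free table match both bound strands; strand-
    resolved free records match their own strand only.  Atoms present
    in only one table are reported as unmatched, never imputed.
    """
    free = validate_shift_table(free, "free")
    bound = validate_shift_table(bound, "bound")

    sym = free[free["strand"] == "sym"]
    resolved = free[free["strand"] != "sym"]
    parts = []
    if not sym.empty:
        parts.append(
            bound.merge(
                sym[_MATCH_KEY + ["ppm"]],
                on=_MATCH_KEY,
                suffixes=("_bound", "_free"),
            )
        )
    if not resolved.empty:
        parts.append(
            bound.merge(
                resolved[_KEY + ["ppm"]],
                on=_KEY,
                suffixes=("_bound", "_free"),
            )
        )
    merged = (
        pd.concat(parts, ignore_index=True)
        if parts
        else pd.DataFrame(columns=_KEY + ["ppm_bound", "ppm_free"])
    )
    if merged.empty:
        raise EmptyProfileError("free and bound tables share no keys")
    merged = merged.drop_duplicates(_KEY)
    merged["delta"] = merged["ppm_bound"] - merged["ppm_free"]
    merged["abs_delta"] = merged["delta"].abs()

    matched_bound = merged[_KEY]
    unmatched_bound = bound.merge(
        matched_bound, on=_KEY, how="left", indicator=True
    )
    unmatched_bound = unmatched_bound[unmatched_bound["_merge"] == "left_only"]
    matched_free_keys = merged[_MATCH_KEY].drop_duplicates()
    unmatched_free = free.merge(
        matched_free_keys, on=_MATCH_KEY, how="left", indicator=True
    )
    unmatched_free = unmatched_free[unmatched_free["_merge"] == "left_only"]

    return CspProfile(
        data=merged[_KEY + ["delta", "abs_delta"]].reset_index(drop=True),
        unmatched_bound=unmatched_bound.drop(columns="_merge").reset_index(drop=True),
        unmatched_free=unmatched_free.drop(columns="_merge").reset_index(drop=True),
    )


def localize_site(
    profile: CspProfile,
    channel: str = "1H",
    aggregate: str = "max",
    length: int | None = None,
) -> SiteRanking:
    """Rank candidate step positions by perturbation score.

    score(p) = mean per-residue aggregate over residues {p, p+1} on
    both strands.  Ties are broken toward the central position and the
    ranking is flagged ambiguous when the top two scores coincide.
    """
    agg = profile.residue_aggregate(channel, aggregate)
    by_res = agg.groupby("residue")["aggregate"].mean()
    L = length if length is not None else int(by_res.index.max())
    center = (L) / 2.0
    scores = []
    for p in range(1, L):
        vals = [by_res.get(p), by_res.get(p + 1)]
        vals = [v for v in vals if v is not None and not np.isnan(v)]
        scores.append((p, float(np.mean(vals)) if vals else 0.0))
    scores.sort(key=lambda t: (-t[1], abs(t[0] - center), t[0]))
    ambiguous = len(scores) > 1 and scores[0][1] - scores[1][1] <= 1e-12
    return SiteRanking(scores=scores, ambiguous=ambiguous)
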