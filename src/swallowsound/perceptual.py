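"""Perceptual clinical rating schema for cervical auscultation.

Two trained raters listen to a 2-minute feeding recording and rate, for
each neonate, a closed inventory of pre-swallow breath sounds, during-swallow
sounds and post-swallow breath sounds as yes / no / cannot_be_determined.
A parameter is "present" if demonstrated on at least one swallow in the
file; during-swallow parameters rated present also carry a consistency flag
(present in strictly more than 80% of swallows).  Disagreements between the
two raters are resolved to a consensus profile, and each consensus profile
is classified as having a coordinated or uncoordinated swallow pattern by
an explicit rule over the bolus transit sound (BTS), the glottal release
sound (GRS) and the post-swallow breath sounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Phase",
    "RatingValue",
    "Coordination",
    "BREATH_SOUNDS",
    "SWALLOW_SOUNDS",
    "PARAMETER_INVENTORY",
    "ADVENTITIOUS_POST_SOUNDS",
    "Rating",
    "PerceptualProfile",
    "presence_from_swallows",
    "classify_coordination",
    "consensus",
    "cohort_presence_table",
    "coordination_summary",
    "read_ratings",
    "write_ratings",
    "profiles_from_table",
    "round_percent",
]


class Phase(str, Enum):
    PRE = "pre"
    DURING = "during"
    POST = "post"


class RatingValue(str, Enum):
    YES = "yes"
    NO = "no"
    CANNOT_BE_DETERMINED = "cannot_be_determined"


class Coordination(str, Enum):
    COORDINATED = "coordinated"
    UNCOORDINATED = "uncoordinated"
    UNDETERMINED = "undetermined"


# Breath-sound inventory rated both pre- and post-swallow.
BREATH_SOUNDS: tuple[str, ...] = (
    "normal_breathing",
    "wet_breathing",
    "rattly_chest",
    "grunting",
    "crackles",
    "stridor",
    "wheeze",
    "throat_clearing",
    "coughing",
)

# During-swallow sound descriptors (IDS-BTS-FDS-GRS sequence plus quality).
SWALLOW_SOUNDS: tuple[str, ...] = (
    "crisp_clear",
    "quick",
    "loud",
    "initial_discrete_sound",
    "bolus_transit_sound",
    "final_discrete_sound",
    "glottal_release_sound",
)

PARAMETER_INVENTORY: dict[Phase, tuple[str, ...]] = {
    Phase.PRE: BREATH_SOUNDS,
    Phase.DURING: SWALLOW_SOUNDS,
    Phase.POST: BREATH_SOUNDS,
}

# Post-swallow sounds that, together with a glottal release sound, mark an
# uncoordinated swallow.  Grunting is breath effort, not airway residue, and
# is deliberately excluded.
ADVENTITIOUS_POST_SOUNDS: tuple[str, ...] = (
    "wet_breathing",
    "rattly_chest",
    "coughing",
    "wheeze",
    "crackles",
    "throat_clearing",
    "stridor",
)


def _check_parameter(phase: Phase, name: str) -> None:
    if name not in PARAMETER_INVENTORY[phase]:
        raise ValueError(
            f"unknown {phase.value}-swallow parameter {name!r}; inventory is "
            f"closed: {PARAMETER_INVENTORY[phase]}"
        )


@dataclass(frozen=True)
class Rating:
    """Nominal rating; ``consistent`` only for during-swallow yes ratings."""

    value: RatingValue
    consistent: bool | None = None

    def __post_init__(self) -> None:
        if self.consistent is not None and self.value is not RatingValue.YES:
            raise ValueError("consistency flag requires a 'yes' rating")


@dataclass(frozen=True)
class PerceptualProfile:
    """One rater's (or the consensus) ratings for one neonate."""

    neonate_id: str
    rater_id: str
    ratings: Mapping[tuple[Phase, str], Rating]

    def __post_init__(self) -> None:
        for (phase, name), rating in self.ratings.items():
            _check_parameter(phase, name)
            if rating.consistent is not None and phase is not Phase.DURING:
                raise ValueError(
                    f"consistency flag on {phase.value} parameter {name!r}"
                )

    def get(self, phase: Phase, name: str) -> Rating:
        _check_parameter(phase, name)
        return self.ratings.get(
            (phase, name), Rating(RatingValue.CANNOT_BE_DETERMINED)
        )


def presence_from_swallows(present: Sequence[bool]) -> Rating:
    """Collapse per-swallow presence into one file-level rating.

    Present (yes) if the parameter was demonstrated on at least one swallow;
    consistent if demonstrated in strictly more than 80% of all swallows in
    the file (the 0.80 boundary itself is not consistent).
    """
    if len(present) == 0:
        raise ValueError("presence vector must cover at least one swallow")
    n_true = sum(bool(b) for b in present)
    if n_true == 0:
        return Rating(RatingValue.NO)
    return Rating(RatingValue.YES, consistent=n_true / len(present) > 0.80)


# three-valued helpers: True / False / None (= cannot be determined)

def _tv(rating: Rating) -> bool | None:
    if rating.value is RatingValue.CANNOT_BE_DETERMINED:
        return None
    return rating.value is RatingValue.YES


def _tv_and(a: bool | None, b: bool | None) -> bool | None:
    if a is False or b is False:
        return False
    if a is None or b is None:
        return None
    return True


def _tv_or(a: bool | None, b: bool | None) -> bool | None:
    if a is True or b is True:
        return True
    if a is None or b is None:
        return None
    return False


def _tv_not(a: bool | None) -> bool | None:
    return None if a is None else not a


def classify_coordination(profile: PerceptualProfile) -> Coordination:
    """Rule-based coordinated / uncoordinated classification.

    Uncoordinated if either sufficient condition holds:

    * a bolus transit sound with an absence of normal breathing
      post-swallow, or
    * a glottal release sound plus at least one adventitious post-swallow
      sound (wet breathing, rattly chest, cough, wheeze, crackles, throat
      clearing, stridor).

    Otherwise coordinated if a bolus transit sound is present and either
    normal breathing returns post-swallow or the pre- and post-swallow
    breath-sound profiles are identical.  Uncoordinated takes precedence
    when both rules fire.  Ratings of cannot_be_determined propagate as
    unknowns (Kleene logic); if neither rule can be decided the result is
    undetermined.
    """
    bts = _tv(profile.get(Phase.DURING, "bolus_transit_sound"))
    grs = _tv(profile.get(Phase.DURING, "glottal_release_sound"))
    post_normal = _tv(profile.get(Phase.POST, "normal_breathing"))

    adventitious: bool | None = False
    for name in ADVENTITIOUS_POST_SOUNDS:
        adventitious = _tv_or(adventitious, _tv(profile.get(Phase.POST, name)))

    uncoordinated = _tv_or(
        _tv_and(bts, _tv_not(post_normal)),
        _tv_and(grs, adventitious),
    )
    if uncoordinated is True:
        return Coordination.UNCOORDINATED

    unchanged: bool | None = True
    for name in BREATH_SOUNDS:
        pre_v = _tv(profile.get(Phase.PRE, name))
        post_v = _tv(profile.get(Phase.POST, name))
        if pre_v is None or post_v is None:
            unchanged = _tv_and(unchanged, None)
        else:
            unchanged = _tv_and(unchanged, pre_v == post_v)

    coordinated = _tv_and(bts, _tv_or(post_normal, unchanged))
    if uncoordinated is False and coordinated is True:
        return Coordination.COORDINATED
    return Coordination.UNDETERMINED


def consensus(
    rater_a: PerceptualProfile,
    rater_b: PerceptualProfile,
    resolutions: Mapping[tuple[Phase, str], Rating] | None = None,
) -> PerceptualProfile:
    """Merge two raters' profiles; disagreements must carry a resolution."""
    if rater_a.neonate_id != rater_b.neonate_id:
        raise ValueError(
            f"profiles rate different neonates: {rater_a.neonate_id!r} vs "
            f"{rater_b.neonate_id!r}"
        )
    resolutions = dict(resolutions or {})
    keys = set(rater_a.ratings) | set(rater_b.ratings)
    merged: dict[tuple[Phase, str], Rating] = {}
    unresolved = []
    for key in keys:
        ra, rb = rater_a.ratings.get(key), rater_b.ratings.get(key)
        if ra == rb:
            merged[key] = ra
        elif key in resolutions:
            merged[key] = resolutions[key]
        else:
            unresolved.append(key)
    if unresolved:
        names = ", ".join(f"{p.value}:{n}" for p, n in sorted(unresolved))
        raise ValueError(f"unresolved rater disagreement on: {names}")
    return PerceptualProfile(
        neonate_id=rater_a.neonate_id, rater_id="consensus", ratings=merged
    )


def round_percent(numerator: int, denominator: int) -> float:
    """Percentage rounded half-up to one decimal (cohort-table style)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    pct = Decimal(100 * numerator) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def cohort_presence_table(
    profiles: Iterable[PerceptualProfile],
) -> pd.DataFrame:
    """Per-parameter presence counts across a cohort of consensus profiles.

    The denominator for each parameter excludes neonates whose rating is
    cannot_be_determined (available-case denominators).
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("need at least one profile")
    rows = []
    for phase, names in PARAMETER_INVENTORY.items():
        for name in names:
            ratings = [p.get(phase, name) for p in profiles]
            rateable = [r for r in ratings
                        if r.value is not RatingValue.CANNOT_BE_DETERMINED]
            n_present = sum(r.value is RatingValue.YES for r in rateable)
            n_rateable = len(rateable)
            rows.append({
                "phase": phase.value,
                "parameter": name,
                "n_present": n_present,
                "n_rateable": n_rateable,
                "percent": (round_percent(n_present, n_rateable)
                            if n_rateable else float("nan")),
            })
    return pd.DataFrame(rows)


def coordination_summary(
    profiles: Iterable[PerceptualProfile],
) -> pd.DataFrame:
    """Coordinated / uncoordinated counts via :func:`classify_coordination`."""
    classes = [classify_coordination(p) for p in profiles]
    n = len(classes)
    rows = []
    for cls in (Coordination.COORDINATED, Coordination.UNCOORDINATED,
                Coordination.UNDETERMINED):
        count = sum(c is cls for c in classes)
        rows.append({
            "class": cls.value,
            "n": count,
            "percent": round_percent(count, n) if n else float("nan"),
        })
    return pd.DataFrame(rows)


RATINGS_COLUMNS = ["neonate_id", "rater_id", "phase", "parameter", "value",
                   "consistent"]


def write_ratings(path: str | Path,
                  profiles: Iterable[PerceptualProfile]) -> None:
    """Write profiles as the long-format ratings CSV."""
    rows = []
    for p in profiles:
        for (phase, name), rating in sorted(
            p.ratings.items(), key=lambda kv: (kv[0][0].value, kv[0][1])
        ):
            rows.append({
                "neonate_id": p.neonate_id,
                "rater_id": p.rater_id,
                "phase": phase.value,
                "parameter": name,
                "value": rating.value.value,
                "consistent": ("" if rating.consistent is None
                               else ("yes" if rating.consistent else "no")),
            })
    pd.DataFrame(rows, columns=RATINGS_COLUMNS).to_csv(path, index=False)


def read_ratings(path: str | Path) -> pd.DataFrame:
    """Read the long-format ratings CSV, validating against the inventory."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in RATINGS_COLUMNS if c not in df.columns and
               c != "consistent"]
    if missing:
        raise ValueError(f"{path}: ratings CSV missing columns {missing}")
    for i, row in df.iterrows():
        try:
            _check_parameter(Phase(row["phase"]), row["parameter"])
            RatingValue(row["value"])
        except ValueError as exc:
            raise ValueError(f"{path}: row {i}: {exc}") from exc
    return df


def profiles_from_table(df: pd.DataFrame) -> list[PerceptualProfile]:
    """Group a long-format ratings table into per-(neonate, rater) profiles."""
    profiles = []
    for (neonate, rater), grp in df.groupby(["neonate_id", "rater_id"],
                                            sort=True):
        ratings = {}
        for _, row in grp.iterrows():
            consistent = None
            raw = str(row.get("consistent", "") or "")
            if raw in ("yes", "no"):
                consistent = raw == "yes"
            ratings[(Phase(row["phase"]), row["parameter"])] = Rating(
                RatingValue(row["value"]), consistent
            )
        profiles.append(PerceptualProfile(str(neonate), str(rater), ratings))
    return profiles
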