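"""Modified dictator-game trial schedule.

Each trial offers a choice between a *reference* allocation (shown first)
and an *alternative* allocation (revealed later) of tokens between the
decider ("self") and a passive receiver ("other").  Trials come in two
inequality contexts:

* ``DIS`` (disadvantageous): self gets fewer tokens than other in both
  options;
* ``ADV`` (advantageous): self gets more tokens than other in both options.

The full schedule holds 416 trials: 2 contexts x 4 reference levels x 26
alternative levels x 2 trial sets, where trial set 2 repeats set 1 with a
random per-payoff jitter of -1/0/+1.  For every reference, 13 alternatives
reduce the self/other payoff gap ("more equal") and 13 widen it.  Payoff
changes from reference to alternative span -19..+19 tokens per party.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PayoffPair",
    "Trial",
    "TrialDesign",
    "REFERENCES_DIS",
    "REFERENCES_ADV",
    "DEFAULT_OFFSETS_DIS",
    "generate_schedule",
    "classify_equal_unequal",
    "payoff_changes",
    "equal_unequal_diffs",
]

CONTEXTS = ("DIS", "ADV")

#: Reference allocations (self, other) in the disadvantageous context.
REFERENCES_DIS = ((24, 74), (24, 98), (46, 74), (46, 98))
#: Advantageous references mirror the DIS ones (self and other swapped).
REFERENCES_ADV = tuple((o, s) for s, o in REFERENCES_DIS)

# 26 alternative offsets (d_self, d_other) added to a DIS reference.  The
# first 13 reduce |self - other| ("more equal"), the last 13 increase it.
# The gap change d_other - d_self stays within +/-27 so that even the
# narrowest reference gap (46/74 -> 28 tokens) never flips sign (context
# purity).  Two offsets per half move both payoffs in the same direction
# (dominating / dominated alternatives).  ADV offsets are the negation.
_MORE_EQUAL_DIS = (
    (2, -2), (5, -4), (8, -6), (11, -8), (14, -10), (19, -8), (16, -11),
    (9, 3), (-3, -9), (1, -19), (5, -19), (0, -16), (0, -19),
)
_MORE_UNEQUAL_DIS = (
    (-2, 2), (-5, 4), (-8, 6), (-11, 8), (-14, 10), (-19, 8), (-16, 11),
    (-9, -3), (3, 9), (-1, 19), (-5, 19), (0, 16), (0, 19),
)
DEFAULT_OFFSETS_DIS = _MORE_EQUAL_DIS + _MORE_UNEQUAL_DIS

_MAX_DELTA = 19


@dataclass(frozen=True)
class PayoffPair:
    """Token allocation (self, other); inequality is the absolute gap."""

    self_tokens: int
    other_tokens: int

    def __post_init__(self) -> None:
        if self.self_tokens < 0 or self.other_tokens < 0:
            raise ValueError("token amounts must be non-negative")

    @property
    def inequality(self) -> int:
        return abs(self.self_tokens - self.other_tokens)


@dataclass(frozen=True)
class Trial:
    context: str
    reference: PayoffPair
    alternative: PayoffPair
    trial_set: int = 1
    side_of_reference: str = "left"

    @property
    def delta_self(self) -> int:
        return self.alternative.self_tokens - self.reference.self_tokens

    @property
    def delta_other(self) -> int:
        return self.alternative.other_tokens - self.reference.other_tokens

    @property
    def equal_option(self) -> str:
        return classify_equal_unequal(self.reference, self.alternative)


def classify_equal_unequal(reference: PayoffPair, alternative: PayoffPair) -> str:
    """Which option has the more equal (smaller |self-other|) allocation.

    Returns ``"reference"`` or ``"alternative"``; identical inequality is
    flagged as ``"tie"`` and such trials are excluded from equal/unequal
    conditioned summaries downstream.
    """
    ri, ai = reference.inequality, alternative.inequality
    if ri == ai:
        return "tie"
    return "alternative" if ai < ri else "reference"


def payoff_changes(trial: Trial) -> tuple[int, int]:
    """(delta_self, delta_other): alternative minus reference payoffs."""
    return trial.delta_self, trial.delta_other


class TrialDesign:
    """An ordered 416-trial schedule for one participant.

    Thin wrapper around a :class:`pandas.DataFrame` with one row per trial
    and columns: participant_id, trial_index, context, ref_self, ref_other,
    alt_self, alt_other, trial_set, side_of_reference, delta_self,
    delta_other, equal_option, onset_jitter.
    """

    COLUMNS = [
        "participant_id", "trial_index", "context", "ref_self", "ref_other",
        "alt_self", "alt_other", "trial_set", "side_of_reference",
        "delta_self", "delta_other", "equal_option", "onset_jitter",
    ]

    def __init__(self, table: pd.DataFrame):
        missing = set(self.COLUMNS) - set(table.columns)
        if missing:
            raise ValueError(f"design table missing columns: {sorted(missing)}")
        self.table = table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TrialDesign) and self.table.equals(other.table)

    @property
    def participant_id(self) -> str:
        return str(self.table["participant_id"].iloc[0])

    def context_table(self, context: str) -> pd.DataFrame:
        return self.table[self.table["context"] == context]

    def trial(self, i: int) -> Trial:
        row = self.table.iloc[i]
        return Trial(
            context=row["context"],
            reference=PayoffPair(int(row["ref_self"]), int(row["ref_other"])),
            alternative=PayoffPair(int(row["alt_self"]), int(row["alt_other"])),
            trial_set=int(row["trial_set"]),
            side_of_reference=row["side_of_reference"],
        )

    def validate(self) -> None:
        t = self.table
        if len(t) != 416:
            raise ValueError(f"expected 416 trials, got {len(t)}")
        for ctx, sign in (("DIS", -1), ("ADV", 1)):
            sub = t[t["context"] == ctx]
            if sorted(set(zip(sub["ref_self"], sub["ref_other"]))) != sorted(
                set(REFERENCES_DIS if ctx == "DIS" else REFERENCES_ADV)
            ):
                raise ValueError(f"wrong reference set in {ctx}")
            gaps_ref = sign * (sub["ref_self"] - sub["ref_other"])
            gaps_alt = sign * (sub["alt_self"] - sub["alt_other"])
            if not ((gaps_ref > 0).all() and (gaps_alt > 0).all()):
                raise ValueError(f"context purity violated in {ctx}")
        if (t[["delta_self", "delta_other"]].abs() > _MAX_DELTA).any().any():
            raise ValueError("payoff change outside [-19, 19]")
        if (t["equal_option"] == "tie").any():
            raise ValueError("design contains inequality ties")

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TrialDesign":
        return cls(pd.read_csv(path))


def _jitter_ok(ref: tuple[int, int], alt: tuple[int, int], context: str) -> bool:
    s, o = alt
    if s < 0 or o < 0:
        return False
    gap = s - o
    if context == "DIS" and gap >= 0:
        return False
    if context == "ADV" and gap <= 0:
        return False
    if abs(s - ref[0]) > _MAX_DELTA or abs(o - ref[1]) > _MAX_DELTA:
        return False
    if abs(gap) == abs(ref[0] - ref[1]):  # inequality tie
        return False
    return True


def generate_schedule(
    seed: int,
    jitter_seed: int | None = None,
    participant_id: str = "sub-00",
    offsets_dis=DEFAULT_OFFSETS_DIS,
) -> TrialDesign:
    """Generate the 416-trial schedule.

    ``seed`` controls trial-order randomisation and side counterbalancing;
    ``jitter_seed`` (defaults to ``seed + 1``) controls the -1/0/+1 payoff
    jitter that turns trial set 1 into trial set 2.  Jitters that would
    break context purity, exceed the +/-19 payoff-change range, make a
    payoff negative, or create an inequality tie are redrawn.
    """
    if seed < 0 or (jitter_seed is not None and jitter_seed < 0):
        raise ValueError("seeds must be non-negative")
    if jitter_seed is None:
        jitter_seed = seed + 1
    rng = np.random.default_rng(seed)
    jrng = np.random.default_rng(jitter_seed)

    # jitters are drawn once per (reference, offset) in the DIS context and
    # applied with flipped sign in ADV, keeping the two contexts exact
    # mirrors of each other (same multiset of absolute payoff changes)
    jitters = []
    for ref in REFERENCES_DIS:
        row = []
        for ds, do in offsets_dis:
            alt = (ref[0] + ds, ref[1] + do)
            while True:
                js, jo = (int(v) for v in jrng.integers(-1, 2, size=2))
                if _jitter_ok(ref, (alt[0] + js, alt[1] + jo), "DIS"):
                    row.append((js, jo))
                    break
        jitters.append(row)

    rows = []
    for context in CONTEXTS:
        refs = REFERENCES_DIS if context == "DIS" else REFERENCES_ADV
        sign = 1 if context == "DIS" else -1
        for ref, jrow in zip(refs, jitters):
            for (ds, do), (js, jo) in zip(offsets_dis, jrow):
                set1_alt = (ref[0] + sign * ds, ref[1] + sign * do)
                set2_alt = (ref[0] + sign * (ds + js), ref[1] + sign * (do + jo))
                rows.append((context, ref, set1_alt, 1))
                rows.append((context, ref, set2_alt, 2))

    order = rng.permutation(len(rows))
    # trial-by-trial counterbalancing of the reference side: alternate
    # left/right over the randomised order, with a seed-determined start.
    sides = ["left", "right"] if rng.integers(2) == 0 else ["right", "left"]
    records = []
    for new_idx, old_idx in enumerate(order):
        context, ref, alt, trial_set = rows[old_idx]
        rp = PayoffPair(*ref)
        ap = PayoffPair(*alt)
        records.append(
            dict(
                participant_id=participant_id,
                trial_index=new_idx,
                context=context,
                ref_self=ref[0],
                ref_other=ref[1],
                alt_self=alt[0],
                alt_other=alt[1],
                trial_set=trial_set,
                side_of_reference=sides[new_idx % 2],
                delta_self=alt[0] - ref[0],
                delta_other=alt[1] - ref[1],
                equal_option=classify_equal_unequal(rp, ap),
                onset_jitter=round(float(rng.uniform(0.5, 2.0)), 4),
            )
        )
    design = TrialDesign(pd.DataFrame.from_records(records, columns=TrialDesign.COLUMNS))
    design.validate()
    return design


def equal_unequal_diffs(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial payoff differences, equal option minus unequal option.

    Returns (d_self, d_other) arrays; these feed the Charness-Rabin value
    difference that drives evidence accumulation toward the equal bound.
    """
    eq_is_alt = (table["equal_option"] == "alternative").to_numpy()
    if (table["equal_option"] == "tie").to_numpy().any():
        raise ValueError("table contains tie trials; exclude them first")
    ds = np.where(eq_is_alt, table["delta_self"], -table["delta_self"])
    do = np.where(eq_is_alt, table["delta_other"], -table["delta_other"])
    return ds.astype(float), do.astype(float)
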