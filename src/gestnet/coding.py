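"""Segmentation and classification of gesture event streams.

A gesture *sequence* is one or more gestures made consecutively by the same
signaller, to the same recipient, with the same goal (operationalised as an
observer-coded context label), with no more than 30 s between consecutive
gestures.  Within a sequence, the timing of the gaps decides the class:

single
    exactly one gesture, isolated from any other by the 30 s window.
rapid
    two or more gestures with every inter-gesture gap shorter than the
    response-waiting minimum (1 s by default) — a burst too fast for the
    signaller to have monitored the recipient between gestures.
persistence
    two or more gestures with at least one gap long enough for response
    waiting (>= 1 s) — the signaller paused, monitored, and gestured again.

The 1–5 s band is the canonical response-waiting window.  Gaps in (5 s,
30 s] fall between the definitions: by default any within-sequence gap
>= 1 s counts as response waiting (consistent with the 30 s independence
rule); ``strict_wait_window=True`` instead splits sequences at gaps longer
than 5 s, for sensitivity analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "RESPONSE_CATEGORIES",
    "GestureEvent",
    "ResponseRecord",
    "GestureSequence",
    "expand_multi_recipient",
    "segment_sequences",
    "classify_sequence",
    "attach_response",
    "kappa_sample",
    "events_from_frame",
    "sequences_to_frame",
    "code_events",
]

#: The three-way response taxonomy (plus absence) used for recipient responses.
RESPONSE_CATEGORIES = ("activity_change", "vocalisation", "visual_tactile_gesture")

SEQUENCE_WINDOW_S = 30.0  #: max gap between gestures of one sequence, inclusive
RESPONSE_WAIT_MIN_S = 1.0
RESPONSE_WAIT_MAX_S = 5.0


@dataclass(frozen=True)
class GestureEvent:
    """One time-stamped intentional gesture."""

    event_id: str
    time: float  # seconds
    signaller: str
    recipients: frozenset
    gesture_label: str = ""
    modality: str = "visual"
    context: str = ""
    signaller_oriented: bool = True
    recipient_oriented: bool = True
    response_present: bool | None = None
    response_category: str | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.time):
            raise ValueError(f"event {self.event_id}: non-finite time")
        rec = frozenset(self.recipients)
        object.__setattr__(self, "recipients", rec)
        if self.signaller in rec:
            raise ValueError(
                f"event {self.event_id}: signaller {self.signaller} in recipients"
            )

    @property
    def recipient(self) -> str:
        if len(self.recipients) != 1:
            raise ValueError(
                f"event {self.event_id}: expected a single recipient, "
                f"got {sorted(self.recipients)}; expand multi-recipient events first"
            )
        return next(iter(self.recipients))


@dataclass(frozen=True)
class ResponseRecord:
    present: bool
    category: str | None = None

    def __post_init__(self) -> None:
        if self.present:
            if self.category not in RESPONSE_CATEGORIES:
                raise ValueError(
                    f"unknown response category {self.category!r}; "
                    f"expected one of {RESPONSE_CATEGORIES}"
                )
        elif self.category is not None:
            raise ValueError("absent response must not carry a category")


@dataclass
class GestureSequence:
    """An ordered run of gestures forming one communicative attempt."""

    events: list[GestureEvent]
    signaller: str
    recipient: str
    context: str
    cls: str | None = None
    response: ResponseRecord | None = None

    @property
    def gaps(self) -> list[float]:
        t = [e.time for e in self.events]
        return [b - a for a, b in zip(t, t[1:])]

    @property
    def first_time(self) -> float:
        return self.events[0].time

    def __len__(self) -> int:
        return len(self.events)


def expand_multi_recipient(events: list[GestureEvent]) -> list[GestureEvent]:
    """One event per recipient, so downstream tallies are dyadic.

    Broadcast gestures (e.g. gestures accompanied by pant-hoots, whose
    audience is everyone within 10 m) are duplicated per recipient with a
    derived event id.
    """
    out = []
    for e in events:
        if len(e.recipients) == 1:
            out.append(e)
        else:
            for r in sorted(e.recipients):
                out.append(
                    replace(e, event_id=f"{e.event_id}@{r}", recipients=frozenset({r}))
                )
    return out


def segment_sequences(
    events: list[GestureEvent],
    window: float = SEQUENCE_WINDOW_S,
    strict_wait_window: bool = False,
) -> list[GestureSequence]:
    """Partition an event log into gesture sequences.

    Events are sorted by time (ties broken by event id for determinism) and
    grouped per (signaller, recipient, context); a new sequence starts when
    the gap to the previous gesture of the same group exceeds ``window``
    (or ``RESPONSE_WAIT_MAX_S`` when ``strict_wait_window``).  Both cut-offs
    are inclusive: a gap of exactly 30 s stays within one sequence.
    """
    events = expand_multi_recipient(events)
    cut = RESPONSE_WAIT_MAX_S if strict_wait_window else window
    groups: dict[tuple, list[GestureEvent]] = {}
    for e in sorted(events, key=lambda e: (e.time, e.event_id)):
        groups.setdefault((e.signaller, e.recipient, e.context), []).append(e)

    sequences: list[GestureSequence] = []
    for (sig, rec, ctx), evs in groups.items():
        run = [evs[0]]
        for e in evs[1:]:
            if e.time - run[-1].time > cut:
                sequences.append(GestureSequence(run, sig, rec, ctx))
                run = [e]
            else:
                run.append(e)
        sequences.append(GestureSequence(run, sig, rec, ctx))

    sequences.sort(key=lambda s: (s.first_time, s.signaller, s.recipient))
    for seq in sequences:
        seq.cls = classify_sequence(seq)
        seq.response = _response_from_events(seq.events)
    return sequences


def classify_sequence(
    seq: GestureSequence,
    response_wait_min: float = RESPONSE_WAIT_MIN_S,
    response_wait_max: float = RESPONSE_WAIT_MAX_S,
) -> str:
    """Class label from the gap vector alone.

    One gesture -> ``single``.  Otherwise ``rapid`` iff every gap is below
    ``response_wait_min`` (no room for response waiting), else
    ``persistence`` (at least one waiting pause; a gap of exactly 1.0 s
    counts as waiting).  ``response_wait_max`` is kept in the signature for
    the strict-window dialect but does not affect the default rule.
    """
    if not seq.events:
        raise ValueError("cannot classify an empty sequence")
    gaps = seq.gaps
    if not gaps:
        return "single"
    if all(g < response_wait_min for g in gaps):
        return "rapid"
    return "persistence"


def _response_from_events(events: list[GestureEvent]) -> ResponseRecord | None:
    """Response annotation carried on the log: last annotated event wins."""
    for e in reversed(events):
        if e.response_present is not None:
            cat = e.response_category if e.response_present else None
            return ResponseRecord(bool(e.response_present), cat)
    return None


def attach_response(seq: GestureSequence, annotation) -> GestureSequence:
    """Attach a coded recipient response to a sequence.

    ``annotation`` may be a :class:`ResponseRecord`, a category string, or
    ``None``/``"absent"`` for no response.  Unknown categories raise.
    """
    if isinstance(annotation, ResponseRecord):
        rec = annotation
    elif annotation is None or annotation == "absent":
        rec = ResponseRecord(False)
    elif isinstance(annotation, str):
        rec = ResponseRecord(True, annotation)
    else:
        present = bool(annotation.get("present"))
        rec = ResponseRecord(present, annotation.get("category") if present else None)
    seq.response = rec
    return seq


def kappa_sample(
    sequences: list[GestureSequence], k: int, seed: int
) -> list[GestureSequence]:
    """Seeded uniform sample without replacement, for second-coder reliability."""
    if k > len(sequences):
        raise ValueError(f"requested {k} sequences but only {len(sequences)} exist")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(sequences), size=k, replace=False)
    return [sequences[i] for i in sorted(idx)]


# ---------------------------------------------------------------------------
# tabular round-trip

def events_from_frame(frame: pd.DataFrame) -> list[GestureEvent]:
    """Build events from the events CSV schema (recipients ';'-joined)."""
    events = []
    for row in frame.itertuples(index=False):
        rp = getattr(row, "response_present", None)
        present = None if pd.isna(rp) else bool(rp)
        cat = getattr(row, "response_category", None)
        if cat is not None and (pd.isna(cat) or cat == ""):
            cat = None
        events.append(
            GestureEvent(
                event_id=str(row.event_id),
                time=float(row.time_s),
                signaller=str(row.signaller),
                recipients=frozenset(str(row.recipients).split(";")),
                gesture_label=str(getattr(row, "gesture_label", "")),
                modality=str(getattr(row, "modality", "visual")),
                context=str(getattr(row, "context", "")),
                response_present=present,
                response_category=cat,
            )
        )
    return events


def sequences_to_frame(sequences: list[GestureSequence]) -> pd.DataFrame:
    rows = []
    for i, s in enumerate(sequences):
        resp = s.response
        rows.append(
            {
                "sequence_id": f"seq{i:06d}",
                "signaller": s.signaller,
                "recipient": s.recipient,
                "context": s.context,
                "cls": s.cls,
                "n_gestures": len(s),
                "first_time_s": s.first_time,
                "response_present": bool(resp.present) if resp else False,
                "response_category": (resp.category or "") if resp else "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sequence_id", "signaller", "recipient", "context", "cls",
            "n_gestures", "first_time_s", "response_present", "response_category",
        ],
    )


def code_events(
    events_frame: pd.DataFrame, strict_wait_window: bool = False
) -> pd.DataFrame:
    """events CSV -> sequences CSV, the coder's end-to-end step."""
    seqs = segment_sequences(
        events_from_frame(events_frame), strict_wait_window=strict_wait_window
    )
    return sequences_to_frame(seqs)
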