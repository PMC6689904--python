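"""Dyadic matrices from scan samples and coded gesture sequences.

Three families of matrices feed the regressions:

* **proximity** — minutes spent within 10 m per hour spent in the same
  party, ``PROX_AB = 60 * P10_AB / party_AB`` (bounded by [0, 60]);
* **communication rates** — sequence initiations per hour of co-proximity,
  ``CA_AB = (C_AB * 60) / (P10_AB * 2)`` where each within-10 m scan stands
  for a 2-min exposure interval, computed per sequence class and per
  response category;
* **attribute similarities** — binary symmetric matrices for sex, age
  (within 5 years), reproductive activity (male x cycling female) and
  maternal kinship.

All tallies are directed: row A is A's focal observation time, so
``P10_AB`` counts A-focal scans with B within 10 m, which need not equal
``P10_BA``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrices import DyadMatrix

__all__ = [
    "COMMUNICATION_KEYS",
    "DyadTallies",
    "tally_dyads",
    "communication_rate",
    "proximity_rate",
    "similarity_matrix",
    "build_networks",
]

#: tally keys: the three sequence classes, response presence/absence, and
#: the three response categories
COMMUNICATION_KEYS = (
    "single",
    "rapid",
    "persistence",
    "response_present",
    "response_absent",
    "response_activity_change",
    "response_vocalisation",
    "response_visual_tactile_gesture",
)

SCAN_INTERVAL_MIN = 2.0


@dataclass
class DyadTallies:
    """Integer counts per ordered dyad (row = focal/signaller)."""

    labels: list[str]
    party: np.ndarray  # scans with B in A's party
    p10: np.ndarray    # scans with B within 10 m of A
    comm: dict[str, np.ndarray] = field(default_factory=dict)
    n_excluded: int = 0  # sequences whose recipient was not within 10 m

    @property
    def n(self) -> int:
        return len(self.labels)

    def zero_exposure_mask(self) -> np.ndarray:
        """True where the dyad was never observed within 10 m (rate undefined)."""
        m = self.p10 == 0
        np.fill_diagonal(m, False)
        return m


def _member_lists(col: pd.Series) -> list[list[str]]:
    out = []
    for v in col:
        if isinstance(v, str):
            out.append(v.split(";") if v else [])
        elif isinstance(v, (list, tuple)):
            out.append(list(v))
        elif v is None or (isinstance(v, float) and np.isnan(v)):
            out.append([])
        else:
            raise TypeError(f"cannot parse member list {v!r}")
    return out


def tally_dyads(
    scans: pd.DataFrame,
    sequences: pd.DataFrame,
    labels: list[str] | None = None,
    scan_interval_min: float = SCAN_INTERVAL_MIN,
) -> DyadTallies:
    """Exact integer tallies of proximity scans and attributed sequences.

    Each coded sequence is attributed to the focal-follow scan interval
    ``[t_scan, t_scan + 2 min)`` containing its first gesture, matched on
    the signaller being the focal.  Sequences whose recipient was not
    within 10 m at that scan (or that fall inside no follow of their
    signaller) are excluded from the communication counts but tallied in
    ``n_excluded``.
    """
    if labels is None:
        labels = sorted(
            set(scans["focal_id"].astype(str))
            | {m for lst in _member_lists(scans["party_members"]) for m in lst}
        )
    labels = [str(x) for x in labels]
    idx = {l: i for i, l in enumerate(labels)}
    n = len(labels)

    party = np.zeros((n, n), dtype=np.int64)
    p10 = np.zeros((n, n), dtype=np.int64)
    party_lists = _member_lists(scans["party_members"])
    w10_lists = _member_lists(scans["within10_members"])
    focal_ids = scans["focal_id"].astype(str).to_numpy()
    start_times = scans["time_min"].to_numpy(dtype=float) * 60.0

    # per-focal interval tables for sequence attribution
    by_focal: dict[str, tuple[np.ndarray, list[set]]] = {}
    order = np.argsort(start_times, kind="mergesort")
    for a, lst in zip(focal_ids, party_lists):
        if a not in idx:
            raise KeyError(f"scan focal {a!r} not in node labels")
        for b in lst:
            if b not in idx:
                raise KeyError(f"party member {b!r} not in node labels")
            party[idx[a], idx[b]] += 1
    for a, lst in zip(focal_ids, w10_lists):
        for b in lst:
            if b not in idx:
                raise KeyError(f"within-10 m member {b!r} not in node labels")
            p10[idx[a], idx[b]] += 1
    for f in set(focal_ids):
        sel = order[focal_ids[order] == f]
        by_focal[f] = (start_times[sel], [set(w10_lists[i]) for i in sel])

    comm = {k: np.zeros((n, n), dtype=np.int64) for k in COMMUNICATION_KEYS}
    n_excluded = 0
    interval_s = scan_interval_min * 60.0
    for seq in sequences.itertuples(index=False):
        a, b = str(seq.signaller), str(seq.recipient)
        if a not in idx or b not in idx:
            raise KeyError(f"sequence references unknown node: {a!r} -> {b!r}")
        if seq.cls not in ("single", "rapid", "persistence"):
            raise ValueError(f"unknown sequence class {seq.cls!r}")
        starts, w10_sets = by_focal.get(a, (np.empty(0), []))
        k = int(np.searchsorted(starts, float(seq.first_time_s), side="right")) - 1
        attributed = (
            k >= 0
            and float(seq.first_time_s) < starts[k] + interval_s
            and b in w10_sets[k]
        )
        if not attributed:
            n_excluded += 1
            continue
        i, j = idx[a], idx[b]
        comm[seq.cls][i, j] += 1
        cat = getattr(seq, "response_category", "")
        present = bool(seq.response_present) and isinstance(cat, str) and cat != ""
        if present:
            comm["response_present"][i, j] += 1
            key = f"response_{cat}"
            if key not in comm:
                raise ValueError(f"unknown response category {cat!r}")
            comm[key][i, j] += 1
        else:
            comm["response_absent"][i, j] += 1

    return DyadTallies(labels, party, p10, comm, n_excluded)


def communication_rate(
    tallies: DyadTallies,
    key: str,
    scan_interval_min: float = SCAN_INTERVAL_MIN,
) -> DyadMatrix:
    """Events per hour of co-proximity: ``CA_AB = (C_AB * 60) / (P10_AB * 2)``.

    Each within-10 m scan represents one instantaneous-subsample interval
    (2 min by default), so ``P10 * 2`` is minutes of observed co-proximity.
    Dyads never observed within 10 m get rate 0; use
    :meth:`DyadTallies.zero_exposure_mask` to flag or mask them.
    """
    if key not in tallies.comm:
        raise KeyError(f"no tally named {key!r}; have {sorted(tallies.comm)}")
    c = tallies.comm[key].astype(float)
    denom = tallies.p10.astype(float) * scan_interval_min
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(denom > 0, c * 60.0 / denom, 0.0)
    np.fill_diagonal(rate, 0.0)
    return DyadMatrix(tallies.labels, rate, name=key, directed=True)


def proximity_rate(tallies: DyadTallies) -> DyadMatrix:
    """Minutes within 10 m per hour in the same party: ``60 * P10 / party``.

    Both numerator and denominator are scan counts scaled by the same
    interval length, so the interval cancels and the value lives in
    [0, 60] by the invariant ``P10_AB <= party_AB``.
    """
    p10 = tallies.p10.astype(float)
    party = tallies.party.astype(float)
    if np.any(tallies.p10 > tallies.party):
        raise ValueError("P10 exceeds party count for some dyad")
    with np.errstate(divide="ignore", invalid="ignore"):
        prox = np.where(party > 0, 60.0 * p10 / party, 0.0)
    np.fill_diagonal(prox, 0.0)
    return DyadMatrix(tallies.labels, prox, name="proximity", directed=True)


def similarity_matrix(attrs: pd.DataFrame, kind: str) -> DyadMatrix:
    """Binary symmetric attribute-similarity matrix.

    kind:
      ``sex``      1 iff same sex;
      ``age``      1 iff age difference of 5 years or less;
      ``oestrous`` 1 iff one member is male and the other a cycling female
                   (the reproductively active pairing);
      ``kin``      1 iff mother–offspring link in either direction.
    """
    labels = [str(x) for x in attrs["id"]]
    n = len(labels)
    vals = np.zeros((n, n))
    if kind == "sex":
        sex = attrs["sex"].astype(str).to_numpy()
        vals = (sex[:, None] == sex[None, :]).astype(float)
    elif kind == "age":
        if attrs["age"].isna().any():
            raise ValueError("age similarity requires ages for every individual")
        age = attrs["age"].to_numpy(dtype=float)
        vals = (np.abs(age[:, None] - age[None, :]) <= 5.0).astype(float)
    elif kind == "oestrous":
        male = (attrs["sex"].astype(str) == "male").to_numpy()
        cycling = (attrs["reproductive_status"].astype(str) == "cycling").to_numpy()
        vals = (
            (male[:, None] & cycling[None, :]) | (cycling[:, None] & male[None, :])
        ).astype(float)
    elif kind == "kin":
        if "mother_id" not in attrs.columns:
            raise ValueError("kin similarity requires a mother_id column")
        mother = attrs["mother_id"]
        for i in range(n):
            m = mother.iloc[i]
            if pd.isna(m) or m == "":
                continue
            if str(m) not in labels:
                raise ValueError(f"mother {m!r} of {labels[i]!r} not in table")
            j = labels.index(str(m))
            vals[i, j] = vals[j, i] = 1.0
    else:
        raise ValueError(f"unknown similarity kind {kind!r}")
    np.fill_diagonal(vals, 0.0)
    return DyadMatrix(labels, vals, name=f"{kind}_similarity", directed=False)


def build_networks(
    scans: pd.DataFrame,
    sequences: pd.DataFrame,
    attrs: pd.DataFrame,
    scan_interval_min: float = SCAN_INTERVAL_MIN,
) -> tuple[dict[str, DyadMatrix], DyadTallies]:
    """Every matrix the dyadic models need, keyed by measure name."""
    labels = [str(x) for x in attrs["id"]]
    tallies = tally_dyads(scans, sequences, labels, scan_interval_min)
    nets = {"proximity": proximity_rate(tallies)}
    for key in COMMUNICATION_KEYS:
        nets[key] = communication_rate(tallies, key, scan_interval_min)
    for kind in ("sex", "age", "oestrous", "kin"):
        nets[f"{kind}_similarity"] = similarity_matrix(attrs, kind)
    return nets, tallies
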