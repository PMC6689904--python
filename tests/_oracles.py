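"""Independent brute-force oracles the fast implementations are checked against.

Everything here is deliberately naive — nested loops, full enumeration,
per-permutation refits — and shares no code with the package internals.
"""

from __future__ import annotations

import itertools

import numpy as np


def classify_by_rule(gaps) -> str:
    """Timing rule restated independently: no gaps -> single; all gaps
    shorter than 1 s -> rapid; any waiting gap (>= 1 s) -> persistence."""
    if len(gaps) == 0:
        return "single"
    if max(gaps) < 1.0:
        return "rapid"
    return "persistence"


def segment_components(events) -> list[set]:
    """Partition of event ids by the grouping constraints, via pairwise
    adjacency: same signaller/recipient/context and consecutive gaps <= 30 s."""
    groups = {}
    for e in events:
        key = (e.signaller, next(iter(e.recipients)), e.context)
        groups.setdefault(key, []).append(e)
    comps = []
    for evs in groups.values():
        evs = sorted(evs, key=lambda e: (e.time, e.event_id))
        current = {evs[0].event_id}
        for prev, nxt in zip(evs, evs[1:]):
            if nxt.time - prev.time > 30.0:
                comps.append(current)
                current = set()
            current.add(nxt.event_id)
        comps.append(current)
    return comps


def qap_correlation_exhaustive(Xv: np.ndarray, Yv: np.ndarray):
    """Exact two-sided QAP correlation p over all n! relabelings, naively."""
    n = Xv.shape[0]
    off = ~np.eye(n, dtype=bool)
    r_obs = np.corrcoef(Xv[off], Yv[off])[0, 1]
    hits, total = 0, 0
    for perm in itertools.permutations(range(n)):
        P = np.array(perm)
        Xp = np.empty_like(Xv)
        for i in range(n):
            for j in range(n):
                Xp[i, j] = Xv[P[i], P[j]]
        r = np.corrcoef(Xp[off], Yv[off])[0, 1]
        if abs(r) >= abs(r_obs) * (1 - 1e-12):
            hits += 1
        total += 1
    return r_obs, hits / total


def dsp_exhaustive(Yv: np.ndarray, X_list: list[np.ndarray]):
    """Exact Double-Dekker semi-partialling p-values by full enumeration.

    For each predictor: residualize its matrix on the others (dyad-wise OLS
    with intercept), apply every node relabeling to the residual matrix,
    substitute, refit with lstsq, and count |beta*| >= |beta|.
    """
    n = Yv.shape[0]
    off = ~np.eye(n, dtype=bool)
    y = Yv[off]
    cols = [X[off] for X in X_list]
    design = np.column_stack([np.ones(len(y))] + cols)
    beta = np.linalg.lstsq(design, y, rcond=None)[0]

    p_values = []
    for t in range(len(cols)):
        others = np.column_stack(
            [np.ones(len(y))] + [c for s, c in enumerate(cols) if s != t]
        )
        gamma = np.linalg.lstsq(others, cols[t], rcond=None)[0]
        resid = cols[t] - others @ gamma
        R = np.zeros((n, n))
        R[off] = resid
        hits, total = 0, 0
        for perm in itertools.permutations(range(n)):
            P = np.array(perm)
            Rp = np.empty_like(R)
            for i in range(n):
                for j in range(n):
                    Rp[i, j] = R[P[i], P[j]]
            sub = np.column_stack([others, Rp[off]])
            b = np.linalg.lstsq(sub, y, rcond=None)[0][-1]
            if abs(b) >= abs(beta[t + 1]) * (1 - 1e-12):
                hits += 1
            total += 1
        p_values.append(hits / total)
    return beta[1:], np.array(p_values)


def node_regression_exhaustive(y: np.ndarray, X: np.ndarray):
    """Exact outcome-permutation p-values for node-level OLS."""
    n = len(y)
    design = np.column_stack([np.ones(n), X])
    beta = np.linalg.lstsq(design, y, rcond=None)[0][1:]
    hits = np.zeros(len(beta))
    total = 0
    for perm in itertools.permutations(range(n)):
        b = np.linalg.lstsq(design, y[np.array(perm)], rcond=None)[0][1:]
        hits += np.abs(b) >= np.abs(beta) * (1 - 1e-12)
        total += 1
    return beta, hits / total


def tally_by_double_loop(scans_rows, sequences_rows, labels, interval_s=120.0):
    """Spec-literal tallies: for every sequence, scan all scans."""
    idx = {l: i for i, l in enumerate(labels)}
    n = len(labels)
    party = np.zeros((n, n), dtype=int)
    p10 = np.zeros((n, n), dtype=int)
    comm = {}
    excluded = 0
    for s in scans_rows:
        for b in s["party"]:
            party[idx[s["focal"]], idx[b]] += 1
        for b in s["w10"]:
            p10[idx[s["focal"]], idx[b]] += 1
    for q in sequences_rows:
        hit = None
        for s in scans_rows:
            t0 = s["time_min"] * 60.0
            if (
                s["focal"] == q["signaller"]
                and t0 <= q["first_time_s"] < t0 + interval_s
            ):
                hit = s
                break
        if hit is None or q["recipient"] not in hit["w10"]:
            excluded += 1
            continue
        key = q["cls"]
        comm.setdefault(key, np.zeros((n, n), dtype=int))
        comm[key][idx[q["signaller"]], idx[q["recipient"]]] += 1
    return party, p10, comm, excluded
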