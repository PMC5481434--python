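"""Marker-state-space panel search with cross-validation and label nulls.

A panel uses 1-3 markers, one scanned threshold per marker, and a state
table mapping each binary marker state (1 = strictly above threshold) to
case or control.  The search enumerates every marker subset of size 1-3 and
every combination of candidate thresholds (midpoints between consecutive
unique observed values, capped at 50 quantile-based candidates), labels
each observed state by its majority class (ties and unobserved states go to
control), and keeps the panels whose training sensitivity and specificity
both meet the user minima (default 80% / 80%).

Cross-validation randomly partitions the samples into k unstratified
groups; for each split the search runs on the training portion and every
qualifying panel is applied to the held-out group, the split's accuracy
being the unweighted mean over qualifying panels.  Splits where no panel
meets the minima report no accuracy.  Per-round medians are taken over the
splits that produced values, and the overall figure is the mean of the
round medians.  The random-label null reruns the identical machinery with
each sample independently reassigned case or control by a fair coin.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ThresholdGrid",
    "PanelRule",
    "PanelPerformance",
    "CVReport",
    "candidate_thresholds",
    "binarize",
    "fit_state_rule",
    "classify",
    "evaluate_panel",
    "search_panels",
    "cross_validate",
    "random_label_null",
    "round_median",
    "average_of_medians",
    "MIN_SENSITIVITY",
    "MIN_SPECIFICITY",
    "MAX_MARKERS",
]

MIN_SENSITIVITY = 0.80
MIN_SPECIFICITY = 0.80
MAX_MARKERS = 3
MAX_THRESHOLD_CANDIDATES = 50
_EPS = 1e-9


# ---------------------------------------------------------------------------
# thresholds and states
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ThresholdGrid:
    """Sorted candidate thresholds per marker."""

    markers: tuple[str, ...]
    candidates: tuple[np.ndarray, ...]

    def __getitem__(self, marker: str) -> np.ndarray:
        return self.candidates[self.markers.index(marker)]


def candidate_thresholds(
    values: Sequence[float], max_candidates: int = MAX_THRESHOLD_CANDIDATES
) -> np.ndarray:
    """Candidate thresholds: midpoints between consecutive unique values.

    Midpoints realize every distinct dichotomization of the observed sample
    and guarantee that no observed value equals a threshold.  With more
    than ``max_candidates`` midpoints, an evenly spaced quantile subset of
    the midpoints is used.
    """

    u = np.unique(np.asarray(values, dtype=float))
    if u.size < 2:
        raise ValueError("need at least two distinct values")
    mids = (u[:-1] + u[1:]) / 2.0
    if mids.size > max_candidates:
        mids = np.unique(np.quantile(mids, np.linspace(0, 1, max_candidates)))
    return mids


def binarize(values: np.ndarray, thresholds: Sequence[float]) -> np.ndarray:
    """Binary state matrix: 1 iff value strictly above its marker threshold."""

    values = np.atleast_2d(np.asarray(values, dtype=float))
    thresholds = np.asarray(thresholds, dtype=float)
    if values.shape[1] != thresholds.size:
        raise ValueError("one threshold per marker required")
    return (values > thresholds[None, :]).astype(np.uint8)


def _state_index(states: np.ndarray) -> np.ndarray:
    """Pack binary state rows into integers; the first marker is the MSB."""

    m = states.shape[1]
    weights = 1 << np.arange(m - 1, -1, -1)
    return states.astype(np.int64) @ weights


# ---------------------------------------------------------------------------
# rules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PanelPerformance:
    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")

    @property
    def accuracy(self) -> float:
        total = self.tp + self.fn + self.fp + self.tn
        return (self.tp + self.tn) / total if total else float("nan")

    @classmethod
    def from_counts(cls, tp: int, fn: int, fp: int, tn: int) -> "PanelPerformance":
        return cls(tp=tp, fn=fn, fp=fp, tn=tn)


@dataclass(frozen=True)
class PanelRule:
    """A <=3-marker threshold rule with a full binary state table.

    ``state_to_case[s]`` is the class of state ``s`` where ``s`` packs the
    per-marker above-threshold bits with the first marker as the most
    significant bit.  The wildcard (X) form available from
    :meth:`compact_rows` is cosmetic; classification always uses the full
    table.
    """

    markers: tuple[str, ...]
    thresholds: tuple[float, ...]
    state_to_case: tuple[bool, ...]
    performance: PanelPerformance | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        m = len(self.markers)
        if not 1 <= m <= MAX_MARKERS:
            raise ValueError(f"panels use 1-{MAX_MARKERS} markers")
        if len(self.thresholds) != m or len(self.state_to_case) != (1 << m):
            raise ValueError("thresholds/state table sizes inconsistent with markers")

    def compact_rows(self) -> list[tuple[str, str]]:
        """Merged 1/0/X rows for the case states, most general first.

        Greedy merge of adjacent implicants over the case minterms; every
        state not covered is control.
        """

        m = len(self.markers)
        case_states = {s for s, c in enumerate(self.state_to_case) if c}
        implicants = {tuple(format(s, f"0{m}b")) for s in case_states}
        changed = True
        while changed:
            changed = False
            merged = set()
            used = set()
            for a, b in itertools.combinations(sorted(implicants), 2):
                diff = [i for i in range(m) if a[i] != b[i]]
                if len(diff) == 1 and all(
                    a[i] == b[i] for i in range(m) if i != diff[0]
                ):
                    new = tuple("X" if i == diff[0] else a[i] for i in range(m))
                    if self._covers_only_cases(new, case_states, m):
                        merged.add(new)
                        used.update((a, b))
                        changed = True
            implicants = (implicants - used) | merged
        rows = sorted(implicants, key=lambda r: (-r.count("X"), r))
        return [("".join(r), "case") for r in rows]

    @staticmethod
    def _covers_only_cases(pattern: tuple[str, ...], case_states: set[int], m: int) -> bool:
        free = [i for i, ch in enumerate(pattern) if ch == "X"]
        for bits in itertools.product("01", repeat=len(free)):
            full = list(pattern)
            for i, b in zip(free, bits):
                full[i] = b
            if int("".join(full), 2) not in case_states:
                return False
        return True


def fit_state_rule(
    states: np.ndarray, labels: Sequence[bool], markers: Sequence[str] | None = None,
    thresholds: Sequence[float] | None = None,
) -> np.ndarray:
    """Majority-class state table from binary states and case labels.

    Each observed state is assigned its majority class; ties and unobserved
    states are control.  Returns a boolean array of length ``2**m`` (True =
    case); wrap in :class:`PanelRule` to attach markers/thresholds.
    """

    states = np.atleast_2d(np.asarray(states))
    y = np.asarray(labels, dtype=bool)
    if states.shape[0] != y.size:
        raise ValueError("states and labels length mismatch")
    if states.shape[0] == 0:
        raise ValueError("empty input")
    m = states.shape[1]
    if not 1 <= m <= MAX_MARKERS:
        raise ValueError(f"states must use 1-{MAX_MARKERS} markers")
    idx = _state_index(states)
    n_states = 1 << m
    cc = np.bincount(idx[y], minlength=n_states)
    cn = np.bincount(idx[~y], minlength=n_states)
    return cc > cn


def classify(rule: PanelRule, values: Mapping[str, float] | pd.DataFrame | np.ndarray) -> np.ndarray | bool:
    """Apply a panel rule: binarize the rule's markers, look up the state.

    ``values`` may be a mapping or single-row frame (returns one bool) or a
    DataFrame / (n, m) array in the rule's marker order (returns an array).
    True = case.
    """

    scalar = False
    if isinstance(values, Mapping):
        row = []
        for mk in rule.markers:
            if mk not in values:
                raise KeyError(f"missing marker value {mk!r}")
            row.append(values[mk])
        arr = np.asarray([row], dtype=float)
        scalar = True
    elif isinstance(values, pd.DataFrame):
        missing = [mk for mk in rule.markers if mk not in values.columns]
        if missing:
            raise KeyError(f"missing marker columns {missing}")
        arr = values.loc[:, list(rule.markers)].to_numpy(dtype=float)
    else:
        arr = np.atleast_2d(np.asarray(values, dtype=float))
    states = binarize(arr, rule.thresholds)
    table = np.asarray(rule.state_to_case, dtype=bool)
    out = table[_state_index(states)]
    return bool(out[0]) if scalar else out


def evaluate_panel(
    rule: PanelRule,
    values: pd.DataFrame | np.ndarray,
    labels: Sequence[bool],
) -> PanelPerformance:
    """Confusion counts of a rule on labeled data (True / 'case' = positive)."""

    y = _as_case_bool(labels)
    if y.size == 0:
        raise ValueError("labeled data must be nonempty")
    pred = classify(rule, values)
    tp = int(np.sum(pred & y))
    fn = int(np.sum(~pred & y))
    fp = int(np.sum(pred & ~y))
    tn = int(np.sum(~pred & ~y))
    return PanelPerformance(tp=tp, fn=fn, fp=fp, tn=tn)


def _as_case_bool(labels: Sequence) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype == bool:
        return y
    if y.dtype.kind in "iu":
        return y.astype(bool)
    return np.isin(y, ("case", "short", "1", "True"))


# ---------------------------------------------------------------------------
# exhaustive search (vectorized over threshold combinations)
# ---------------------------------------------------------------------------


@dataclass
class _SubsetResult:
    """Qualifying panels for one marker subset, in array form."""

    marker_idx: tuple[int, ...]
    thresholds: np.ndarray  # (q, m)
    tables: np.ndarray  # (q, 2**m) bool
    tp: np.ndarray
    tn: np.ndarray


def _gate_block(S, y, n_states, ncase, nctrl, min_sens, min_spec):
    """Majority tables + gate over a block of state arrays (..., n)."""

    cc = np.empty(S.shape[:-1] + (n_states,), dtype=np.int32)
    cn = np.empty_like(cc)
    for s in range(n_states):
        eq = S == s
        cc[..., s] = (eq & y).sum(axis=-1)
        cn[..., s] = (eq & ~y).sum(axis=-1)
    tables = cc > cn
    tp = np.where(tables, cc, 0).sum(axis=-1)
    tn = np.where(~tables, cn, 0).sum(axis=-1)
    ok = (tp >= min_sens * ncase - _EPS) & (tn >= min_spec * nctrl - _EPS)
    return tables, tp, tn, ok


def _scan_subset(
    X: np.ndarray,
    y: np.ndarray,
    subset: tuple[int, ...],
    grids: Sequence[np.ndarray],
    min_sens: float,
    min_spec: float,
) -> _SubsetResult | None:
    m = len(subset)
    n = y.size
    ncase = int(y.sum())
    nctrl = n - ncase
    if ncase == 0 or nctrl == 0:
        return None
    n_states = 1 << m
    B = [X[:, j][None, :] > grids[i][:, None] for i, j in enumerate(subset)]  # (T_i, n)

    thr_list, tab_list, tp_list, tn_list = [], [], [], []

    def collect(ok, tables, tp, tn, thr_arrays):
        if not ok.any():
            return
        where = np.nonzero(ok)
        thr_list.append(np.stack([t[where] for t in thr_arrays], axis=1))
        tab_list.append(tables[where])
        tp_list.append(tp[where])
        tn_list.append(tn[where])

    if m == 1:
        S = B[0].astype(np.int8)
        tables, tp, tn, ok = _gate_block(S, y, n_states, ncase, nctrl, min_sens, min_spec)
        collect(ok, tables, tp, tn, (grids[0],))
    elif m == 2:
        S = (B[0].astype(np.int8)[:, None, :] << 1) + B[1].astype(np.int8)[None, :, :]
        tables, tp, tn, ok = _gate_block(S, y, n_states, ncase, nctrl, min_sens, min_spec)
        g0 = np.broadcast_to(grids[0][:, None], ok.shape)
        g1 = np.broadcast_to(grids[1][None, :], ok.shape)
        collect(ok, tables, tp, tn, (g0, g1))
    else:
        S12 = (B[1].astype(np.int8)[:, None, :] << 1) + B[2].astype(np.int8)[None, :, :]
        for t0 in range(grids[0].size):
            S = S12 + (B[0][t0].astype(np.int8) << 2)[None, None, :]
            tables, tp, tn, ok = _gate_block(S, y, n_states, ncase, nctrl, min_sens, min_spec)
            g0 = np.full(ok.shape, grids[0][t0])
            g1 = np.broadcast_to(grids[1][:, None], ok.shape)
            g2 = np.broadcast_to(grids[2][None, :], ok.shape)
            collect(ok, tables, tp, tn, (g0, g1, g2))

    if not thr_list:
        return None
    return _SubsetResult(
        marker_idx=subset,
        thresholds=np.concatenate(thr_list, axis=0),
        tables=np.concatenate(tab_list, axis=0),
        tp=np.concatenate(tp_list, axis=0),
        tn=np.concatenate(tn_list, axis=0),
    )


def _scan_all(
    X: np.ndarray,
    y: np.ndarray,
    min_sens: float,
    min_spec: float,
    max_markers: int,
    max_candidates: int,
) -> list[_SubsetResult]:
    n_markers = X.shape[1]
    grids_by_marker: dict[int, np.ndarray | None] = {}
    for j in range(n_markers):
        try:
            grids_by_marker[j] = candidate_thresholds(X[:, j], max_candidates)
        except ValueError:
            grids_by_marker[j] = None  # constant marker: no dichotomization
    results = []
    for size in range(1, min(max_markers, MAX_MARKERS, n_markers) + 1):
        for subset in itertools.combinations(range(n_markers), size):
            grids = [grids_by_marker[j] for j in subset]
            if any(g is None for g in grids):
                continue
            res = _scan_subset(X, y, subset, grids, min_sens, min_spec)
            if res is not None:
                results.append(res)
    return results


def _coerce_xy(
    data: pd.DataFrame | np.ndarray,
    labels: Sequence | None,
    markers: Sequence[str] | None,
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    if isinstance(data, pd.DataFrame):
        if markers is None:
            markers = [c for c in data.columns if c not in ("label", "class_label", "patient_id")]
        X = data.loc[:, list(markers)].to_numpy(dtype=float)
        if labels is None:
            col = "label" if "label" in data.columns else "class_label"
            labels = data[col].to_numpy()
    else:
        X = np.atleast_2d(np.asarray(data, dtype=float))
        if markers is None:
            markers = [f"m{j}" for j in range(X.shape[1])]
        if labels is None:
            raise ValueError("labels required with array input")
    y = _as_case_bool(labels)
    if y.size != X.shape[0]:
        raise ValueError("labels length mismatch")
    return X, y, tuple(markers)


def search_panels(
    data: pd.DataFrame | np.ndarray,
    labels: Sequence | None = None,
    markers: Sequence[str] | None = None,
    min_sens: float = MIN_SENSITIVITY,
    min_spec: float = MIN_SPECIFICITY,
    max_markers: int = MAX_MARKERS,
    max_candidates: int = MAX_THRESHOLD_CANDIDATES,
) -> list[PanelRule]:
    """Exhaustive panel search over marker subsets and threshold grids.

    Returns every panel whose majority state rule reaches both training
    minima, ordered by training accuracy (descending) then lexicographically
    by markers and thresholds.  An empty list is a valid outcome.
    """

    X, y, marker_names = _coerce_xy(data, labels, markers)
    ncase = int(y.sum())
    nctrl = y.size - ncase
    if ncase < 2 or nctrl < 2:
        raise ValueError("need at least two patients per class")
    panels: list[PanelRule] = []
    for res in _scan_all(X, y, min_sens, min_spec, max_markers, max_candidates):
        names = tuple(marker_names[j] for j in res.marker_idx)
        for q in range(res.thresholds.shape[0]):
            perf = PanelPerformance(
                tp=int(res.tp[q]),
                fn=ncase - int(res.tp[q]),
                fp=nctrl - int(res.tn[q]),
                tn=int(res.tn[q]),
            )
            panels.append(
                PanelRule(
                    markers=names,
                    thresholds=tuple(float(t) for t in res.thresholds[q]),
                    state_to_case=tuple(bool(b) for b in res.tables[q]),
                    performance=perf,
                )
            )
    panels.sort(key=lambda p: (-p.performance.accuracy, p.markers, p.thresholds))
    return panels


# ---------------------------------------------------------------------------
# cross-validation and nulls
# ---------------------------------------------------------------------------


@dataclass
class CVReport:
    """Per-split accuracies (percent, ``None`` when no panel qualified).

    ``accuracies`` is rounds x splits.  Medians are computed only over the
    splits that produced values; the overall figure is the mean of the
    per-round medians that exist.
    """

    accuracies: list[list[float | None]]
    seed: int | None = None
    n_panels: list[list[int]] | None = None
    label_mode: str = "true"

    @property
    def round_medians(self) -> list[float | None]:
        return [round_median(row) for row in self.accuracies]

    @property
    def overall_average(self) -> float | None:
        return average_of_medians(self.round_medians)

    def to_frame(self, human_dash: bool = False) -> pd.DataFrame:
        k = max((len(r) for r in self.accuracies), default=0)
        cols = [f"Split{i + 1}" for i in range(k)]
        rows = []
        for row in self.accuracies:
            rows.append(list(row) + [None] * (k - len(row)) + [round_median(row)])
        frame = pd.DataFrame(rows, columns=cols + ["Median"])
        frame.insert(0, "Round", [f"Round {i + 1}" for i in range(len(self.accuracies))])
        if human_dash:
            frame = frame.where(frame.notna(), "—")
        return frame

    def to_csv(self, path: str | Path, human_dash: bool = False) -> None:
        self.to_frame(human_dash=human_dash).to_csv(path, index=False)


def round_median(values: Sequence[float | None]) -> float | None:
    """Median over the non-absent split accuracies; None if all are absent."""

    present = [v for v in values if v is not None and not (isinstance(v, float) and np.isnan(v))]
    if not present:
        return None
    return float(np.median(present))


def average_of_medians(medians: Sequence[float | None]) -> float | None:
    """Mean of the per-round medians that exist; None if none exist."""

    present = [m for m in medians if m is not None]
    if not present:
        return None
    return float(np.mean(present))


def _kfold_indices(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Unstratified random partition into k groups of near-equal size."""

    perm = rng.permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(perm, k)]


def _apply_results(
    results: list[_SubsetResult], X_test: np.ndarray, y_test: np.ndarray
) -> tuple[float, int]:
    """Mean held-out accuracy over all qualifying panels, plus panel count."""

    acc_sum = 0.0
    count = 0
    for res in results:
        m = len(res.marker_idx)
        q = res.thresholds.shape[0]
        S = np.zeros((q, X_test.shape[0]), dtype=np.int64)
        for i, j in enumerate(res.marker_idx):
            S += (X_test[:, j][None, :] > res.thresholds[:, i][:, None]).astype(np.int64) << (m - 1 - i)
        pred = np.take_along_axis(res.tables, S, axis=1)
        acc_sum += float((pred == y_test[None, :]).mean(axis=1).sum())
        count += q
    if count == 0:
        return float("nan"), 0
    return acc_sum / count, count


def cross_validate(
    data: pd.DataFrame | np.ndarray,
    labels: Sequence | None = None,
    markers: Sequence[str] | None = None,
    k: int = 10,
    rounds: int = 5,
    min_sens: float = MIN_SENSITIVITY,
    min_spec: float = MIN_SPECIFICITY,
    max_markers: int = MAX_MARKERS,
    max_candidates: int = MAX_THRESHOLD_CANDIDATES,
    seed: int = 0,
    _label_mode: str = "true",
) -> CVReport:
    """k-fold cross-validated panel search, repeated for several rounds.

    Each round draws a fresh random partition.  Per split, every panel
    meeting the training minima is applied to the held-out samples and the
    split accuracy is the unweighted mean of the panels' held-out
    accuracies (percent); a split with no qualifying panel stays absent.
    Fully reproducible from ``seed``.
    """

    X, y, _ = _coerce_xy(data, labels, markers)
    n = y.size
    if k > n:
        raise ValueError("k exceeds the number of samples")
    rng = np.random.default_rng(seed)
    accuracies: list[list[float | None]] = []
    n_panels: list[list[int]] = []
    for _ in range(rounds):
        y_round = y if _label_mode == "true" else rng.random(n) < 0.5
        folds = _kfold_indices(n, k, rng)
        row: list[float | None] = []
        row_panels: list[int] = []
        for test_idx in folds:
            train_mask = np.ones(n, dtype=bool)
            train_mask[test_idx] = False
            ytr = y_round[train_mask]
            if ytr.sum() == 0 or (~ytr).sum() == 0:
                row.append(None)
                row_panels.append(0)
                continue
            results = _scan_all(
                X[train_mask], ytr, min_sens, min_spec, max_markers, max_candidates
            )
            acc, count = _apply_results(results, X[test_idx], y_round[test_idx])
            row.append(None if count == 0 else 100.0 * acc)
            row_panels.append(count)
        accuracies.append(row)
        n_panels.append(row_panels)
    return CVReport(accuracies=accuracies, seed=seed, n_panels=n_panels, label_mode=_label_mode)


def random_label_null(
    data: pd.DataFrame | np.ndarray,
    labels: Sequence | None = None,
    markers: Sequence[str] | None = None,
    k: int = 10,
    rounds: int = 5,
    min_sens: float = MIN_SENSITIVITY,
    min_spec: float = MIN_SPECIFICITY,
    max_markers: int = MAX_MARKERS,
    max_candidates: int = MAX_THRESHOLD_CANDIDATES,
    seed: int = 0,
) -> CVReport:
    """Cross-validation with labels replaced by independent fair coin flips.

    One random assignment is drawn per round (class sizes as drawn, not
    fixed); everything else is identical to :func:`cross_validate`.
    """

    return cross_validate(
        data,
        labels=labels,
        markers=markers,
        k=k,
        rounds=rounds,
        min_sens=min_sens,
        min_spec=min_spec,
        max_markers=max_markers,
        max_candidates=max_candidates,
        seed=seed,
        _label_mode="random",
    )


def panels_to_json(panels: Sequence[PanelRule]) -> list[dict]:
    """JSON-ready representation of panels (markers, thresholds, table, counts)."""

    out = []
    for p in panels:
        entry = {
            "markers": list(p.markers),
            "thresholds": list(p.thresholds),
            "state_to_case": ["case" if b else "control" for b in p.state_to_case],
            "compact_case_rows": [row for row, _ in p.compact_rows()],
        }
        if p.performance is not None:
            perf = p.performance
            entry["training"] = {
                "tp": perf.tp, "fn": perf.fn, "fp": perf.fp, "tn": perf.tn,
                "sensitivity": perf.sensitivity,
                "specificity": perf.specificity,
                "accuracy": perf.accuracy,
            }
        out.append(entry)
    return out
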