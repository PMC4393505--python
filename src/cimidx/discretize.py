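"""Joint feature selection and supervised discretization.

Each feature is discretized independently by greedily adding boundary-point
cuts (midpoints between consecutive sorted values whose class labels differ),
each step choosing the cut that most decreases that feature's inconsistency

    I_f = (1/N) * sum over discrete patterns of (count(pattern) - max class count(pattern)),

until the inconsistency reaches zero, no cut improves it, or ``max_cuts`` is
hit.  A feature is *selected* when both its inconsistency and its cut count
are no worse than the global averages (I_f <= mean I, C_f <= mean C): the
selected, discretized features are the "consistent" features handed to rule
mining.  Selected features map values to (name, interval-index) items via
right-open intervals (a value equal to a cut falls in the right interval).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Hashable, Mapping, Sequence

import numpy as np

from .features import FeatureVector

Item = tuple[str, int] | str


@dataclass
class FeatureScheme:
    name: str
    cuts: list[float]
    inconsistency: float
    selected: bool = False
    vmin: float = 0.0            # training range, used only to warn on clamping
    vmax: float = 0.0

    @property
    def n_cuts(self) -> int:
        return len(self.cuts)


@dataclass
class DiscretizationScheme:
    features: list[FeatureScheme]
    mean_inconsistency: float
    mean_cuts: float

    def __post_init__(self):
        for f in self.features:
            assert all(a < b for a, b in zip(f.cuts, f.cuts[1:])), \
                f"{f.name}: cuts not strictly increasing"
            if f.selected:
                assert f.inconsistency <= self.mean_inconsistency + 1e-12
                assert f.n_cuts <= self.mean_cuts + 1e-12

    @property
    def selected_names(self) -> list[str]:
        return [f.name for f in self.features if f.selected]

    # ----- serialization -----
    def to_json(self, path: str | Path) -> None:
        payload = {
            "mean_inconsistency": self.mean_inconsistency,
            "mean_cuts": self.mean_cuts,
            "features": [{
                "name": f.name, "cuts": f.cuts, "inconsistency": f.inconsistency,
                "selected": f.selected, "vmin": f.vmin, "vmax": f.vmax,
            } for f in self.features],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "DiscretizationScheme":
        d = json.loads(Path(path).read_text())
        feats = [FeatureScheme(**f) for f in d["features"]]
        return cls(features=feats, mean_inconsistency=d["mean_inconsistency"],
                   mean_cuts=d["mean_cuts"])


def _inconsistency(bins: np.ndarray, labels: Sequence[Hashable]) -> float:
    """Pattern/class conflict fraction for one discretized feature."""
    groups: dict[int, dict[Hashable, int]] = {}
    for b, y in zip(bins, labels):
        groups.setdefault(int(b), {}).setdefault(y, 0)
        groups[int(b)][y] += 1
    n = len(labels)
    conflict = sum(sum(cls.values()) - max(cls.values()) for cls in groups.values())
    return conflict / n


def _bin(values: np.ndarray, cuts: Sequence[float]) -> np.ndarray:
    # right-open intervals; a value equal to a cut goes right
    return np.searchsorted(np.asarray(cuts, dtype=float), values, side="right")


def _candidate_cuts(values: np.ndarray, labels: Sequence[Hashable]) -> list[float]:
    """Boundary points: midpoints between consecutive distinct values whose
    label sets differ (or either value carries mixed labels)."""
    order = np.argsort(values, kind="stable")
    v_sorted = values[order]
    distinct: list[float] = []
    lab_sets: list[set] = []
    labels_arr = [labels[i] for i in order]
    k = 0
    while k < len(v_sorted):
        j = k
        labs = set()
        while j < len(v_sorted) and v_sorted[j] == v_sorted[k]:
            labs.add(labels_arr[j])
            j += 1
        distinct.append(v_sorted[k])
        lab_sets.append(labs)
        k = j
    cuts = []
    for a in range(len(distinct) - 1):
        if len(lab_sets[a] | lab_sets[a + 1]) > 1:
            cuts.append((distinct[a] + distinct[a + 1]) / 2.0)
    return cuts


def fit_feature(values: np.ndarray, labels: Sequence[Hashable], max_cuts: int,
                name: str = "") -> FeatureScheme:
    """Greedy boundary-point discretization of one feature (ties on the
    inconsistency drop are broken toward the lower cut value)."""
    values = np.asarray(values, dtype=float)
    cuts: list[float] = []
    current = _inconsistency(np.zeros(len(values), dtype=int), labels)
    candidates = _candidate_cuts(values, labels)
    while current > 0 and len(cuts) < max_cuts and candidates:
        best = None
        for c in candidates:                      # ascending, so ties keep the lower cut
            trial = sorted(cuts + [c])
            inc = _inconsistency(_bin(values, trial), labels)
            if best is None or inc < best[0] - 1e-15:
                best = (inc, c)
        if best is None or best[0] >= current - 1e-15:
            break
        assert best[0] <= current + 1e-12, "adding a cut increased inconsistency"
        current = best[0]
        cuts = sorted(cuts + [best[1]])
        candidates.remove(best[1])
    return FeatureScheme(name=name, cuts=cuts, inconsistency=current,
                         vmin=float(values.min()), vmax=float(values.max()))


def fit_scheme(matrix: np.ndarray, labels: Sequence[Hashable],
               names: Sequence[str] | None = None,
               max_cuts: int = 7) -> DiscretizationScheme:
    """Fit the per-feature discretization and the global selection rule.

    ``matrix`` is (n_samples, n_features); ``labels`` one hashable class label
    per sample (keyword sets should be passed as frozensets).
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("matrix must be 2-D (samples x features)")
    n, p = X.shape
    if len(labels) != n:
        raise ValueError("labels length must match the number of rows")
    if max_cuts < 1:
        raise ValueError("max_cuts must be >= 1")
    labels = [lab if isinstance(lab, Hashable) else frozenset(lab) for lab in labels]
    if names is None:
        names = [f"f{k}" for k in range(p)]

    feats = [fit_feature(X[:, k], labels, max_cuts, name=names[k]) for k in range(p)]
    mean_inc = float(np.mean([f.inconsistency for f in feats]))
    mean_cuts = float(np.mean([f.n_cuts for f in feats]))
    for f in feats:
        f.selected = (f.inconsistency <= mean_inc + 1e-12) and (f.n_cuts <= mean_cuts + 1e-12)
    return DiscretizationScheme(features=feats, mean_inconsistency=mean_inc,
                                mean_cuts=mean_cuts)


def apply_scheme(scheme: DiscretizationScheme,
                 vector: FeatureVector | Mapping[str, float] | Sequence[float],
                 keywords: frozenset[str] = frozenset()) -> frozenset[Item]:
    """Itemize one feature vector: (name, interval index) per selected feature,
    plus the keyword items (training path) or none (test path)."""
    if isinstance(vector, FeatureVector):
        lookup = vector.as_dict()
    elif isinstance(vector, Mapping):
        lookup = dict(vector)
    else:
        vals = np.asarray(vector, dtype=float)
        if len(vals) != len(scheme.features):
            raise ValueError("vector length does not match the scheme")
        lookup = {f.name: float(vals[k]) for k, f in enumerate(scheme.features)}

    items: set[Item] = set()
    for f in scheme.features:
        if not f.selected:
            continue
        v = lookup[f.name]
        if v < f.vmin or v > f.vmax:
            warnings.warn(f"{f.name}: value {v} outside the training range "
                          f"[{f.vmin}, {f.vmax}]; clamped to the edge interval",
                          stacklevel=2)
        idx = int(_bin(np.array([v]), f.cuts)[0])
        items.add((f.name, idx))
    return frozenset(items | set(keywords))
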