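"""End-to-end train and test pipelines.

Training runs pre-processing -> segmentation -> feature extraction ->
discretization (with keywords) -> representative rule mining and returns the
two trained artifacts: a DiscretizationScheme and a RuleBase.  Testing runs
the same image stages, itemizes the vector without keywords, and hands the
itemset to the AMIDE engine.  Both paths can also start from pre-itemized
transaction cohorts, bypassing the image stages.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .amide import Diagnosis, diagnose
from .discretize import DiscretizationScheme, apply_scheme, fit_scheme
from .features import FEATURE_NAMES, extract_all
from .preprocess import NoBreastRegionError, preprocess_image
from .rulemine import RuleBase, mine_rules
from .segment import LevelSetParams, ROISet, detect_edges, op_transform, refine_contour
from .vocab import DEFAULT_VOCABULARY, KeywordVocabulary


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters, each validated against its documented range."""
    srg_tol: float = 16.0
    significance: float = 0.05
    levelset: LevelSetParams = field(default_factory=LevelSetParams)
    max_cuts: int = 7
    minsup: float = 0.05
    minconf: float = 0.8
    alpha: float = 0.5
    delta: float = 0.5
    #: cap on the number of itemized (most consistent) features on the image
    #: path; keeps the pattern tree bounded on dense feature transactions
    max_selected_features: int = 16
    #: bound on mined itemset length (body + head items) on the image path
    mining_max_len: int = 4
    seed: int = 0

    def validate(self) -> None:
        if self.srg_tol <= 0:
            raise ValueError("srg_tol must be positive")
        if not (0 < self.significance < 1):
            raise ValueError("significance must lie in (0, 1)")
        if self.max_cuts < 1:
            raise ValueError("max_cuts must be >= 1")
        if self.max_selected_features < 1:
            raise ValueError("max_selected_features must be >= 1")
        if self.mining_max_len < 2:
            raise ValueError("mining_max_len must be >= 2")
        for nm in ("minsup", "minconf", "alpha", "delta"):
            if not (0 < getattr(self, nm) <= 1):
                raise ValueError(f"{nm} must lie in (0, 1]")
        if self.levelset.dt * self.levelset.mu >= 0.25:
            raise ValueError("levelset: dt * mu must stay below 0.25")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        ls_keys = {f for f in LevelSetParams.__dataclass_fields__}
        known = set(cls.__dataclass_fields__) - {"levelset"}
        unknown = set(d) - known - {"levelset"}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "levelset" in d:
            ls = d.pop("levelset")
            bad = set(ls) - ls_keys
            if bad:
                raise ValueError(f"unknown levelset keys: {sorted(bad)}")
            d["levelset"] = LevelSetParams(**ls)
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class TrainResult:
    scheme: DiscretizationScheme
    rulebase: RuleBase
    feature_table: pd.DataFrame | None = None
    log: dict = field(default_factory=dict)


class StageError(RuntimeError):
    """Wraps a failure with the stage name and the offending input id."""

    def __init__(self, stage: str, input_id: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on input {input_id!r}: {cause}")
        self.stage = stage
        self.input_id = input_id
        self.cause = cause


def segment_image(image: np.ndarray, config: PipelineConfig
                  ) -> tuple[ROISet, np.ndarray, np.ndarray]:
    """Pre-process and segment one image; returns the ROI set, the AOI mask
    and the image, all in canonical (left) orientation."""
    contour, cp, aoi = preprocess_image(image, srg_tol=config.srg_tol)
    planes = op_transform(contour.image, aoi.aoi_mask)
    edges = detect_edges(planes, significance=config.significance)
    edges.edges &= aoi.aoi_mask
    rois = refine_contour(contour.image, edges, params=config.levelset,
                          aoi=aoi.aoi_mask)
    return rois, aoi.aoi_mask, contour.image


def image_features(image: np.ndarray, config: PipelineConfig,
                   input_id: str = "image") -> list[dict[str, float]]:
    """One feature row per segmented ROI (largest first)."""
    try:
        rois, _, canonical = segment_image(image, config)
    except NoBreastRegionError as exc:
        raise StageError("preprocess", input_id, exc) from exc
    rows = []
    for roi in rois:
        try:
            fv = extract_all(canonical, roi.mask)
        except ValueError:
            continue
        rows.append(fv.as_dict())
    return rows


def train_from_transactions(transactions: Sequence[tuple[frozenset, frozenset]],
                            config: PipelineConfig = PipelineConfig(),
                            ) -> TrainResult:
    """Mine a rule base from pre-itemized labeled transactions."""
    config.validate()
    keyword_universe = frozenset(k for _, kws in transactions for k in kws)
    itemsets = [items | kws for items, kws in transactions]
    rb = mine_rules(itemsets, keyword_universe,
                    minsup=config.minsup, minconf=config.minconf)
    log = _run_log(config, n_inputs=len(transactions))
    return TrainResult(scheme=None, rulebase=rb, log=log)


def train_from_images(images_with_keywords: Sequence[tuple[np.ndarray, frozenset[str]]],
                      config: PipelineConfig = PipelineConfig(),
                      vocabulary: KeywordVocabulary = DEFAULT_VOCABULARY,
                      ) -> TrainResult:
    """Full image pipeline: one feature row per (image, largest ROI)."""
    config.validate()
    labels_seen = {frozenset(k) for _, k in images_with_keywords}
    if len(labels_seen) < 2:
        raise ValueError("training requires at least 2 distinct keyword sets")

    rows, row_labels = [], []
    for idx, (img, kws) in enumerate(images_with_keywords):
        vocabulary.validate(kws)
        input_id = f"image{idx}"
        try:
            rois, _, canonical = segment_image(img, config)
        except Exception as exc:
            raise StageError("segment", input_id, exc) from exc
        made_row = False
        for roi in rois:
            try:
                fv = extract_all(canonical, roi.mask)
            except ValueError:
                continue
            rows.append(fv.values)
            row_labels.append(frozenset(kws))
            made_row = True
            break                       # largest suitable ROI represents the image
        if not made_row:
            warnings.warn(f"{input_id}: no usable ROI; image skipped", stacklevel=2)

    if len({lab for lab in row_labels}) < 2:
        raise StageError("features", "cohort", ValueError(
            "fewer than 2 classes survived segmentation"))

    X = np.vstack(rows)
    scheme = fit_scheme(X, row_labels, names=list(FEATURE_NAMES),
                        max_cuts=config.max_cuts)
    _cap_selected(scheme, config.max_selected_features)
    transactions = [apply_scheme(scheme, row, keywords=lab)
                    for row, lab in zip(rows, row_labels)]
    keyword_universe = frozenset(k for lab in row_labels for k in lab)
    rb = mine_rules(transactions, keyword_universe,
                    minsup=config.minsup, minconf=config.minconf,
                    max_len=config.mining_max_len)

    table = pd.DataFrame(X, columns=list(FEATURE_NAMES))
    table["keywords"] = ["|".join(sorted(lab)) for lab in row_labels]
    return TrainResult(scheme=scheme, rulebase=rb, feature_table=table,
                       log=_run_log(config, n_inputs=len(images_with_keywords)))


def diagnose_transaction(items: frozenset, rulebase: RuleBase,
                     config: PipelineConfig = PipelineConfig()) -> Diagnosis:
    """Diagnose one pre-itemized test itemset."""
    config.validate()
    return diagnose(rulebase, frozenset(items), alpha=config.alpha, delta=config.delta)


def diagnose_image(image: np.ndarray, scheme: DiscretizationScheme, rulebase: RuleBase,
               config: PipelineConfig = PipelineConfig()) -> list[Diagnosis]:
    """Diagnose a new image: one report per usable ROI (no keywords supplied)."""
    config.validate()
    known = set(rulebase.items)
    for f in scheme.features:
        if f.selected:
            break
    else:
        raise ValueError("scheme selects no features; artifacts are inconsistent")
    rois, _, canonical = segment_image(image, config)
    reports = []
    for roi in rois:
        try:
            fv = extract_all(canonical, roi.mask)
        except ValueError:
            continue
        items = apply_scheme(scheme, fv)
        if known and not (items & known) and items:
            warnings.warn("test itemset shares no items with the rule base vocabulary",
                          stacklevel=2)
        reports.append(diagnose(rulebase, items, alpha=config.alpha, delta=config.delta))
    return reports


def _cap_selected(scheme, cap: int) -> None:
    """Keep only the ``cap`` most consistent selected features (lowest
    inconsistency, then fewest cuts, then name) so the itemized transactions
    stay narrow enough for bounded pattern-tree mining."""
    selected = [f for f in scheme.features if f.selected]
    if len(selected) <= cap:
        return
    selected.sort(key=lambda f: (f.inconsistency, f.n_cuts, f.name))
    keep = {f.name for f in selected[:cap]}
    for f in scheme.features:
        if f.selected and f.name not in keep:
            f.selected = False


def _run_log(config: PipelineConfig, n_inputs: int) -> dict:
    return {
        "tool": "cimidx",
        "version": __version__,
        "config": asdict(config),
        "config_hash": config.digest(),
        "seed": config.seed,
        "n_inputs": n_inputs,
    }
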