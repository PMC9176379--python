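"""Whole-body composition prediction from regional optical fractions.

DXA fat% (or lean-soft-tissue %) is regressed on the optical fat fraction
(or optical lean fraction) of the four anatomical regions — biceps, abdomen,
quadriceps, calf — using a Gaussian identity-link generalized linear model
(ordinary least squares) with an intercept.  The model is trained on a
randomly assigned 80% of participants and evaluated on the held-out 20%
with a Bland-Altman analysis; predictors are on the percent (0-100) scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .composition_metrics import DXARecord, REGIONS, RegionSummary
from .satt_model import BlandAltman, bland_altman

__all__ = [
    "BodyCompModel",
    "LeakageError",
    "MissingRegionError",
    "split_participants",
    "regions_to_frame",
    "dxa_to_frame",
    "fit_bodycomp",
    "predict_bodycomp",
    "evaluate_bodycomp",
]

_TARGET_PREDICTOR = {"fat_pct": "off", "lst_pct": "olf"}


class MissingRegionError(ValueError):
    """A participant lacks one or more of the four regional summaries."""

    def __init__(self, missing: dict):
        self.missing = missing
        super().__init__(f"participants with missing regions: {missing}")


class LeakageError(ValueError):
    """Evaluation set overlaps the training set."""


@dataclass(frozen=True)
class BodyCompModel:
    """Linear model: target = intercept + sum_r coef[r] * predictor_r."""

    target: str  # "fat_pct" or "lst_pct"
    intercept: float
    coefficients: dict  # region -> coefficient
    train_ids: tuple
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.target not in _TARGET_PREDICTOR:
            raise ValueError("target must be 'fat_pct' or 'lst_pct'")
        if set(self.coefficients) != set(REGIONS):
            raise ValueError("need exactly one coefficient per region")

    @property
    def predictor(self) -> str:
        return _TARGET_PREDICTOR[self.target]


def regions_to_frame(summaries: Iterable[RegionSummary]) -> pd.DataFrame:
    """Long table (participant_id, region, off, olf) from RegionSummary objects."""
    return pd.DataFrame(
        {
            "participant_id": s.participant_id,
            "region": s.region,
            "off": s.off,
            "olf": s.olf,
        }
        for s in summaries
    )


def dxa_to_frame(records: Iterable[DXARecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant_id": r.participant_id,
            "fat_pct": r.fat_pct,
            "lst_pct": r.lst_pct,
            "bone_pct": r.bone_pct,
        }
        for r in records
    )


def split_participants(
    ids: Sequence, seed: int, train_fraction: float = 0.8
) -> tuple[tuple, tuple]:
    """Seeded random train/test split of participant ids (default 80/20)."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    ids = sorted(map(str, ids))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_train = int(round(train_fraction * len(ids)))
    train = tuple(sorted(ids[i] for i in perm[:n_train]))
    test = tuple(sorted(ids[i] for i in perm[n_train:]))
    return train, test


def _wide_predictors(regions: pd.DataFrame, predictor: str) -> pd.DataFrame:
    wide = regions.pivot_table(
        index="participant_id", columns="region", values=predictor, aggfunc="mean"
    )
    wide.index = wide.index.astype(str)
    return wide


def fit_bodycomp(
    regions: pd.DataFrame,
    dxa: pd.DataFrame,
    target: str = "fat_pct",
    seed: int | None = None,
    train_ids: Sequence | None = None,
    train_fraction: float = 0.8,
) -> BodyCompModel:
    """Fit the four-region linear model on the training split.

    ``regions`` is a long table (participant_id, region, off, olf); ``dxa``
    has participant_id plus fat_pct/lst_pct columns.  Either pass explicit
    ``train_ids`` or a ``seed`` for the random 80/20 split.  Every training
    participant must have all four regional summaries and a DXA record.
    """
    predictor = _TARGET_PREDICTOR.get(target)
    if predictor is None:
        raise ValueError("target must be 'fat_pct' or 'lst_pct'")
    dxa = dxa.copy()
    dxa["participant_id"] = dxa["participant_id"].astype(str)
    wide = _wide_predictors(regions, predictor)

    all_ids = sorted(set(wide.index) & set(dxa["participant_id"]))
    if train_ids is None:
        if seed is None:
            raise ValueError("pass either train_ids or a seed")
        train_ids, _ = split_participants(all_ids, seed, train_fraction)
    train_ids = tuple(sorted(map(str, train_ids)))

    missing = {}
    for pid in train_ids:
        if pid not in wide.index:
            missing[pid] = list(REGIONS)
            continue
        absent = [r for r in REGIONS if pd.isna(wide.loc[pid].get(r, np.nan))]
        if absent:
            missing[pid] = absent
    if missing:
        raise MissingRegionError(missing)

    X = wide.loc[list(train_ids), list(REGIONS)].to_numpy()
    y = (
        dxa.set_index("participant_id")
        .loc[list(train_ids), target]
        .to_numpy(dtype=float)
    )
    # Gaussian identity-link GLM == ordinary least squares; OLS also handles
    # the degenerate constant-target case gracefully
    fit = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
    params = np.asarray(fit.params, float)
    return BodyCompModel(
        target=target,
        intercept=float(params[0]),
        coefficients={r: float(c) for r, c in zip(REGIONS, params[1:])},
        train_ids=train_ids,
        seed=seed,
    )


def predict_bodycomp(
    model: BodyCompModel, regions, return_flag: bool = False
):
    """Predict the target percent for one participant.

    ``regions`` maps region name to the predictor value (OFF for fat%, OLF
    for LST%), e.g. ``{"biceps": 12.0, "abdomen": 30.0, ...}``.  Output is
    clamped to the reportable [0, 100] range; ``return_flag=True`` also
    reports whether clamping occurred.
    """
    if isinstance(regions, RegionSummary):
        regions = {regions.region: getattr(regions, model.predictor)}
    missing = [r for r in REGIONS if r not in regions or pd.isna(regions[r])]
    if missing:
        raise MissingRegionError({"<participant>": missing})
    raw = model.intercept + sum(
        model.coefficients[r] * float(regions[r]) for r in REGIONS
    )
    clamped = float(np.clip(raw, 0.0, 100.0))
    if return_flag:
        return clamped, clamped != raw
    return clamped


def evaluate_bodycomp(
    model: BodyCompModel,
    regions: pd.DataFrame,
    dxa: pd.DataFrame,
    test_ids: Sequence | None = None,
) -> BlandAltman:
    """Bland-Altman of model predictions vs DXA on held-out participants.

    Raises :class:`LeakageError` if any evaluated participant was in the
    training set.
    """
    dxa = dxa.copy()
    dxa["participant_id"] = dxa["participant_id"].astype(str)
    wide = _wide_predictors(regions, model.predictor)
    if test_ids is None:
        test_ids = sorted(
            (set(wide.index) & set(dxa["participant_id"])) - set(model.train_ids)
        )
    test_ids = tuple(sorted(map(str, test_ids)))
    overlap = set(test_ids) & set(model.train_ids)
    if overlap:
        raise LeakageError(f"test participants appear in training set: {sorted(overlap)}")
    if not test_ids:
        raise ValueError("no held-out participants to evaluate")

    dxa_idx = dxa.set_index("participant_id")
    predicted, measured = [], []
    for pid in test_ids:
        row = wide.loc[pid]
        predicted.append(predict_bodycomp(model, {r: row[r] for r in REGIONS}))
        measured.append(float(dxa_idx.loc[pid, model.target]))
    return bland_altman(predicted, measured)
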