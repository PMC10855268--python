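"""Backward-elimination PLS-DA (BE-PLS-DA).

Iteratively fit a PLS-DA (latent-variable count chosen by paired
venetian-blind cross-validation), score every feature with VIP on the
full-data fit, remove the minimum-VIP feature, and record the CV errors.
The retained set at the cycle with the best cross-validated prediction
error is selected and the final model refit on it. Selection uses the
continuous prediction error (RMSECV): the classification error is a step
function that ties at zero over long stretches of the trace whenever the
classes separate cleanly, whereas the RMSECV keeps falling while noise
variables are removed and rises again once informative ones go, giving a
well-defined optimum.

By default one feature is removed per cycle, making the trace exhaustive
down to a single feature. For wide matrices a percent-elimination mode
removes the bottom fraction of features per cycle until a floor is
reached, then proceeds one at a time; the trace (and possibly the
selection) can differ from exhaustive single elimination.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .plsda import (CVResult, PLSDAError, PLSDAModel, fit_autoscaled,
                    plsda_predict, venetian_blind_cv, vip)
from .preprocess import FusedDataset, OmicsBlock, fuse

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BEConfig:
    max_lv: int = 5
    #: fraction of features removed per cycle while more than
    #: ``drop_floor`` remain; 0 disables percent elimination
    drop_fraction: float = 0.0
    drop_floor: int = 100

    def __post_init__(self) -> None:
        if not 0.0 <= self.drop_fraction < 1.0:
            raise ValueError("drop_fraction must be in [0, 1)")


@dataclass
class BEPLSDAModel:
    """Result of a BE-PLS-DA run."""

    selected_features: list[str]
    blocks: pd.Series  # selected feature -> block name
    model: PLSDAModel  # final refit on the selected set
    trace: pd.DataFrame  # one row per elimination cycle
    cv: CVResult  # CV of the final refit
    accuracy_cal: float  # percent
    accuracy_cv: float  # percent

    def selected_counts(self) -> pd.Series:
        """Number of selected features per block."""
        return self.blocks.value_counts().sort_index()


def _cycle_vips(X: pd.DataFrame, y: pd.Series, n_lv: int) -> pd.Series:
    model = fit_autoscaled(X, y, n_lv)
    return vip(model)


def be_plsda(fused: FusedDataset, y: pd.Series,
             config: BEConfig | None = None) -> BEPLSDAModel:
    """Run backward-elimination PLS-DA on a fused, pair-centered dataset.

    ``fused.data`` must be pair-centered but unscaled: the global fit
    autoscales over all samples, while CV re-estimates the scaling inside
    every fold. Fully deterministic: VIP ties are broken toward the
    lexicographically smallest feature id and CV-error ties toward fewer
    features.
    """
    config = config or BEConfig()
    X_all = fused.data
    if X_all.shape[1] < 1:
        raise PLSDAError("empty feature matrix")
    y = y.reindex(X_all.index)
    if y.isna().any():
        raise PLSDAError("class vector does not cover all samples")

    retained = list(X_all.columns)
    rows = []
    retained_sets: list[list[str]] = []
    while True:
        X = X_all[retained]
        cvr = venetian_blind_cv(X, y, fused.pairing, config.max_lv)
        rows.append({
            "n_retained": len(retained),
            "cv_error": cvr.error,
            "rmsecv": cvr.rmsecv,
            "n_lv": cvr.best_nlv,
        })
        retained_sets.append(list(retained))
        if len(retained) == 1:
            rows[-1].update(removed="", removed_vip=np.nan, n_removed=0)
            break
        vips = _cycle_vips(X, y, cvr.best_nlv)
        if not np.isfinite(vips.to_numpy()).all():
            bad = vips.index[~np.isfinite(vips.to_numpy())][0]
            raise PLSDAError(f"non-finite VIP for feature {bad!r}")
        if (config.drop_fraction > 0
                and len(retained) > config.drop_floor):
            k = max(1, int(len(retained) * config.drop_fraction))
            k = min(k, len(retained) - max(1, config.drop_floor))
        else:
            k = 1
        # sort by (VIP, feature id): deterministic minimum-VIP removal
        order = sorted(vips.items(), key=lambda kv: (kv[1], kv[0]))
        removed = [fid for fid, _ in order[:k]]
        rows[-1].update(removed=removed[0] if k == 1 else ";".join(removed),
                        removed_vip=float(order[0][1]), n_removed=k)
        drop = set(removed)
        retained = [f for f in retained if f not in drop]

    trace = pd.DataFrame(rows)
    # best cycle: lowest continuous CV prediction error (RMSECV), which is
    # essentially never tied; residual ties break toward the smallest
    # retained set, then lowest classification error
    best = trace.sort_values(["rmsecv", "n_retained", "cv_error"],
                             kind="stable").index[0]
    selected = retained_sets[best]

    Xs = X_all[selected]
    final_cv = venetian_blind_cv(Xs, y, fused.pairing, config.max_lv)
    model = fit_autoscaled(Xs, y, final_cv.best_nlv)
    labels = plsda_predict(model, Xs)
    acc_cal = 100.0 * float(np.mean(labels == np.sign(y.to_numpy())))
    return BEPLSDAModel(
        selected_features=selected,
        blocks=fused.block_index.reindex(selected),
        model=model,
        trace=trace,
        cv=final_cv,
        accuracy_cal=acc_cal,
        accuracy_cv=final_cv.accuracy_cv,
    )


def single_source_be(block: OmicsBlock, design: pd.DataFrame, y: pd.Series,
                     config: BEConfig | None = None) -> BEPLSDAModel:
    """BE-PLS-DA on one pair-centered block alone (single-source model)."""
    fused = fuse([block], design)
    return be_plsda(fused, y, config)


def coefficient_report(model: BEPLSDAModel) -> pd.DataFrame:
    """Signed coefficient table for the selected features.

    The direction column reads the regression coefficient through the
    class coding: a feature whose coefficient pushes predictions toward
    the treated class increases after treatment.
    """
    final = model.model
    vips = vip(final)
    treated_sign = np.sign(final.y_coding["treated"])
    coef = pd.Series(final.coefficients, index=final.feature_ids)
    rows = pd.DataFrame({
        "block": model.blocks.reindex(final.feature_ids),
        "coefficient": coef,
        "VIP": vips,
    })
    rows["direction"] = np.where(coef * treated_sign > 0,
                                 "increase", "decrease")
    rows = rows.sort_values(
        ["block", "coefficient"],
        key=lambda s: -s.abs() if s.name == "coefficient" else s,
        kind="stable")
    rows.index.name = "feature"
    return rows
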