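"""Elastic-net prediction of metabolite usage from reaction frequencies.

The metabolic niche of a lineage is summarized by how often each external
metabolite is imported by its sampled panEFMs.  Because reaction
frequencies are observable from genomes while metabolite usage is not, a
multi-output elastic net is trained on (reaction frequency -> metabolite
usage) pairs across growth-supporting environments and then applied to
natural or simulated reaction frequencies to infer the niche.

Each metabolite is fit as an independent elastic net sharing the same
5-fold cross-validation splits; inputs are standardized per feature and
predictions are clipped back to [0, 1] (frequencies are proportions).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold, cross_val_predict

DEFAULT_L1_RATIOS = (0.1, 0.5, 0.9)
DEFAULT_N_ALPHAS = 50
CV_FOLDS = 5


@dataclass
class NicheModel:
    """Fitted multi-output elastic net (affine map on frequency vectors)."""

    feature_ids: List[str]
    target_ids: List[str]
    coef: np.ndarray          # (n_features, n_targets), on standardized X
    intercept: np.ndarray     # (n_targets,)
    x_mean: np.ndarray
    x_scale: np.ndarray
    cv_r: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    l1_ratio: Dict[str, float] = field(default_factory=dict)
    alpha: Dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def predict_frame(self, X: pd.DataFrame) -> pd.DataFrame:
        Z = (X[self.feature_ids].to_numpy(float) - self.x_mean) / self.x_scale
        Y = Z @ self.coef + self.intercept
        return pd.DataFrame(
            np.clip(Y, 0.0, 1.0), index=X.index, columns=self.target_ids
        )

    # -- persistence ---------------------------------------------------------

    def save(self, path: Union[str, Path]) -> None:
        path = Path(path)
        payload = {
            "feature_ids": self.feature_ids,
            "target_ids": self.target_ids,
            "coef": self.coef.tolist(),
            "intercept": self.intercept.tolist(),
            "x_mean": self.x_mean.tolist(),
            "x_scale": self.x_scale.tolist(),
            "cv_r": {k: (None if pd.isna(v) else float(v))
                     for k, v in self.cv_r.items()},
            "l1_ratio": self.l1_ratio,
            "alpha": self.alpha,
            "seed": self.seed,
        }
        path.write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path: Union[str, Path]) -> "NicheModel":
        d = json.loads(Path(path).read_text())
        return cls(
            d["feature_ids"],
            d["target_ids"],
            np.asarray(d["coef"], float),
            np.asarray(d["intercept"], float),
            np.asarray(d["x_mean"], float),
            np.asarray(d["x_scale"], float),
            pd.Series({k: (np.nan if v is None else v)
                       for k, v in d["cv_r"].items()}, dtype=float),
            d["l1_ratio"],
            d["alpha"],
            d["seed"],
        )


def train_niche_model(
    reaction_freq: pd.DataFrame,
    metabolite_freq: pd.DataFrame,
    seed: int = 0,
    l1_ratios: Sequence[float] = DEFAULT_L1_RATIOS,
    n_alphas: int = DEFAULT_N_ALPHAS,
    cv_folds: int = CV_FOLDS,
) -> NicheModel:
    """Fit per-metabolite elastic nets with shared CV splits.

    For every metabolite column the regularization path (``n_alphas`` alphas
    x ``l1_ratios``) is searched by ``cv_folds``-fold cross-validation; the
    reported ``cv_r`` is the held-out Pearson correlation of the selected
    model, computed with the same folds.  Constant targets get an
    intercept-only model with undefined (NaN) held-out correlation.
    """
    if not reaction_freq.index.equals(metabolite_freq.index):
        raise ValueError("environment rows of the two matrices do not match")
    n = len(reaction_freq)
    if n < 2 * cv_folds:
        raise ValueError(
            f"{n} rows is too few for {cv_folds}-fold cross-validation"
        )
    feats = list(reaction_freq.columns)
    targets = list(metabolite_freq.columns)
    X = reaction_freq.to_numpy(float)
    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0, ddof=0)
    x_scale[x_scale == 0.0] = 1.0
    Z = (X - x_mean) / x_scale
    folds = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    coef = np.zeros((len(feats), len(targets)))
    intercept = np.zeros(len(targets))
    cv_r: Dict[str, float] = {}
    l1_sel: Dict[str, float] = {}
    alpha_sel: Dict[str, float] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for j, tgt in enumerate(targets):
            y = metabolite_freq[tgt].to_numpy(float)
            if np.std(y) == 0.0:
                intercept[j] = y.mean()
                cv_r[tgt] = np.nan
                continue
            search = ElasticNetCV(
                l1_ratio=list(l1_ratios),
                alphas=n_alphas,
                cv=folds,
                random_state=seed,
                max_iter=5000,
            )
            search.fit(Z, y)
            coef[:, j] = search.coef_
            intercept[j] = search.intercept_
            l1_sel[tgt] = float(search.l1_ratio_)
            alpha_sel[tgt] = float(search.alpha_)
            best = ElasticNet(
                alpha=search.alpha_,
                l1_ratio=search.l1_ratio_,
                random_state=seed,
                max_iter=5000,
            )
            pred = cross_val_predict(best, Z, y, cv=folds)
            if np.std(pred) > 1e-12:
                cv_r[tgt] = float(sps.pearsonr(y, pred)[0])
            else:
                cv_r[tgt] = np.nan
    return NicheModel(
        feats,
        targets,
        coef,
        intercept,
        x_mean,
        x_scale,
        pd.Series(cv_r, dtype=float),
        l1_sel,
        alpha_sel,
        seed,
    )


def predict_niche(
    model: NicheModel,
    frequencies: Union[Mapping[str, float], pd.Series],
) -> pd.Series:
    """Predict a metabolite-usage profile from one reaction-frequency vector.

    Features missing from the input are treated as frequency 0 (with a
    warning); the affine prediction is clipped to [0, 1].
    """
    freqs = dict(frequencies)
    if not freqs:
        raise ValueError("empty frequency vector")
    missing = [f for f in model.feature_ids if f not in freqs]
    if missing:
        warnings.warn(
            f"{len(missing)} model features missing from input; assuming 0",
            stacklevel=2,
        )
    row = pd.DataFrame(
        [[float(freqs.get(f, 0.0)) for f in model.feature_ids]],
        columns=model.feature_ids,
    )
    return model.predict_frame(row).iloc[0].rename(None)
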