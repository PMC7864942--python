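"""Clinical-table preprocessing: from a mixed-type EHR table to the
normalized numeric matrix the autoencoder consumes.

The encoding convention places every feature on the range [1, 2]:
quantitative features are min-max mapped (train min -> 1, train max -> 2),
binary features become {1, 2}, and categorical features are one-hot
expanded with the active level at 2 and the rest at 1. Features missing in
more than 70% of *training* rows are discarded; remaining missing cells are
imputed with the training median (quantitative) or mode (binary /
categorical) so the downstream autoencoder never sees a hole. All fitted
statistics come from the training rows alone — no test-row leakage.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import RawEHRTable


@dataclass
class EHRTransformState:
    """Fitted per-feature statistics, JSON-serializable for reproducibility."""

    missing_threshold: float
    kept: list[str]
    kinds: dict[str, str]
    medians: dict[str, float]
    minmax: dict[str, tuple[float, float]]
    modes: dict[str, object]
    levels: dict[str, list]
    degenerate: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, default=str, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "EHRTransformState":
        d = json.loads(text)
        d["minmax"] = {k: tuple(v) for k, v in d["minmax"].items()}
        return cls(**d)


@dataclass
class EHRMatrix:
    """Patients x features matrix with every value in [1, 2], no missing."""

    values: pd.DataFrame
    state: EHRTransformState

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    def to_array(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


class EHRTransformer(TransformerMixin, BaseEstimator):
    """Scikit-learn-style transformer implementing the encoding above.

    Parameters
    ----------
    missing_threshold : float, default 0.70
        Features whose training-row missing fraction strictly exceeds this
        are dropped (a feature missing in exactly 70% of rows is retained).
    """

    def __init__(self, missing_threshold: float = 0.70):
        self.missing_threshold = missing_threshold

    def fit(self, table: RawEHRTable, y=None, train_rows=None):
        if train_rows is None:
            train_rows = list(table.values.index)
        train_rows = list(train_rows)
        if len(train_rows) == 0:
            raise ValueError("train_rows must be non-empty")
        vals = table.values.loc[train_rows]
        miss = table.missing.loc[train_rows]

        kept, kinds = [], {}
        medians, minmax, modes, levels, degenerate = {}, {}, {}, {}, []
        for col in table.values.columns:
            if miss[col].mean() > self.missing_threshold:
                continue
            kind = table.schema[col]
            observed = vals[col][~miss[col]]
            kept.append(col)
            kinds[col] = kind
            if kind == "quantitative":
                obs = observed.astype(float)
                med = float(obs.median()) if len(obs) else 1.5
                lo = float(obs.min()) if len(obs) else 0.0
                hi = float(obs.max()) if len(obs) else 0.0
                medians[col] = med
                minmax[col] = (lo, hi)
                if hi <= lo:
                    degenerate.append(col)
            elif kind == "binary":
                modes[col] = float(observed.mode().iloc[0]) if len(observed) else 0.0
            else:  # categorical
                lv = sorted(observed.dropna().astype(str).unique().tolist())
                levels[col] = lv
                modes[col] = lv[0] if lv else ""
                mode_series = observed.astype(str).mode()
                if len(mode_series):
                    modes[col] = str(mode_series.iloc[0])
        if not kept:
            raise ValueError("every feature exceeded the missing-value threshold")

        self.state_ = EHRTransformState(
            missing_threshold=self.missing_threshold,
            kept=kept, kinds=kinds, medians=medians, minmax=minmax,
            modes=modes, levels=levels, degenerate=degenerate,
        )
        return self

    def transform(self, table: RawEHRTable) -> EHRMatrix:
        st = self._check_fitted()
        cols = {}
        for col in st.kept:
            vals = table.values[col]
            miss = table.missing[col]
            kind = st.kinds[col]
            if kind == "quantitative":
                x = vals.astype(float).where(~miss, st.medians[col]).astype(float)
                lo, hi = st.minmax[col]
                if hi <= lo:  # constant on train: map to the band midpoint
                    cols[col] = pd.Series(1.5, index=vals.index)
                else:
                    cols[col] = (1.0 + (x - lo) / (hi - lo)).clip(1.0, 2.0)
            elif kind == "binary":
                x = vals.astype(float).where(~miss, st.modes[col])
                cols[col] = 1.0 + x.astype(float)  # 0 -> 1, 1 -> 2
            else:
                filled = vals.astype(object).where(~miss, st.modes[col]).astype(str)
                known = set(st.levels[col])
                unseen = sorted(set(filled.unique()) - known)
                if unseen:
                    warnings.warn(
                        f"column {col!r}: unseen categorical level(s) {unseen} "
                        "encoded as all-reference (every indicator at 1)"
                    )
                for lv in st.levels[col]:
                    cols[f"{col}={lv}"] = pd.Series(
                        np.where(filled.to_numpy() == lv, 2.0, 1.0), index=vals.index
                    )
        out = pd.DataFrame(cols, index=table.values.index)
        return EHRMatrix(values=out, state=st)

    def _check_fitted(self) -> EHRTransformState:
        if not hasattr(self, "state_"):
            raise RuntimeError("EHRTransformer is not fitted")
        return self.state_


def fit_ehr_transform(table: RawEHRTable, train_rows, missing_threshold=0.70):
    """Fit the transform on the given training rows; returns the state."""
    return EHRTransformer(missing_threshold).fit(table, train_rows=train_rows).state_


def apply_ehr_transform(table: RawEHRTable, state: EHRTransformState) -> EHRMatrix:
    t = EHRTransformer(state.missing_threshold)
    t.state_ = state
    return t.transform(table)


def to_unit_interval(x: np.ndarray) -> np.ndarray:
    """Affine [1,2] -> [0,1] map used before the autoencoder (inverse: x+1)."""
    return np.asarray(x, dtype=float) - 1.0
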