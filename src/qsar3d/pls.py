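"""PLS modelling of field matrices against pIC50.

The central object is :class:`PLSQsarRegressor`, a scikit-learn style
estimator wrapping the canonical CoMFA/CoMSIA fitting protocol:

1. column filtering — grid columns whose standard deviation falls below a
   minimum-sigma threshold (default 2.00 kcal/mol) are dropped, once, on
   the full training matrix (per-fold refiltering is available as a flag);
2. block scaling — each field block is scaled to equal total variance so
   no field dominates the latent decomposition by sheer magnitude;
3. PLS regression (NIPALS, via sklearn's ``PLSRegression`` with
   ``scale=False``; X and y are mean-centred inside the fit);
4. leave-one-out cross-validation — q² = 1 − PRESS/TSS, SEP =
   sqrt(PRESS/(n − c − 1)) — used both to report predictivity and to pick
   the optimal number of components (ONC), ties broken toward fewer;
5. training statistics — r², SEE = sqrt(RSS/(n − c − 1)),
   F = [r²/(1 − r²)]·[(n − c − 1)/c] — and per-block field-contribution
   fractions Σ|coef_j|·sd_j normalised over blocks.

Residuals follow the single convention experimental − predicted.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .fields import FieldBlock, Grid, write_cube
from .io import CompoundRecord

logger = logging.getLogger(__name__)

_EPS = 1e-12


# ---------------------------------------------------------------------------
# column filtering


def column_filter(X: np.ndarray, min_sigma: float) -> np.ndarray:
    """Boolean mask of columns whose sample sd is >= ``min_sigma`` (inclusive)."""
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("X must be finite")
    sd = X.std(axis=0, ddof=1)
    mask = sd >= (min_sigma - _EPS)
    if not mask.any():
        raise ValueError(
            f"column filter at min_sigma={min_sigma} removed every column; "
            "lower the threshold"
        )
    return mask


class ColumnVarianceFilter(BaseEstimator):
    """Transformer dropping low-variance grid columns (minimum-sigma filter)."""

    def __init__(self, min_sigma: float = 2.0):
        self.min_sigma = min_sigma

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        self.n_features_in_ = X.shape[1]
        self.mask_ = column_filter(X, self.min_sigma)
        return self

    def transform(self, X):
        check_is_fitted(self, "mask_")
        X = check_array(X, dtype=float)
        return X[:, self.mask_]

    def fit_transform(self, X, y=None, **kwargs):
        return self.fit(X, y).transform(X)

    def get_support(self) -> np.ndarray:
        check_is_fitted(self, "mask_")
        return self.mask_


# ---------------------------------------------------------------------------
# internals shared by the estimator and the functional wrappers


def _block_scales(Xf: np.ndarray, block_index: Optional[np.ndarray]) -> np.ndarray:
    """Per-column multipliers giving each block unit total column variance."""
    scales = np.ones(Xf.shape[1])
    if block_index is None:
        return scales
    for b in np.unique(block_index):
        cols = block_index == b
        total_var = Xf[:, cols].var(axis=0, ddof=1).sum()
        if total_var > _EPS:
            scales[cols] = 1.0 / np.sqrt(total_var)
    return scales


def _max_valid_components(n_samples: int, n_cols: int) -> int:
    # LOO folds have n-1 samples, and centring costs one more degree
    return max(1, min(n_samples - 2, n_cols))


def _fit_raw_pls(Xs: np.ndarray, y: np.ndarray, c: int) -> PLSRegression:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return PLSRegression(n_components=c, scale=False).fit(Xs, y)


def _loo_predictions(Xs: np.ndarray, y: np.ndarray, c: int) -> np.ndarray:
    """Out-of-fold predictions from n explicit leave-one-out refits."""
    n = len(y)
    preds = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        model = _fit_raw_pls(Xs[keep], y[keep], c)
        preds[i] = float(model.predict(Xs[i][None, :]).ravel()[0])
    return preds


def _press_stats(y: np.ndarray, preds: np.ndarray, c: int) -> Tuple[float, float, float]:
    press = float(np.sum((y - preds) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    q2 = 1.0 - press / tss
    dof = len(y) - c - 1
    sep = float(np.sqrt(press / dof)) if dof > 0 else float("nan")
    return q2, sep, press


# ---------------------------------------------------------------------------
# the estimator


class PLSQsarRegressor(RegressorMixin, BaseEstimator):
    """PLS regression of a grid-field matrix on activity, CoMFA-style.

    Parameters
    ----------
    n_components : int or None
        Latent components. ``None`` selects the ONC by maximising the
        LOO q² over ``1..max_components`` (ties toward fewer components).
    max_components : int
        Upper bound of the ONC search.
    min_sigma : float
        Column-filter threshold in the units of X (kcal/mol for CoMFA);
        0 disables filtering.
    block_scale : bool
        Scale each field block (as given by ``block_index`` at fit time)
        to equal total variance before the decomposition.
    refilter_per_fold : bool
        Re-run the column filter inside every LOO fold instead of fixing
        the mask on the full training matrix (off by default, matching
        the conventional protocol).

    Attributes (after fit)
    ----------------------
    column_mask_, col_scale_, n_components_, component_q2_, q2_, sep_,
    press_, r2_, see_, f_value_, coef_, stdev_coef_, field_fractions_
    """

    def __init__(
        self,
        n_components: Optional[int] = None,
        max_components: int = 10,
        min_sigma: float = 2.0,
        block_scale: bool = True,
        refilter_per_fold: bool = False,
    ):
        self.n_components = n_components
        self.max_components = max_components
        self.min_sigma = min_sigma
        self.block_scale = block_scale
        self.refilter_per_fold = refilter_per_fold

    # -- fitting ----------------------------------------------------------

    def fit(self, X, y, block_index: Optional[np.ndarray] = None):
        X, y = check_X_y(X, y, y_numeric=True)
        y = y.astype(float)
        n, p = X.shape
        if n < 3:
            raise ValueError("need at least 3 samples")
        self.n_features_in_ = p
        self.block_index_ = (
            np.asarray(block_index, dtype=int) if block_index is not None else None
        )

        mask = (
            column_filter(X, self.min_sigma)
            if self.min_sigma > 0
            else np.ones(p, dtype=bool)
        )
        self.column_mask_ = mask
        Xf = X[:, mask]
        bi_f = self.block_index_[mask] if self.block_index_ is not None else None
        scales = _block_scales(Xf, bi_f) if self.block_scale else np.ones(Xf.shape[1])
        self.col_scale_ = scales
        Xs = Xf * scales

        rank = np.linalg.matrix_rank(Xs - Xs.mean(axis=0))
        cap = _max_valid_components(n, Xs.shape[1])
        if self.n_components is not None:
            c = int(self.n_components)
            if c < 1:
                raise ValueError("n_components must be >= 1")
            if c > min(n - 1, Xs.shape[1]) or c > rank:
                raise ValueError(
                    f"n_components={c} exceeds usable rank "
                    f"(rank={rank}, n={n}, columns={Xs.shape[1]})"
                )
            self.component_q2_ = None
        else:
            search = min(self.max_components, cap, rank)
            q2s = np.array(
                [self._cv_q2(X, y, k)[0] for k in range(1, search + 1)]
            )
            c = 1 + int(np.argmax(q2s))  # argmax takes the first = fewest
            self.component_q2_ = q2s

        self.n_components_ = c
        self.q2_, self.sep_, self.press_ = self._cv_q2(X, y, c)

        pls = _fit_raw_pls(Xs, y, c)
        self._pls = pls
        self.coef_ = np.asarray(pls.coef_).reshape(-1)
        self.x_mean_ = Xs.mean(axis=0)
        self.y_mean_ = float(y.mean())
        yhat = pls.predict(Xs).ravel()
        rss = float(np.sum((y - yhat) ** 2))
        tss = float(np.sum((y - y.mean()) ** 2))
        self.r2_ = 1.0 - rss / tss
        dof = n - c - 1
        self.see_ = float(np.sqrt(rss / dof)) if dof > 0 else float("nan")
        if self.r2_ >= 1.0 - _EPS:
            self.f_value_ = float("inf")
        else:
            self.f_value_ = (self.r2_ / (1.0 - self.r2_)) * (dof / c)

        sd = Xs.std(axis=0, ddof=1)
        self.stdev_coef_ = np.zeros(p)
        self.stdev_coef_[mask] = sd * self.coef_
        if bi_f is not None:
            self.field_fractions_ = field_contributions(
                self.coef_, sd, bi_f, n_blocks=int(self.block_index_.max()) + 1
            )
        else:
            self.field_fractions_ = None
        self._train_shape = (n, p)
        return self

    def _cv_q2(self, X: np.ndarray, y: np.ndarray, c: int) -> Tuple[float, float, float]:
        """LOO q², SEP, PRESS at ``c`` components under the configured protocol."""
        n = len(y)
        if self.refilter_per_fold:
            preds = np.empty(n)
            idx = np.arange(n)
            for i in range(n):
                keep = idx != i
                mask = (
                    column_filter(X[keep], self.min_sigma)
                    if self.min_sigma > 0
                    else np.ones(X.shape[1], dtype=bool)
                )
                Xf = X[keep][:, mask]
                bi = self.block_index_[mask] if self.block_index_ is not None else None
                scales = _block_scales(Xf, bi) if self.block_scale else 1.0
                model = _fit_raw_pls(Xf * scales, y[keep], min(c, Xf.shape[1]))
                preds[i] = float(
                    model.predict((X[i][mask] * scales)[None, :]).ravel()[0]
                )
        else:
            Xs = X[:, self.column_mask_] * self.col_scale_
            preds = _loo_predictions(Xs, y, c)
        return _press_stats(y, preds, c)

    # -- prediction -------------------------------------------------------

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        X = check_array(X, dtype=float)
        Xs = X[:, self.column_mask_] * self.col_scale_
        return (Xs - self.x_mean_) @ self.coef_ + self.y_mean_


# ---------------------------------------------------------------------------
# functional wrappers (the operation-level surface)


def fit_pls(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    block_index: Optional[np.ndarray] = None,
    min_sigma: float = 0.0,
    block_scale: bool = True,
) -> PLSQsarRegressor:
    """Fit a PLS model at a fixed component count (no ONC search)."""
    est = PLSQsarRegressor(
        n_components=n_components, min_sigma=min_sigma, block_scale=block_scale
    )
    return est.fit(X, y, block_index=block_index)


def loo_q2(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    min_sigma: float = 0.0,
    block_index: Optional[np.ndarray] = None,
    block_scale: bool = False,
) -> Tuple[float, float, float]:
    """(q², SEP, PRESS) from explicit leave-one-out refits.

    Preprocessing (filter + block scaling) is computed once on the full
    matrix and held fixed across folds.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = column_filter(X, min_sigma) if min_sigma > 0 else np.ones(X.shape[1], bool)
    Xf = X[:, mask]
    bi = np.asarray(block_index)[mask] if block_index is not None else None
    scales = _block_scales(Xf, bi) if block_scale else np.ones(Xf.shape[1])
    preds = _loo_predictions(Xf * scales, y, n_components)
    return _press_stats(y, preds, n_components)


def select_onc(
    X: np.ndarray,
    y: np.ndarray,
    max_components: int,
    **loo_kwargs,
) -> Tuple[int, np.ndarray]:
    """ONC maximising the LOO q²; ties broken toward fewer components."""
    if max_components < 1:
        raise ValueError("max_components must be >= 1")
    n = len(y)
    cap = min(max_components, _max_valid_components(n, np.asarray(X).shape[1]))
    q2s = np.array([loo_q2(X, y, c, **loo_kwargs)[0] for c in range(1, cap + 1)])
    return 1 + int(np.argmax(q2s)), q2s


@dataclass
class ModelStats:
    """Validation and fit statistics of one model (one printed-table column)."""

    q2: float
    onc: int
    r2: float
    see: float
    f_value: float
    sep: float
    field_fractions: Optional[Dict[str, float]] = None

    def __post_init__(self):
        if self.field_fractions:
            total = sum(self.field_fractions.values())
            if total > 0 and abs(total - 1.0) > 1e-10:
                raise ValueError("field fractions must sum to 1")


def model_stats(
    model: PLSQsarRegressor, field_names: Optional[Sequence[str]] = None
) -> ModelStats:
    """Collect a fitted model's statistics into a :class:`ModelStats`."""
    check_is_fitted(model, "coef_")
    fractions = None
    if model.field_fractions_ is not None:
        names = (
            list(field_names)
            if field_names is not None
            else [f"block{i}" for i in range(len(model.field_fractions_))]
        )
        fractions = dict(zip(names, model.field_fractions_.tolist()))
    return ModelStats(
        q2=model.q2_,
        onc=model.n_components_,
        r2=model.r2_,
        see=model.see_,
        f_value=model.f_value_,
        sep=model.sep_,
        field_fractions=fractions,
    )


def field_contributions(
    coef: np.ndarray,
    col_sd: np.ndarray,
    block_index: np.ndarray,
    n_blocks: Optional[int] = None,
) -> np.ndarray:
    """fraction_b = Σ_{j∈b} |coef_j| sd_j / Σ_all |coef_j| sd_j (empty block → 0)."""
    weights = np.abs(np.asarray(coef)) * np.asarray(col_sd)
    total = weights.sum()
    if n_blocks is None:
        n_blocks = int(np.max(block_index)) + 1 if len(block_index) else 0
    fractions = np.zeros(n_blocks)
    if total <= _EPS:
        return fractions
    for b in range(n_blocks):
        fractions[b] = weights[np.asarray(block_index) == b].sum() / total
    return fractions


def predict_table(
    model: PLSQsarRegressor,
    records: Sequence[CompoundRecord],
    X_all: np.ndarray,
) -> pd.DataFrame:
    """Per-compound experimental vs predicted pIC50 with residual = exp − pred."""
    X_all = np.asarray(X_all, dtype=float)
    if X_all.shape[0] != len(records):
        raise ValueError(
            f"{X_all.shape[0]} rows of X for {len(records)} records"
        )
    predicted = model.predict(X_all)
    return pd.DataFrame(
        {
            "compound_id": [r.compound_id for r in records],
            "subset": [r.subset for r in records],
            "experimental_pic50": [r.pic50 for r in records],
            "predicted_pic50": predicted,
            "residual": np.array([r.pic50 for r in records]) - predicted,
        }
    )


# ---------------------------------------------------------------------------
# persistence


_SAVED_SCALARS = (
    "n_components_", "q2_", "sep_", "press_", "r2_", "see_", "f_value_",
    "y_mean_", "n_features_in_",
)
_SAVED_ARRAYS = (
    "column_mask_", "col_scale_", "coef_", "x_mean_", "stdev_coef_",
    "block_index_", "field_fractions_", "component_q2_",
)


def save_model(
    directory: Union[str, Path],
    model: PLSQsarRegressor,
    field_names: Optional[Sequence[str]] = None,
) -> None:
    """Persist a fitted model as a JSON manifest plus an .npz of arrays."""
    check_is_fitted(model, "coef_")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "params": model.get_params(),
        "scalars": {k: getattr(model, k) for k in _SAVED_SCALARS},
        "field_names": list(field_names) if field_names else None,
    }
    arrays = {
        k: getattr(model, k)
        for k in _SAVED_ARRAYS
        if getattr(model, k, None) is not None
    }
    np.savez(directory / "model_arrays.npz", **arrays)
    (directory / "model.json").write_text(json.dumps(manifest, indent=2, default=float))


def load_model(directory: Union[str, Path]) -> Tuple[PLSQsarRegressor, Optional[List[str]]]:
    """Rebuild a persisted model; returns (model, field_names)."""
    directory = Path(directory)
    manifest = json.loads((directory / "model.json").read_text())
    model = PLSQsarRegressor(**manifest["params"])
    for k, v in manifest["scalars"].items():
        setattr(model, k, int(v) if k in ("n_components_", "n_features_in_") else float(v))
    with np.load(directory / "model_arrays.npz") as arrays:
        for k in arrays.files:
            setattr(model, k, arrays[k])
    if not hasattr(model, "block_index_"):
        model.block_index_ = None
    if not hasattr(model, "field_fractions_"):
        model.field_fractions_ = None
    return model, manifest.get("field_names")


# ---------------------------------------------------------------------------
# contour maps


@dataclass
class ContourMap:
    """stdev·coefficient grid values for one field plus its iso-levels."""

    field_kind: str
    values: np.ndarray
    favored_level: float
    disfavored_level: float
    grid: Grid = field(repr=False, default=None)


def contour_maps(
    model: PLSQsarRegressor,
    grid: Grid,
    blocks: Sequence[FieldBlock],
    favored_pct: float = 80.0,
    disfavored_pct: float = 20.0,
) -> Dict[str, ContourMap]:
    """Per-field stdev·coefficient grids with percentile iso-levels.

    Filtered-out columns contribute 0. Levels are percentiles of the
    nonzero value distribution of each field; a field whose values are
    all zero yields an empty contour with a warning.
    """
    check_is_fitted(model, "stdev_coef_")
    widths = [b.values.shape[1] for b in blocks]
    if sum(widths) != model.stdev_coef_.size:
        raise ValueError("blocks do not partition the model's columns")
    out: Dict[str, ContourMap] = {}
    offset = 0
    for b, w in zip(blocks, widths):
        vals = model.stdev_coef_[offset:offset + w]
        offset += w
        nonzero = vals[vals != 0]
        if nonzero.size == 0:
            warnings.warn(f"{b.field_kind}: all contour values are zero; empty contour")
            fav = dis = float("nan")
        else:
            fav = float(np.percentile(nonzero, favored_pct))
            dis = float(np.percentile(nonzero, disfavored_pct))
        out[b.field_kind] = ContourMap(
            field_kind=b.field_kind, values=vals.copy(),
            favored_level=fav, disfavored_level=dis, grid=grid,
        )
    return out


def export_contour_cubes(
    directory: Union[str, Path],
    maps: Dict[str, ContourMap],
    molecule=None,
) -> List[Path]:
    """Two cube files per field: values masked at the favored / disfavored level."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for kind, cm in maps.items():
        for label, keep in (
            ("favored", cm.values >= cm.favored_level),
            ("disfavored", cm.values <= cm.disfavored_level),
        ):
            vals = np.where(keep, cm.values, 0.0)
            if not np.isfinite(cm.favored_level):
                vals = np.zeros_like(cm.values)
            path = directory / f"{kind}_{label}.cube"
            write_cube(path, cm.grid, vals, molecule,
                       comment=f"{kind} {label} stdev*coef contour")
            written.append(path)
    return written


# ---------------------------------------------------------------------------
# printed-table style reports


_STAT_ROWS = [
    ("Optimum Number of Components", "onc", "{:d}"),
    ("Cross-Validated Coefficient (q2)", "q2", "{:.3f}"),
    ("Non-Cross-Validated Validation Coefficient (r2)", "r2", "{:.3f}"),
    ("Standard Error of Estimate", "see", "{:.3f}"),
    ("Standard Error of Prediction", "sep", "{:.3f}"),
    ("Fischer Statistic Value", "f_value", "{:.2f}"),
]

_FIELD_ROWS = [
    ("Steric Field %", "steric"),
    ("Electrostatic Field %", "electrostatic"),
    ("Hydrophobic Field %", "hydrophobic"),
    ("Hydrogen Bond Donor Field %", "donor"),
    ("Hydrogen Bond Acceptor Field %", "acceptor"),
]


def stats_report(stats_by_method: Dict[str, ModelStats]) -> pd.DataFrame:
    """Statistics table in the printed layout: one Item column, one column per model."""
    methods = list(stats_by_method)
    rows = []
    for label, attr, fmt in _STAT_ROWS:
        row = {"Item": label}
        for m in methods:
            val = getattr(stats_by_method[m], attr)
            row[m.upper()] = fmt.format(val) if np.isfinite(val) else "inf"
        rows.append(row)
    for label, kind in _FIELD_ROWS:
        vals = {}
        for m in methods:
            fr = stats_by_method[m].field_fractions or {}
            vals[m.upper()] = f"{100 * fr[kind]:.0f} %" if kind in fr else "-"
        if any(v != "-" for v in vals.values()):
            rows.append({"Item": label, **vals})
    return pd.DataFrame(rows)


def prediction_report(tables_by_method: Dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Experimental-vs-predicted table in the printed layout.

    Columns: Compound, pIC50 Activity, then per model a Prediction and a
    Functional Data (residual, experimental − predicted) column. Test-set
    compounds are starred.
    """
    methods = list(tables_by_method)
    first = tables_by_method[methods[0]]
    out = pd.DataFrame(
        {
            "Compound": [
                f"{cid}*" if sub == "test" else str(cid)
                for cid, sub in zip(first["compound_id"], first["subset"])
            ],
            "pIC50 Activity": first["experimental_pic50"].round(2),
        }
    )
    for m in methods:
        t = tables_by_method[m]
        out[f"{m.upper()} Prediction"] = t["predicted_pic50"].round(2)
        out[f"{m.upper()} Functional Data"] = t["residual"].round(2)
    return out
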