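"""Molecular features: fingerprints, 2D descriptors, and train-only selection.

Fingerprints (166-bit MACCS keys; 1024-bit ECFP4/ECFP6, i.e. Morgan radius
2/3) are used as-is.  The 2D descriptor panel goes through a four-stage
selection chain fitted on training rows only:

1. drop columns that contain NaN/inf on train, or are all-zero/constant;
2. drop low-variance columns (raw-scale variance < 0.1 by default), then
   standardize to zero mean / unit variance on train;
3. for every pair with |Pearson r| > 0.9 keep the alphabetically earlier
   column;
4. recursive feature elimination with cross-validation using a decision
   tree estimator.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors, MACCSkeys, rdFingerprintGenerator
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.feature_selection import RFECV
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor
from sklearn.utils.validation import check_is_fitted

from .datasets import StandardizationError

__all__ = [
    "FeatureType",
    "fingerprint",
    "fingerprint_matrix",
    "descriptors_2d",
    "descriptor_matrix",
    "descriptor_names",
    "FingerprintFeaturizer",
    "DescriptorSelector",
    "SelectionTrace",
]


class FeatureType(str, enum.Enum):
    MACCS = "MACCS"
    ECFP4 = "ECFP4"
    ECFP6 = "ECFP6"
    DESCRIPTORS_2D = "DESCRIPTORS_2D"


N_BITS = {FeatureType.MACCS: 166, FeatureType.ECFP4: 1024, FeatureType.ECFP6: 1024}

_GENERATORS: dict[FeatureType, object] = {}


def _mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StandardizationError(f"unparsable SMILES: {smiles!r}")
    return mol


def _morgan_generator(feature_type: FeatureType):
    if feature_type not in _GENERATORS:
        radius = 2 if feature_type is FeatureType.ECFP4 else 3
        _GENERATORS[feature_type] = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=1024
        )
    return _GENERATORS[feature_type]


def fingerprint(smiles: str, feature_type: FeatureType | str) -> np.ndarray:
    """Bit vector for one molecule: MACCS (166) or ECFP4/ECFP6 (1024).

    Identical molecules give identical vectors regardless of SMILES spelling.
    """
    feature_type = FeatureType(feature_type)
    mol = _mol(smiles)
    if feature_type is FeatureType.MACCS:
        # RDKit MACCS vectors have a dummy bit 0; the key set proper is 166 bits.
        bv = MACCSkeys.GenMACCSKeys(mol)
        arr = np.zeros(167, dtype=np.uint8)
        for b in bv.GetOnBits():
            arr[b] = 1
        return arr[1:]
    if feature_type in (FeatureType.ECFP4, FeatureType.ECFP6):
        bv = _morgan_generator(feature_type).GetFingerprint(mol)
        arr = np.zeros(1024, dtype=np.uint8)
        for b in bv.GetOnBits():
            arr[b] = 1
        return arr
    raise ValueError(f"{feature_type} is not a fingerprint type")


def fingerprint_matrix(smiles_list, feature_type: FeatureType | str) -> np.ndarray:
    feature_type = FeatureType(feature_type)
    return np.vstack([fingerprint(s, feature_type) for s in smiles_list])


_DESCRIPTOR_NAMES: list[str] | None = None


def descriptor_names() -> list[str]:
    """Names of the full 2D descriptor panel, in panel order."""
    global _DESCRIPTOR_NAMES
    if _DESCRIPTOR_NAMES is None:
        _DESCRIPTOR_NAMES = [name for name, _ in Descriptors.descList]
    return list(_DESCRIPTOR_NAMES)


def descriptors_2d(smiles: str) -> pd.Series:
    """Full 2D descriptor panel for one molecule.

    Individual descriptor failures yield NaN for that descriptor rather than
    dropping the molecule; the selection chain removes such columns later.
    """
    mol = _mol(smiles)
    values = Descriptors.CalcMolDescriptors(mol, missingVal=np.nan, silent=True)
    s = pd.Series({name: values.get(name, np.nan) for name in descriptor_names()},
                  dtype=float)
    return s.replace([np.inf, -np.inf], np.nan)


def descriptor_matrix(smiles_list) -> pd.DataFrame:
    return pd.DataFrame([descriptors_2d(s) for s in smiles_list],
                        columns=descriptor_names()).reset_index(drop=True)


class FingerprintFeaturizer(BaseEstimator, TransformerMixin):
    """Stateless transformer mapping SMILES lists to fingerprint matrices."""

    def __init__(self, feature_type: FeatureType | str = FeatureType.ECFP4):
        self.feature_type = feature_type

    def fit(self, X, y=None):
        self.n_features_out_ = N_BITS[FeatureType(self.feature_type)]
        return self

    def transform(self, X):
        return fingerprint_matrix(X, self.feature_type)

    def get_feature_names_out(self, input_features=None):
        ft = FeatureType(self.feature_type)
        return np.array([f"{ft.value}_{i}" for i in range(N_BITS[ft])])


@dataclass
class SelectionTrace:
    """Per-stage survivor counts and dropped names; counts never increase."""

    initial: int = 0
    after_nan_zero: int = 0
    after_variance: int = 0
    after_correlation: int = 0
    after_rfecv: int = 0
    dropped: dict[str, list[str]] = field(default_factory=dict)

    @property
    def counts(self) -> list[int]:
        return [self.initial, self.after_nan_zero, self.after_variance,
                self.after_correlation, self.after_rfecv]


class DescriptorSelector(BaseEstimator, TransformerMixin):
    """Four-stage train-only descriptor selection and standardization.

    Parameters
    ----------
    task : "classification" or "regression"
        Chooses the decision-tree estimator and CV scorer for the recursive
        elimination stage (balanced accuracy vs. R2).
    variance_threshold : float
        Minimum raw-scale variance; columns below it are dropped.
    corr_threshold : float
        |Pearson r| above which one of a pair of columns is redundant.
    standardize_before_variance : bool
        Alternative chain order (variance computed on standardized data,
        which makes the threshold near-vacuous); off by default.
    rfe_cv : int
        Folds for the recursive-elimination cross-validation.
    random_state : int
        Seed for the tree estimator and CV shuffling; selection is
        deterministic under a fixed seed.

    Fitted attributes: ``selected_names_``, ``selected_idx_`` (into the
    input panel), ``means_``/``scales_`` (train standardization), ``trace_``.
    """

    def __init__(
        self,
        task: str = "classification",
        variance_threshold: float = 0.1,
        corr_threshold: float = 0.9,
        standardize_before_variance: bool = False,
        rfe_cv: int = 10,
        min_features: int = 2,
        random_state: int = 0,
    ):
        self.task = task
        self.variance_threshold = variance_threshold
        self.corr_threshold = corr_threshold
        self.standardize_before_variance = standardize_before_variance
        self.rfe_cv = rfe_cv
        self.min_features = min_features
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float),
                             columns=[f"x{i}" for i in range(np.shape(X)[1])])
        X = X.replace([np.inf, -np.inf], np.nan)
        y = np.asarray(y)
        trace = SelectionTrace(initial=X.shape[1])

        # Stage 1: drop columns with any train NaN, all-zero or constant.
        bad = X.columns[X.isna().any(axis=0) | (X.nunique(dropna=False) <= 1)]
        X1 = X.drop(columns=bad)
        trace.dropped["nan_zero"] = list(bad)
        trace.after_nan_zero = X1.shape[1]

        # Stage 2: variance filter (raw scale by default), then standardize.
        if self.standardize_before_variance:
            Xs = (X1 - X1.mean()) / X1.std(ddof=0)
            low = Xs.columns[Xs.var(ddof=0) < self.variance_threshold]
        else:
            low = X1.columns[X1.var(ddof=0) < self.variance_threshold]
        X2 = X1.drop(columns=low)
        trace.dropped["low_variance"] = list(low)
        trace.after_variance = X2.shape[1]
        if X2.shape[1] < self.min_features:
            raise ValueError("fewer than 2 descriptors survive the variance filter")

        # Stage 3: greedy correlation filter in alphabetical column order.
        ordered = sorted(X2.columns)
        corr = X2[ordered].corr().abs().to_numpy()
        keep_mask = np.ones(len(ordered), dtype=bool)
        for j in range(len(ordered)):
            if not keep_mask[j]:
                continue
            too_high = corr[j, j + 1:] > self.corr_threshold
            keep_mask[j + 1:][too_high] = False
        kept3 = [c for c, k in zip(ordered, keep_mask) if k]
        trace.dropped["correlated"] = [c for c, k in zip(ordered, keep_mask) if not k]
        # restore panel order
        kept3 = [c for c in X2.columns if c in set(kept3)]
        X3 = X2[kept3]
        trace.after_correlation = X3.shape[1]
        if X3.shape[1] < self.min_features:
            raise ValueError("fewer than 2 descriptors survive the correlation filter")

        means = X3.mean()
        scales = X3.std(ddof=0).replace(0.0, 1.0)
        Z = (X3 - means) / scales

        # Stage 4: RFE with cross-validation on a decision tree.
        if self.task == "classification":
            est = DecisionTreeClassifier(random_state=self.random_state)
            cv = StratifiedKFold(self.rfe_cv, shuffle=True,
                                 random_state=self.random_state)
            scoring = "balanced_accuracy"
        else:
            est = DecisionTreeRegressor(random_state=self.random_state)
            cv = KFold(self.rfe_cv, shuffle=True, random_state=self.random_state)
            scoring = "r2"
        step = max(1, int(np.ceil(0.01 * Z.shape[1])))
        rfecv = RFECV(est, step=step, cv=cv, scoring=scoring,
                      min_features_to_select=self.min_features)
        rfecv.fit(Z.to_numpy(), y)
        support = rfecv.support_
        trace.dropped["rfecv"] = [c for c, s in zip(Z.columns, support) if not s]
        selected = [c for c, s in zip(Z.columns, support) if s]
        trace.after_rfecv = len(selected)

        self.selected_names_ = selected
        self.input_names_ = list(X.columns)
        self.selected_idx_ = np.array([self.input_names_.index(c) for c in selected])
        self.means_ = means[selected]
        self.scales_ = scales[selected]
        self.trace_ = trace
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "selected_names_")
        if isinstance(X, pd.DataFrame):
            missing = set(self.selected_names_) - set(X.columns)
            if missing:
                raise ValueError(f"missing descriptor columns: {sorted(missing)}")
            sub = X[self.selected_names_]
        else:
            sub = pd.DataFrame(np.asarray(X, dtype=float),
                               columns=self.input_names_)[self.selected_names_]
        return ((sub - self.means_) / self.scales_).to_numpy()

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "selected_names_")
        return np.array(self.selected_names_)

    def fitted_state(self) -> dict:
        """JSON-serializable standardization + selection state."""
        check_is_fitted(self, "selected_names_")
        return {
            "selected_names": list(self.selected_names_),
            "means": self.means_.to_dict(),
            "scales": self.scales_.to_dict(),
        }
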