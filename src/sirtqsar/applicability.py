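"""Prediction-confidence tooling: leverage applicability domain (AD),
indeterminate probability zones, atom-contribution maps, and Tanimoto lookup.

The leverage AD restricts the training matrix to its important features
(mean permutation importance > 0, 30 repeats by default), standardizes
them, and measures a query's distance from the training centroid as the
hat-matrix diagonal h_i = x_i^T (X^T X)^+ x_i.  Queries with h_i above the
conventional threshold h* = 3(m+1)/p (m features, p training molecules)
are flagged out-of-domain.  A Moore-Penrose pseudo-inverse keeps leverage
defined when X^T X is singular (common for sparse fingerprint bits); the
hat-matrix trace identity (sum of train leverages = rank X) holds on the
column space.

Classification confidence uses indeterminate zones: binary predictions with
probability in 0.5 +/- 0.1 are unconfident; multiclass predictions need
predicted-class probability > 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit import DataStructs
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator
from sklearn.base import BaseEstimator, is_classifier
from sklearn.utils.validation import check_is_fitted

from .datasets import StandardizationError
from .features import FeatureType, fingerprint

logger = logging.getLogger(__name__)

__all__ = [
    "LeverageDomain",
    "williams_data",
    "in_confidence_zone",
    "AtomContributionMap",
    "similarity_map",
    "tanimoto_nearest",
]


def permutation_importance_mean(model, X, y, n_repeats: int = 30,
                                max_samples: float | int = 1.0,
                                random_state: int = 0) -> np.ndarray:
    """Mean permutation importance per feature.

    Importance of feature j is the drop in the model's score (R2 for
    regressors, accuracy for classifiers) when column j is permuted,
    averaged over ``n_repeats`` independent permutations.  All repeats for
    a feature are stacked into one predict call, which keeps large feature
    spaces (e.g. 1024 fingerprint bits) tractable.  ``max_samples`` limits
    the rows used for scoring (int = absolute count, float = fraction).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(random_state)
    n = X.shape[0]
    if isinstance(max_samples, float):
        n_sub = max(2, int(round(max_samples * n)))
    else:
        n_sub = min(int(max_samples), n)
    if n_sub < n:
        rows = rng.choice(n, size=n_sub, replace=False)
        X, y = X[rows], y[rows]
        n = n_sub
    classifier = is_classifier(model)

    def score(pred, truth):
        if classifier:
            return float(np.mean(pred == truth))
        ss_res = float(np.sum((truth - pred) ** 2))
        ss_tot = float(np.sum((truth - truth.mean()) ** 2))
        return 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0

    baseline = score(model.predict(X), y)
    d = X.shape[1]
    importances = np.zeros(d)
    # Exact shortcut for tree ensembles: a feature used in no split cannot
    # change any prediction, so its permutation importance is exactly zero.
    inner = getattr(model, "estimator_", model)
    gini = getattr(inner, "feature_importances_", None)
    candidates = range(d) if gini is None else np.flatnonzero(np.asarray(gini) > 0)
    perms = [rng.permutation(n) for _ in range(n_repeats)]
    stacked = np.tile(X, (n_repeats, 1))
    for j in candidates:
        for r, perm in enumerate(perms):
            stacked[r * n:(r + 1) * n, j] = X[perm, j]
        preds = model.predict(stacked)
        importances[j] = baseline - float(np.mean(
            [score(preds[r * n:(r + 1) * n], y) for r in range(n_repeats)]
        ))
        stacked[:, j] = np.tile(X[:, j], n_repeats)  # restore column
    return importances


class LeverageDomain(BaseEstimator):
    """Leverage-based applicability domain for regression models.

    Parameters
    ----------
    n_repeats : int
        Permutation-importance repeats used to pick important features.
    top_k : int or None
        Alternative rule: keep the k most important features instead of
        all features with positive mean importance.
    random_state : int
        Seed for the permutation importance.

    Fitted attributes: ``important_idx_``, ``m_`` (feature count), ``p_``
    (training size), ``h_star_``, ``train_leverages_``.
    """

    def __init__(self, n_repeats: int = 30, top_k: int | None = None,
                 importance_max_samples: float | int = 1.0,
                 random_state: int = 0):
        self.n_repeats = n_repeats
        self.top_k = top_k
        self.importance_max_samples = importance_max_samples
        self.random_state = random_state

    def fit(self, model, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        imp = permutation_importance_mean(
            model, X, y, n_repeats=self.n_repeats,
            max_samples=self.importance_max_samples,
            random_state=self.random_state,
        )
        if self.top_k is not None:
            idx = np.argsort(imp)[::-1][: self.top_k]
            idx = np.sort(idx)
        else:
            idx = np.flatnonzero(imp > 0)
        if len(idx) == 0:
            logger.warning("no feature had positive permutation importance; "
                           "falling back to all features")
            idx = np.arange(X.shape[1])
        self.important_idx_ = idx
        sub = X[:, idx]
        self.means_ = sub.mean(axis=0)
        scales = sub.std(axis=0)
        scales[scales == 0] = 1.0
        self.scales_ = scales
        Z = (sub - self.means_) / self.scales_
        self.xtx_pinv_ = np.linalg.pinv(Z.T @ Z)
        self.m_ = int(len(idx))
        self.p_ = int(X.shape[0])
        self.h_star_ = 3.0 * (self.m_ + 1) / self.p_
        self.train_leverages_ = self._leverage_of_standardized(Z)
        self.rank_ = int(np.linalg.matrix_rank(Z))
        return self

    def _leverage_of_standardized(self, Z: np.ndarray) -> np.ndarray:
        return np.einsum("ij,jk,ik->i", Z, self.xtx_pinv_, Z)

    def leverage(self, X) -> np.ndarray:
        """Leverage h_i of query rows (full feature space expected)."""
        check_is_fitted(self, "important_idx_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] == self.m_:
            sub = X
        else:
            try:
                sub = X[:, self.important_idx_]
            except IndexError as exc:
                raise ValueError(
                    f"query has {X.shape[1]} features; expected the training "
                    f"width or the {self.m_} important features"
                ) from exc
        Z = (sub - self.means_) / self.scales_
        return self._leverage_of_standardized(Z)

    def contains(self, X) -> np.ndarray:
        """True where the query is inside the domain (h_i <= h*)."""
        return self.leverage(X) <= self.h_star_


def williams_data(domain: LeverageDomain, X, y_obs, y_pred, train_rmse: float):
    """Data for a Williams plot: leverages, standardized residuals, thresholds.

    Residuals are standardized by the training RMSE; the returned thresholds
    are (h*, 3.0) for the leverage and residual axes.  No plotting happens
    here.
    """
    if not train_rmse > 0:
        raise ValueError("train RMSE must be positive")
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if len(y_obs) != len(y_pred):
        raise ValueError("y_obs and y_pred must have equal length")
    leverages = domain.leverage(X)
    std_resid = (y_obs - y_pred) / train_rmse
    return leverages, std_resid, (domain.h_star_, 3.0)


def in_confidence_zone(task: str, proba) -> bool:
    """Decide whether a probability vector is a confident prediction.

    Binary: confident iff the top-class probability is outside (0.4, 0.6),
    i.e. not in the indeterminate zone 0.5 +/- 0.1.  Multiclass: confident
    iff the predicted class has probability > 0.5.
    """
    proba = np.asarray(proba, dtype=float)
    top = float(proba.max())
    if task == "binary":
        return not (0.4 < top < 0.6)
    if task == "multiclass":
        return top > 0.5
    raise ValueError(f"unknown task {task!r}")


# --------------------------------------------------------------------------
# Atom-contribution similarity maps


@dataclass
class AtomContributionMap:
    """Signed per-atom weights for a fingerprint-based prediction.

    weight(atom) = prediction(full fingerprint) - prediction(fingerprint with
    the atom's bits removed); positive weights support activity.  Atoms that
    generate no set bit have weight zero.
    """

    weights: list[float]
    reference_prediction: float
    feature_type: FeatureType

    def to_rows(self) -> list[dict]:
        return [{"atom_index": i, "weight": w} for i, w in enumerate(self.weights)]


def _morgan_atom_bits(mol: Chem.Mol, radius: int) -> dict[int, set[int]]:
    """bit -> atoms inside the generating environment (center or in radius)."""
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=1024)
    ao = rdFingerprintGenerator.AdditionalOutput()
    ao.AllocateBitInfoMap()
    gen.GetFingerprint(mol, additionalOutput=ao)
    atom_bits: dict[int, set[int]] = {a: set() for a in range(mol.GetNumAtoms())}
    for bit, envs in ao.GetBitInfoMap().items():
        for center, rad in envs:
            atoms = {center}
            if rad > 0:
                for bond_idx in Chem.FindAtomEnvironmentOfRadiusN(mol, rad, center):
                    bond = mol.GetBondWithIdx(bond_idx)
                    atoms.add(bond.GetBeginAtomIdx())
                    atoms.add(bond.GetEndAtomIdx())
            for a in atoms:
                atom_bits[a].add(bit)
    return atom_bits


def _maccs_atom_bits(mol: Chem.Mol) -> dict[int, set[int]]:
    """MACCS bit attribution via SMARTS substructure matches.

    An atom owns a key when it occurs in a match of the key's SMARTS
    pattern.  Count-based and composite keys without a single SMARTS are
    left unattributed (their removal cannot be localized to atoms).
    """
    atom_bits: dict[int, set[int]] = {a: set() for a in range(mol.GetNumAtoms())}
    on_bits = set(fingerprint(Chem.MolToSmiles(mol), FeatureType.MACCS).nonzero()[0])
    for key, (smarts, _count) in MACCSkeys.smartsPatts.items():
        bit = key - 1  # our vectors drop the dummy bit 0
        if bit not in on_bits or smarts in ("?", ""):
            continue
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            continue
        for match in mol.GetSubstructMatches(patt):
            for a in match:
                atom_bits[a].add(bit)
    return atom_bits


def similarity_map(
    predict_fn,
    smiles: str,
    feature_type: FeatureType | str,
) -> AtomContributionMap:
    """Per-atom contributions by fingerprint-bit removal.

    ``predict_fn`` maps a single fingerprint vector to a scalar (active-class
    probability or predicted pIC50).  Only fingerprint feature types are
    supported; descriptor-based models have no atom-to-feature mapping.
    """
    feature_type = FeatureType(feature_type)
    if feature_type is FeatureType.DESCRIPTORS_2D:
        raise ValueError("similarity maps are unsupported for descriptor models")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StandardizationError(f"unparsable SMILES: {smiles!r}")
    full = fingerprint(smiles, feature_type)
    if feature_type is FeatureType.MACCS:
        atom_bits = _maccs_atom_bits(mol)
    else:
        radius = 2 if feature_type is FeatureType.ECFP4 else 3
        atom_bits = _morgan_atom_bits(mol, radius)
    ref = float(predict_fn(full))
    weights = []
    for a in range(mol.GetNumAtoms()):
        bits = atom_bits.get(a, set())
        if not bits:
            weights.append(0.0)
            continue
        reduced = full.copy()
        reduced[list(bits)] = 0
        weights.append(ref - float(predict_fn(reduced)))
    return AtomContributionMap(weights=weights, reference_prediction=ref,
                               feature_type=feature_type)


_ECFP4_GEN = None


def _ecfp4_rdkit_fp(smiles: str):
    global _ECFP4_GEN
    if _ECFP4_GEN is None:
        _ECFP4_GEN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=1024)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StandardizationError(f"unparsable SMILES: {smiles!r}")
    return _ECFP4_GEN.GetFingerprint(mol)


def tanimoto_nearest(query_smiles: str, library: list[str],
                     library_ids: list | None = None):
    """Most similar library member by ECFP4 Tanimoto (ties: first occurrence).

    Returns ``(identifier_or_smiles, similarity)``.
    """
    if not library:
        raise ValueError("reference library is empty")
    qfp = _ecfp4_rdkit_fp(query_smiles)
    fps = [_ecfp4_rdkit_fp(s) for s in library]
    sims = DataStructs.BulkTanimotoSimilarity(qfp, fps)
    best = int(np.argmax(sims))
    ident = library_ids[best] if library_ids is not None else library[best]
    return ident, float(sims[best])
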