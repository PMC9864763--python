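"""External-validation statistics, classification metrics, and decoy benchmarks.

Regression external validation implements the standard QSAR battery on the
test (external, EXT) set against the training (TR) set context:

    Rext2  = 1 - sum(y - yhat)^2 / sum(y - mean_EXT(y))^2
    RMSEext = sqrt(mean (y - yhat)^2)
    QF1^2  = 1 - sum(y - yhat)^2 / sum(y - mean_TR)^2
    QF2^2  = Rext2  (denominator uses the external mean)
    QF3^2  = 1 - [sum(y - yhat)^2 / n_EXT] / [TSS_TR / n_TR]
    rm^2   = r^2 (1 - sqrt(r^2 - r0^2))   (Roy), primed variant swaps axes
    CCC    = Lin's concordance correlation coefficient

plus the Golbraikh-Tropsha through-origin regression criteria.  All metrics
are computed directly from the raw vectors here (no library shortcut), so
they can be cross-checked against independent oracles to machine precision.

Early recognition uses ROC enrichment: EF at false-positive fraction f is
the fraction of true actives ranked above the score at which a fraction f
of the inactives has been screened (i.e. TPR at fixed FPR), with
pessimistic tie handling.  Decoys are property-matched, topologically
dissimilar presumed inactives at a configurable active:inactive ratio.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors

from .features import FeatureType, fingerprint_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "RegressionReport",
    "GolbraikhTropsha",
    "ClassificationReport",
    "regression_report",
    "golbraikh_tropsha",
    "classification_report",
    "roc_enrichment",
    "generate_decoys",
    "evaluate_on_decoys",
]


# --------------------------------------------------------------------------
# Regression battery


@dataclass
class GolbraikhTropsha:
    """Through-origin regression quantities and the three criteria flags."""

    r2: float
    r0_2: float
    r0_prime_2: float
    k: float
    k_prime: float
    criterion_r0: bool
    criterion_k: bool
    criterion_delta_r0: bool

    @property
    def all_pass(self) -> bool:
        return self.criterion_r0 and self.criterion_k and self.criterion_delta_r0


@dataclass
class RegressionReport:
    Rext2: float
    RMSEext: float
    QF1_2: float
    QF2_2: float
    QF3_2: float
    rm2: float
    rm2_prime: float
    rm2_bar: float
    delta_rm2: float
    CCC: float
    gt: GolbraikhTropsha
    n_EXT: int
    n_TR: int
    train_mean: float
    criteria: dict[str, bool] = field(default_factory=dict)
    degenerate_reason: str | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gt_all_pass"] = self.gt.all_pass
        return d


def _pearson_r2(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt(float(np.sum(a * a)) * float(np.sum(b * b)))
    if denom == 0.0:
        return float("nan")
    return (float(np.sum(a * b)) / denom) ** 2


def _through_origin(y: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """Slope k of y = k*x through the origin and its determination coefficient
    r0^2 = 1 - sum(y - k x)^2 / sum(y - mean y)^2."""
    sxx = float(np.sum(x * x))
    if sxx == 0.0:
        raise ValueError("through-origin regression undefined for all-zero axis")
    k = float(np.sum(x * y)) / sxx
    ss_res = float(np.sum((y - k * x) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return k, float("nan")
    return k, 1.0 - ss_res / ss_tot


def golbraikh_tropsha(y_obs, y_pred) -> GolbraikhTropsha:
    """Golbraikh-Tropsha external criteria from raw vectors.

    k regresses observations on predictions through the origin; k' swaps the
    axes.  Criteria: (r2 - r0^2)/r2 < 0.1 (or the primed variant),
    0.85 <= k (or k') <= 1.15, and |r0^2 - r0'^2| < 0.3.
    """
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if len(y_obs) != len(y_pred) or len(y_obs) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.all(y_pred == 0):
        raise ValueError("all-zero predictions")
    r2 = _pearson_r2(y_obs, y_pred)
    k, r0_2 = _through_origin(y_obs, y_pred)
    k_prime, r0_prime_2 = _through_origin(y_pred, y_obs)
    crit_r0 = ((r2 - r0_2) / r2 < 0.1) or ((r2 - r0_prime_2) / r2 < 0.1)
    crit_k = (0.85 <= k <= 1.15) or (0.85 <= k_prime <= 1.15)
    crit_delta = abs(r0_2 - r0_prime_2) < 0.3
    return GolbraikhTropsha(
        r2=r2, r0_2=r0_2, r0_prime_2=r0_prime_2, k=k, k_prime=k_prime,
        criterion_r0=bool(crit_r0), criterion_k=bool(crit_k),
        criterion_delta_r0=bool(crit_delta),
    )


def _rm2(y_ordinate: np.ndarray, y_abscissa: np.ndarray) -> float:
    """Roy's rm^2 = r^2 (1 - sqrt(r^2 - r0^2)) for a given axis assignment."""
    r2 = _pearson_r2(y_ordinate, y_abscissa)
    _, r0_2 = _through_origin(y_ordinate, y_abscissa)
    return r2 * (1.0 - math.sqrt(max(0.0, r2 - r0_2)))


def lin_ccc(a, b) -> float:
    """Lin's concordance correlation coefficient; symmetric in its arguments."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n = len(a)
    num = 2.0 * float(np.sum((a - a.mean()) * (b - b.mean())))
    den = (float(np.sum((a - a.mean()) ** 2)) + float(np.sum((b - b.mean()) ** 2))
           + n * (a.mean() - b.mean()) ** 2)
    if den == 0.0:
        return float("nan")
    return num / den


def regression_report(y_obs, y_pred, train_labels) -> RegressionReport:
    """Full external-validation battery for a regression model.

    ``train_labels`` supplies the training mean and total sum of squares
    needed by QF1^2 and QF3^2.  Threshold flags follow the conventional
    acceptance criteria: Rext2 > 0.6; QF1/2/3^2 > 0.7 and CCC > 0.85;
    rm2_bar > 0.5 and delta_rm2 < 0.2.
    """
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    y_tr = np.asarray(train_labels, dtype=float)
    if len(y_obs) != len(y_pred) or len(y_obs) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    n_ext, n_tr = len(y_obs), len(y_tr)
    press = float(np.sum((y_obs - y_pred) ** 2))
    ss_ext = float(np.sum((y_obs - y_obs.mean()) ** 2))
    tr_mean = float(y_tr.mean())
    ss_tr = float(np.sum((y_tr - tr_mean) ** 2))
    degenerate = None
    if ss_ext == 0.0:
        degenerate = "zero variance in observed test values; Rext2/QF2 undefined"
        logger.warning(degenerate)
    rext2 = 1.0 - press / ss_ext if ss_ext > 0 else float("nan")
    ss_obs_tr = float(np.sum((y_obs - tr_mean) ** 2))
    qf1 = 1.0 - press / ss_obs_tr if ss_obs_tr > 0 else float("nan")
    qf3 = 1.0 - (press / n_ext) / (ss_tr / n_tr) if ss_tr > 0 else float("nan")
    rm2 = _rm2(y_obs, y_pred)
    rm2p = _rm2(y_pred, y_obs)
    gt = golbraikh_tropsha(y_obs, y_pred)
    report = RegressionReport(
        Rext2=rext2,
        RMSEext=math.sqrt(press / n_ext),
        QF1_2=qf1,
        QF2_2=rext2,
        QF3_2=qf3,
        rm2=rm2,
        rm2_prime=rm2p,
        rm2_bar=0.5 * (rm2 + rm2p),
        delta_rm2=abs(rm2 - rm2p),
        CCC=lin_ccc(y_obs, y_pred),
        gt=gt,
        n_EXT=n_ext,
        n_TR=n_tr,
        train_mean=tr_mean,
        degenerate_reason=degenerate,
    )
    report.criteria = {
        "Rext2_gt_0.6": report.Rext2 > 0.6,
        "QF1_gt_0.7": report.QF1_2 > 0.7,
        "QF2_gt_0.7": report.QF2_2 > 0.7,
        "QF3_gt_0.7": report.QF3_2 > 0.7,
        "CCC_gt_0.85": report.CCC > 0.85,
        "rm2_bar_gt_0.5": report.rm2_bar > 0.5,
        "delta_rm2_lt_0.2": report.delta_rm2 < 0.2,
        "golbraikh_tropsha": gt.all_pass,
    }
    return report


# --------------------------------------------------------------------------
# Classification metrics


@dataclass
class ClassificationReport:
    classes: list
    confusion: np.ndarray  # rows = true class, cols = predicted class
    per_class: dict
    balanced_accuracy: float
    mcc: float
    roc_auc_macro: float
    precision_macro: float
    recall_macro: float
    f1_macro: float
    enrichment: dict[float, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["confusion"] = self.confusion.tolist()
        d["classes"] = [str(c) for c in self.classes]
        d["enrichment"] = {str(k): v for k, v in self.enrichment.items()}
        return d


def _rank_auc(scores_pos: np.ndarray, scores_neg: np.ndarray) -> float:
    """AUC via the Mann-Whitney statistic with half-credit for ties."""
    all_scores = np.concatenate([scores_pos, scores_neg])
    order = np.argsort(all_scores, kind="mergesort")
    ranks = np.empty(len(all_scores), dtype=float)
    sorted_scores = all_scores[order]
    i = 0
    while i < len(sorted_scores):
        j = i
        while j + 1 < len(sorted_scores) and sorted_scores[j + 1] == sorted_scores[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    n_pos, n_neg = len(scores_pos), len(scores_neg)
    r_pos = float(np.sum(ranks[:n_pos]))
    return (r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def gorodkin_mcc(confusion: np.ndarray) -> float:
    """Multiclass (Gorodkin) Matthews correlation from a confusion matrix."""
    C = confusion.astype(float)
    n = C.sum()
    t = C.sum(axis=1)  # true counts per class
    p = C.sum(axis=0)  # predicted counts per class
    cov_yp = float(np.trace(C)) * n - float(t @ p)
    cov_yy = n * n - float(t @ t)
    cov_pp = n * n - float(p @ p)
    denom = math.sqrt(cov_yy * cov_pp)
    if denom == 0.0:
        return 0.0
    return cov_yp / denom


def classification_report(
    y_true,
    y_proba,
    classes,
    fractions: tuple[float, ...] = (),
    positive_class=None,
) -> ClassificationReport:
    """Confusion-matrix metrics at argmax plus macro one-vs-rest statistics.

    ``y_proba`` rows must sum to one and its columns follow ``classes``.
    Classes absent from ``y_true`` are excluded from the macro ROC AUC with
    a logged note.  When ``fractions`` is given, ROC enrichment of the
    positive class (default: last class in ``classes``) is included.
    """
    y_true = np.asarray(y_true)
    y_proba = np.asarray(y_proba, dtype=float)
    classes = list(classes)
    if y_proba.ndim != 2 or y_proba.shape[1] != len(classes):
        raise ValueError("y_proba must be (n, n_classes)")
    if not np.allclose(y_proba.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    if len(set(y_true.tolist())) < 2:
        raise ValueError("need at least 2 classes present in y_true")
    y_pred_idx = np.argmax(y_proba, axis=1)
    true_idx = np.array([classes.index(c) for c in y_true])
    k = len(classes)
    confusion = np.zeros((k, k), dtype=int)
    for t, p in zip(true_idx, y_pred_idx):
        confusion[t, p] += 1

    per_class = {}
    recalls, precisions, f1s, aucs = [], [], [], []
    for i, cls in enumerate(classes):
        tp = int(confusion[i, i])
        fn = int(confusion[i].sum() - tp)
        fp = int(confusion[:, i].sum() - tp)
        tn = int(confusion.sum() - tp - fn - fp)
        recall = tp / (tp + fn) if tp + fn else float("nan")
        precision = tp / (tp + fp) if tp + fp else 0.0
        f1 = (2 * precision * recall / (precision + recall)
              if (precision + recall) else 0.0)
        per_class[str(cls)] = {"TP": tp, "TN": tn, "FP": fp, "FN": fn,
                               "recall": recall, "precision": precision, "f1": f1}
        if tp + fn == 0:
            logger.warning("class %r absent from y_true; excluded from macro AUC", cls)
            continue
        recalls.append(recall)
        precisions.append(precision)
        f1s.append(f1)
        mask = true_idx == i
        if mask.all():
            continue
        aucs.append(_rank_auc(y_proba[mask, i], y_proba[~mask, i]))

    report = ClassificationReport(
        classes=classes,
        confusion=confusion,
        per_class=per_class,
        balanced_accuracy=float(np.mean(recalls)),
        mcc=gorodkin_mcc(confusion),
        roc_auc_macro=float(np.mean(aucs)) if aucs else float("nan"),
        precision_macro=float(np.mean(precisions)),
        recall_macro=float(np.mean(recalls)),
        f1_macro=float(np.mean(f1s)),
    )
    if fractions:
        pos = positive_class if positive_class is not None else classes[-1]
        i = classes.index(pos)
        labels = (true_idx == i).astype(int)
        report.enrichment = roc_enrichment(y_proba[:, i], labels, fractions)
    return report


def roc_enrichment(
    scores,
    labels,
    fractions=(0.005, 0.01, 0.02, 0.05),
) -> dict[float, float]:
    """ROC enrichment: true-positive rate at fixed false-positive fractions.

    ``labels`` are 1 for actives and 0 for inactives.  EF at fraction f is
    the share of actives scoring strictly above the floor(f * n_inactive)-th
    best inactive score: actives tied with the cutoff count as not recovered
    (pessimistic), making the value a reproducible lower bound.  EF is in
    [0, 1]; under random ranking its expectation is ~f.  Fractions for which
    ``floor(f * n_inactive) < 1`` are reported as NaN (undefined).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    act = scores[labels == 1]
    inact = np.sort(scores[labels == 0])[::-1]
    if len(act) < 1 or len(inact) < 1:
        raise ValueError("need at least one active and one inactive")
    out: dict[float, float] = {}
    for f in fractions:
        m = int(math.floor(f * len(inact)))
        if m < 1:
            out[f] = float("nan")
            continue
        cutoff = inact[m - 1]
        out[f] = float(np.sum(act > cutoff)) / len(act)
    return out


# --------------------------------------------------------------------------
# Decoy generation and evaluation


_DECOY_PROPS = ("MW", "logP", "HBD", "HBA", "RotB", "charge")


def _physchem(smiles_list) -> np.ndarray:
    rows = []
    for s in smiles_list:
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            raise ValueError(f"unparsable SMILES: {s!r}")
        rows.append([
            Descriptors.MolWt(mol),
            Crippen.MolLogP(mol),
            Lipinski.NumHDonors(mol),
            Lipinski.NumHAcceptors(mol),
            rdMolDescriptors.CalcNumRotatableBonds(mol),
            Chem.GetFormalCharge(mol),
        ])
    return np.asarray(rows, dtype=float)


def _bulk_max_tanimoto(fp_query: np.ndarray, fp_ref: np.ndarray) -> np.ndarray:
    """Max Tanimoto of each query bit row against a reference bit matrix."""
    q = fp_query.astype(np.float64)
    r = fp_ref.astype(np.float64)
    inter = q @ r.T
    union = q.sum(axis=1)[:, None] + r.sum(axis=1)[None, :] - inter
    with np.errstate(invalid="ignore"):
        sim = np.where(union > 0, inter / union, 0.0)
    return sim.max(axis=1)


def generate_decoys(
    actives,
    candidate_pool,
    per_active: int,
    seed: int,
    tanimoto_cutoff: float = 0.3,
) -> list[str]:
    """Select property-matched, topologically dissimilar decoys.

    For each active, eligible candidates (ECFP4 max Tanimoto to *any* active
    below the cutoff) are ranked by z-scored Euclidean distance over six
    physicochemical properties (MW, logP, HBD, HBA, rotatable bonds, net
    charge) and the nearest unused ones are taken.  If the constraints are
    infeasible the Tanimoto cutoff is relaxed in steps of 0.05 with a logged
    warning.  Deterministic under a fixed seed.
    """
    actives = list(actives)
    candidate_pool = list(candidate_pool)
    n_requested = per_active * len(actives)
    if len(candidate_pool) < n_requested:
        raise ValueError("candidate pool smaller than requested decoy count")
    props_act = _physchem(actives)
    props_pool = _physchem(candidate_pool)
    mu = props_pool.mean(axis=0)
    sd = props_pool.std(axis=0)
    sd[sd == 0] = 1.0
    z_act = (props_act - mu) / sd
    z_pool = (props_pool - mu) / sd
    fp_act = fingerprint_matrix(actives, FeatureType.ECFP4)
    fp_pool = fingerprint_matrix(candidate_pool, FeatureType.ECFP4)
    max_sim = _bulk_max_tanimoto(fp_pool, fp_act)

    cutoff = tanimoto_cutoff
    while True:
        eligible = np.flatnonzero(max_sim < cutoff)
        if len(eligible) >= n_requested:
            break
        cutoff += 0.05
        logger.warning("decoy constraints infeasible; relaxing Tanimoto cutoff "
                       "to %.2f", cutoff)
        if cutoff > 1.0:
            raise ValueError("cannot satisfy decoy count even without "
                             "dissimilarity constraint")

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(actives))  # active visiting order, seed-fixed
    used = np.zeros(len(candidate_pool), dtype=bool)
    chosen: list[int] = []
    for ai in order:
        d = np.linalg.norm(z_pool[eligible] - z_act[ai], axis=1)
        ranked = eligible[np.argsort(d, kind="mergesort")]
        take = [int(j) for j in ranked if not used[j]][:per_active]
        for j in take:
            used[j] = True
        chosen.extend(take)
    return [candidate_pool[j] for j in chosen]


def evaluate_on_decoys(
    model,
    X_actives,
    X_decoys,
    confident_fn=None,
    fractions=(0.005, 0.01, 0.02, 0.05),
    positive_index: int = 1,
) -> dict:
    """Benchmark a classifier on test actives merged with labelled decoys.

    Returns reports keyed ``"all"`` and, when ``confident_fn`` (a predicate
    over probability rows, e.g. the indeterminate-zone rule) is given,
    ``"ad_filtered"`` restricted to confident predictions.  Each report
    carries the standard metrics plus ROC enrichment of the active class.
    """
    X = np.vstack([np.asarray(X_actives), np.asarray(X_decoys)])
    y = np.array([1] * len(X_actives) + [0] * len(X_decoys))
    proba = model.predict_proba(X)
    classes = [0, 1]
    p2 = np.column_stack([1.0 - proba[:, positive_index], proba[:, positive_index]])
    out = {"all": classification_report(y, p2, classes, fractions=fractions,
                                        positive_class=1)}
    if confident_fn is not None:
        keep = np.array([bool(confident_fn(row)) for row in proba])
        if keep.sum() >= 2 and len(set(y[keep].tolist())) == 2:
            out["ad_filtered"] = classification_report(
                y[keep], p2[keep], classes, fractions=fractions, positive_class=1
            )
        else:
            out["ad_filtered"] = None
            logger.warning("too few confident predictions for an AD-filtered report")
    return out
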