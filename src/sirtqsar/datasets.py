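"""Curation and encoding of structure-activity records.

Raw records are heterogeneous: a compound x isoform measurement is either an
IC50 (stored in µM) or a percent-inhibition value (Inh%) read out at a stated
assay concentration.  This module standardizes structures (salt stripping,
charge neutralization, canonicalization), deduplicates records, converts
potencies to pIC50, encodes activity and selectivity classes with an explicit
"twilight zone" of borderline records that is excluded from classification,
and provides stratified splitting and SMOTE rebalancing of training data.
"""

from __future__ import annotations

import csv
import enum
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski
from rdkit.Chem.MolStandardize import rdMolStandardize
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

__all__ = [
    "Isoform",
    "MeasurementKind",
    "ActivityClass",
    "SelectivityClass",
    "ActivityRecord",
    "CuratedCompound",
    "StandardizationError",
    "standardize_structure",
    "deduplicate",
    "to_pic50",
    "assign_sirt2_class",
    "assign_selectivity_class",
    "stratified_split",
    "rebalance_train",
    "lipinski_violations",
    "read_activity_csv",
    "curate",
]


class Isoform(str, enum.Enum):
    SIRT1 = "SIRT1"
    SIRT2 = "SIRT2"
    SIRT3 = "SIRT3"


class MeasurementKind(str, enum.Enum):
    IC50 = "IC50"
    PERCENT_INHIBITION = "PERCENT_INHIBITION"


class ActivityClass(str, enum.Enum):
    ACTIVE = "ACTIVE"
    INACTIVE = "INACTIVE"
    TWILIGHT = "TWILIGHT"


class SelectivityClass(str, enum.Enum):
    SELECTIVE = "SELECTIVE"
    NONSELECTIVE = "NONSELECTIVE"
    INACTIVE = "INACTIVE"
    EXCLUDED = "EXCLUDED"


class StandardizationError(ValueError):
    """Raised when a SMILES cannot be parsed or standardized."""


@dataclass(frozen=True)
class ActivityRecord:
    """One compound x isoform measurement.

    ``value`` is an IC50 in µM or a percent inhibition; Inh% records must
    carry the assay concentration (µM) at which they were read out.
    """

    compound_id: str
    smiles: str
    isoform: Isoform
    kind: MeasurementKind
    value: float
    assay_conc_uM: float | None = None
    source: str = ""

    def __post_init__(self):
        if not math.isfinite(self.value) or self.value < 0:
            raise ValueError(f"activity value must be finite and >= 0, got {self.value}")
        if self.kind is MeasurementKind.PERCENT_INHIBITION and self.assay_conc_uM is None:
            raise ValueError("Inh% records require assay_conc_uM")
        if self.kind is MeasurementKind.IC50 and self.assay_conc_uM is not None:
            raise ValueError("IC50 records must not carry assay_conc_uM")


@dataclass
class CuratedCompound:
    """A standardized structure with at most one retained record per isoform."""

    canonical_smiles: str
    parent_smiles: str
    records: dict[Isoform, ActivityRecord] = field(default_factory=dict)


_LARGEST_FRAGMENT = None
_UNCHARGER = None


def _standardizers():
    global _LARGEST_FRAGMENT, _UNCHARGER
    if _LARGEST_FRAGMENT is None:
        _LARGEST_FRAGMENT = rdMolStandardize.LargestFragmentChooser(preferOrganic=True)
        _UNCHARGER = rdMolStandardize.Uncharger()
    return _LARGEST_FRAGMENT, _UNCHARGER


def standardize_structure(smiles: str) -> str:
    """Return the canonical SMILES of the neutralized largest organic fragment.

    Salt/solvent fragments are stripped and charges neutralized where
    chemically valid.  The operation is idempotent: feeding its output back
    returns the same string.

    Raises
    ------
    StandardizationError
        If the SMILES cannot be parsed.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StandardizationError(f"unparsable SMILES: {smiles!r}")
    chooser, uncharger = _standardizers()
    mol = chooser.choose(mol)
    mol = uncharger.uncharge(mol)
    mol = rdMolStandardize.Cleanup(mol)
    return Chem.MolToSmiles(mol)


def to_pic50(ic50_uM: float) -> float:
    """pIC50 = -log10(IC50 in mol/L); input in µM, so 10 µM -> 5.0."""
    if not ic50_uM > 0:
        raise ValueError(f"IC50 must be > 0 µM, got {ic50_uM}")
    return -math.log10(ic50_uM * 1e-6)


def from_pic50(pic50: float) -> float:
    """Inverse of :func:`to_pic50`: IC50 in µM."""
    return 10.0 ** (6.0 - pic50)


def assign_sirt2_class(record: ActivityRecord) -> ActivityClass:
    """Encode a single retained record into ACTIVE / INACTIVE / TWILIGHT.

    ACTIVE:  IC50 <= 50 µM, or Inh% >= 80 at >=200 µM, >= 70 at 100 µM,
             >= 60 between 50 and 100 µM, or >= 50 below 50 µM.
    INACTIVE: IC50 >= 90 µM, or Inh% <= 40 when assayed above 100 µM.
    Everything in between is TWILIGHT and is excluded from classification
    datasets (e.g. IC50 in (50, 90) µM; Inh% in (40, 80) at 200 µM).
    """
    if record.kind is MeasurementKind.IC50:
        if record.value <= 50.0:
            return ActivityClass.ACTIVE
        if record.value >= 90.0:
            return ActivityClass.INACTIVE
        return ActivityClass.TWILIGHT
    conc = record.assay_conc_uM
    if conc is None:
        raise ValueError("Inh% record without assay concentration")
    v = record.value
    active = (
        (conc >= 200.0 and v >= 80.0)
        or (conc == 100.0 and v >= 70.0)
        or (50.0 <= conc < 100.0 and v >= 60.0)
        or (conc < 50.0 and v >= 50.0)
    )
    if active:
        return ActivityClass.ACTIVE
    if conc > 100.0 and v <= 40.0:
        return ActivityClass.INACTIVE
    return ActivityClass.TWILIGHT


def assign_selectivity_class(
    sirt2: ActivityClass, offtarget: ActivityClass
) -> SelectivityClass:
    """Combine SIRT2 and off-target (SIRT1 or SIRT3) activity classes.

    SELECTIVE = SIRT2 active, off-target inactive; NONSELECTIVE = both
    active; INACTIVE = both inactive.  Twilight on either isoform, or the
    SIRT2-inactive / off-target-active combination, is EXCLUDED.
    """
    if ActivityClass.TWILIGHT in (sirt2, offtarget):
        return SelectivityClass.EXCLUDED
    if sirt2 is ActivityClass.ACTIVE:
        if offtarget is ActivityClass.INACTIVE:
            return SelectivityClass.SELECTIVE
        return SelectivityClass.NONSELECTIVE
    if offtarget is ActivityClass.INACTIVE:
        return SelectivityClass.INACTIVE
    return SelectivityClass.EXCLUDED


def _more_potent(a: ActivityRecord, b: ActivityRecord) -> ActivityRecord:
    # Tie-break: keep the more potent record (smaller IC50 / larger Inh%).
    if a.kind is MeasurementKind.IC50:
        return a if a.value <= b.value else b
    return a if a.value >= b.value else b


def _closest_to_mean(records: list[ActivityRecord]) -> ActivityRecord:
    values = np.array([r.value for r in records], dtype=float)
    mean = values.mean()
    best = records[0]
    for r in records[1:]:
        d_r, d_best = abs(r.value - mean), abs(best.value - mean)
        if d_r < d_best:
            best = r
        elif d_r == d_best:
            best = _more_potent(best, r)
    return best


def deduplicate(records: Iterable[ActivityRecord]) -> list[CuratedCompound]:
    """Group standardized records by (parent SMILES, isoform) and retain one.

    Within a group, IC50 records take precedence over Inh% records; among
    records of the retained kind the one closest to the group mean is kept,
    ties going to the more potent value.  The result never has more
    compounds than the input and is independent of input order.
    """
    by_smiles: dict[str, dict[Isoform, list[ActivityRecord]]] = {}
    for rec in records:
        smi = standardize_structure(rec.smiles)
        by_smiles.setdefault(smi, {}).setdefault(rec.isoform, []).append(rec)
    out = []
    for smi in sorted(by_smiles):
        compound = CuratedCompound(canonical_smiles=smi, parent_smiles=smi)
        for iso, group in by_smiles[smi].items():
            ic50s = [r for r in group if r.kind is MeasurementKind.IC50]
            pool = ic50s if ic50s else group
            compound.records[iso] = _closest_to_mean(pool)
        out.append(compound)
    return out


def stratified_split(
    labels: Sequence,
    test_fraction: float,
    seed: int,
    *,
    regression: bool = False,
    n_bins: int = 5,
) -> np.ndarray:
    """Assign each row to "TRAIN" or "TEST", preserving label proportions.

    Classification labels are used as strata directly; regression labels are
    binned into ``n_bins`` equal-frequency quantile bins first.  Per-stratum
    test counts equal the proportional allocation within one compound.
    Deterministic under a fixed seed.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if n < 10:
        raise ValueError("need at least 10 rows to split")
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    if regression:
        y = labels.astype(float)
        if not np.all(np.isfinite(y)):
            raise ValueError("regression labels must be finite")
        bins = max(2, min(n_bins, n // 2))
        while bins >= 2:
            strata = pd.qcut(y, bins, labels=False, duplicates="drop")
            counts = pd.Series(strata).value_counts()
            if counts.min() >= 2:
                break
            bins -= 1  # merge sparse quantile bins with neighbors
        else:
            strata = np.zeros(n, dtype=int)
    else:
        strata = labels
        counts = pd.Series(strata).value_counts()
        if counts.min() < 2:
            raise ValueError("every class stratum needs at least 2 members")

    rng = np.random.default_rng(seed)
    assignment = np.full(n, "TRAIN", dtype=object)
    strata = np.asarray(strata)
    # Deterministic order over strata keys.
    for key in sorted(pd.unique(strata), key=str):
        idx = np.flatnonzero(strata == key)
        n_test = int(round(len(idx) * test_fraction))
        n_test = min(max(n_test, 1), len(idx) - 1)
        chosen = rng.choice(idx, size=n_test, replace=False)
        assignment[chosen] = "TEST"
    return assignment


def rebalance_train(
    X: np.ndarray,
    y: Sequence,
    seed: int,
    k_neighbors: int = 5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """SMOTE: oversample minority classes to the majority count.

    Synthetic rows are linear interpolations between a minority row and one
    of its ``k_neighbors`` nearest same-class neighbors.  Returns
    ``(X_out, y_out, synthetic_flag)`` where the flag marks generated rows.
    Classes too small for the requested neighbor count fall back to a
    reduced ``k`` with a logged warning.
    """
    from sklearn.neighbors import NearestNeighbors

    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    counts = pd.Series(y).value_counts()
    n_major = counts.max()
    X_new, y_new = [], []
    for cls in sorted(counts.index, key=str):
        deficit = int(n_major - counts[cls])
        if deficit == 0:
            continue
        Xc = X[y == cls]
        k = min(k_neighbors, len(Xc) - 1)
        if k < 1:
            raise ValueError(f"class {cls!r} has {len(Xc)} member(s); cannot SMOTE")
        if k < k_neighbors:
            logger.warning(
                "class %r has %d members; reducing SMOTE neighbors to %d",
                cls, len(Xc), k,
            )
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Xc)
        _, neigh = nn.kneighbors(Xc)
        base = rng.integers(0, len(Xc), size=deficit)
        pick = rng.integers(1, k + 1, size=deficit)  # skip self at column 0
        lam = rng.uniform(0.0, 1.0, size=deficit)
        for b, p, l in zip(base, pick, lam):
            x0, x1 = Xc[b], Xc[neigh[b, p]]
            X_new.append(x0 + l * (x1 - x0))
            y_new.append(cls)
    if not X_new:
        return X, y, np.zeros(len(y), dtype=bool)
    X_out = np.vstack([X, np.asarray(X_new)])
    y_out = np.concatenate([y, np.asarray(y_new)])
    flag = np.concatenate([np.zeros(len(y), dtype=bool), np.ones(len(y_new), dtype=bool)])
    return X_out, y_out, flag


def lipinski_violations(smiles: str) -> int:
    """Count violations of the rule of 5 (MW<=500, logP<=5, HBD<=5, HBA<=10)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StandardizationError(f"unparsable SMILES: {smiles!r}")
    return sum(
        [
            Descriptors.MolWt(mol) > 500.0,
            Crippen.MolLogP(mol) > 5.0,
            Lipinski.NumHDonors(mol) > 5,
            Lipinski.NumHAcceptors(mol) > 10,
        ]
    )


_UNIT_TO_UM = {"uM": 1.0, "um": 1.0, "µM": 1.0, "nM": 1e-3, "nm": 1e-3, "M": 1e6, "m": 1e6}

CSV_COLUMNS = [
    "compound_id", "smiles", "isoform", "kind", "value", "unit",
    "assay_conc_uM", "source",
]


def read_activity_csv(path: str | Path) -> tuple[list[ActivityRecord], list[dict]]:
    """Read raw activity records; malformed rows become reject entries.

    Expected columns: ``compound_id, smiles, isoform, kind, value, unit,
    assay_conc_uM, source``.  IC50 values may be given in µM, nM or M and
    are stored in µM.  Returns ``(records, rejects)`` where each reject is a
    dict with the original row plus a ``reason`` code.
    """
    records, rejects = [], []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(CSV_COLUMNS[:5]) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"missing required CSV columns: {sorted(missing)}")
        for row in reader:
            try:
                kind = MeasurementKind(row["kind"].strip())
                value = float(row["value"])
                if kind is MeasurementKind.IC50:
                    unit = (row.get("unit") or "uM").strip()
                    if unit not in _UNIT_TO_UM:
                        raise ValueError(f"unknown unit {unit!r}")
                    value *= _UNIT_TO_UM[unit]
                    conc = None
                else:
                    raw = (row.get("assay_conc_uM") or "").strip()
                    conc = float(raw) if raw else None
                rec = ActivityRecord(
                    compound_id=row["compound_id"],
                    smiles=row["smiles"],
                    isoform=Isoform(row["isoform"].strip()),
                    kind=kind,
                    value=value,
                    assay_conc_uM=conc,
                    source=row.get("source", "") or "",
                )
                # Fail early on unparsable structures so the row is rejected.
                standardize_structure(rec.smiles)
                records.append(rec)
            except (ValueError, KeyError, StandardizationError) as exc:
                rejects.append({**row, "reason": str(exc)})
    return records, rejects


def curate(
    input_csv: str | Path,
    output_csv: str | Path | None = None,
) -> tuple[list[CuratedCompound], dict]:
    """Full curation: read, standardize, deduplicate, encode, and log.

    Writes the curated table plus ``*.rejects.csv`` sidecar and a JSON
    curation log next to ``output_csv`` when given.  The log reports counts
    removed per rule and the SIRT2 class histogram.
    """
    records, rejects = read_activity_csv(input_csv)
    compounds = deduplicate(records)
    n_retained = sum(len(c.records) for c in compounds)
    hist: dict[str, int] = {}
    for c in compounds:
        rec = c.records.get(Isoform.SIRT2)
        if rec is not None:
            hist.setdefault(assign_sirt2_class(rec).value, 0)
            hist[assign_sirt2_class(rec).value] += 1
    log = {
        "n_input_rows": len(records) + len(rejects),
        "n_rejected_rows": len(rejects),
        "n_records_after_parse": len(records),
        "n_records_removed_as_duplicates": len(records) - n_retained,
        "n_compounds": len(compounds),
        "sirt2_class_histogram": hist,
    }
    if output_csv is not None:
        output_csv = Path(output_csv)
        rows = []
        for c in compounds:
            for iso, rec in sorted(c.records.items(), key=lambda kv: kv[0].value):
                rows.append(
                    {
                        "compound_id": rec.compound_id,
                        "canonical_smiles": c.canonical_smiles,
                        "isoform": iso.value,
                        "kind": rec.kind.value,
                        "value": rec.value,
                        "assay_conc_uM": rec.assay_conc_uM,
                        "source": rec.source,
                    }
                )
        pd.DataFrame(rows).to_csv(output_csv, index=False)
        if rejects:
            pd.DataFrame(rejects).to_csv(
                output_csv.with_suffix(".rejects.csv"), index=False
            )
        with open(output_csv.with_suffix(".log.json"), "w") as fh:
            json.dump(log, fh, indent=2)
    return compounds, log
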