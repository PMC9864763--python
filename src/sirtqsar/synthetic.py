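"""Synthetic structure-activity data with a planted, recoverable signal.

The generator emulates the statistical structure of a curated sirtuin
inhibition corpus without any download: a mix of IC50 and Inh% records,
roughly a 2:1 active:inactive balance, three-class selectivity labels
driven by a second substructure rule, occasional salt forms and duplicate
measurements to exercise curation, and a potency signal carried by counts
of halogenated substituents so that regression models have structure to
learn.

Compounds are assembled from aromatic scaffold templates; actives carry a
planted pharmacophore substituent (a sulfonamide by default).  pIC50 values
for planted actives are baseline + effect * (number of potency-modulating
substituents) + Gaussian noise, truncated to the class-consistent region
(IC50 <= 50 µM); planted inactives draw from N(4.2, 0.4) truncated to
IC50 >= 90 µM.  The resulting marginals approximate actives ~ N(6.0, 0.7)
and span the 4-8 pIC50 range typical of the public corpus.

Inh% records are derived from the latent IC50 through a one-site binding
curve (Inh% = 100 c / (c + IC50)) at a 200 µM assay concentration and only
emitted when consistent with the class-encoding rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from .datasets import from_pic50

__all__ = [
    "SyntheticSARConfig",
    "generate_synthetic_sar",
    "generate_candidate_pool",
    "reference_library",
]


ACTIVE_TEMPLATES = [
    "c1c({r1})cc({r2})c({r3})c1{ph}",
    "c1c({r1})cc({r2})c({r3})c1C{ph}",
    "c1c({r1})cc({r2})c({r3})c1CC{ph}",
    "c1c({r1})cc({r2})c({r3})c1O{ph}",
    "c1c({r1})cc({r2})c({r3})c1N{ph}",
    "c1c({r1})cc({r2})c({r3})c1C(=O)N{ph}",
    "c1c({r1})cc({r2})c({r3})c1OC{ph}",
    "c1c({r1})cc({r2})c({r3})c1NC{ph}",
    "C(c1c({r1})cc({r2})cc1{r3}){ph}",
    "C(Cc1c({r1})cc({r2})cc1{r3}){ph}",
    "c1c({r1})cc2cc({r2})c({r3})cc2c1{ph}",
    "C(=O)(c1c({r1})cc({r2})cc1{r3})N{ph}",
]

# Decoy/pool scaffolds: saturated and O/N-heterocyclic frames topologically
# distant from the aromatic active series.  Deliberately asymmetric so that
# distinct substituent draws rarely collapse to the same canonical SMILES.
POOL_TEMPLATES = [
    "C1CCC({r1})C({r2})C1C({r3}){t}",
    "C1CCN(C({r1})C1{r2})C({r3}){t}",
    "C1CCOC({r1})C1C({r2})C({r3}){t}",
    "C1CC({r1})CCN1C({r2})C({r3}){t}",
    "O1CCN(CC1C({r1}){r2})C({r3}){t}",
    "C1CCC(CC1{r1})C({r2})({r3})C{t}",
    "N1C({r1})CC({r2})CC1C({r3}){t}",
    "C1CC1C({r1})({r2})CC({r3}){t}",
    "C1COC({r1})C1N({r2})C({r3}){t}",
    "C1CSC({r1})C1C({r2})N({r3}){t}",
]

POOL_SUBS = ["[H]", "C", "CC", "O", "N", "CO", "CN", "OC", "CCC", "C(C)C",
             "OCC", "NC"]

PLAIN_SUBS = ["[H]", "C", "CC", "OC", "C#N", "N", "O", "CO", "N(C)C"]
POTENCY_SUBS = ["F", "Cl", "C(F)(F)F"]
NEUTRAL_TAILS = ["C(C)C", "OC", "N(C)C", "CC(C)=O", "CCO"]
POOL_TAILS = ["C", "CC", "O", "N", "CCC", "OCC", "C(C)C", "CN", "CO", "CCN"]


@dataclass
class SyntheticSARConfig:
    """Study conditions for the planted-signal fixture.

    ``active_fraction`` controls the planted active:inactive balance (the
    curated corpus runs roughly 2:1).  ``potency_effect`` is the pIC50 shift
    per potency-modulating substituent; with ``potency_sub_prob`` per slot it
    composes the active marginal around mean 6.0.  ``inh_fraction`` is the
    share of records emitted as Inh% at ``assay_conc_uM``.
    """

    n_compounds: int = 1500
    active_fraction: float = 0.65
    pharmacophore: str = "S(=O)(=O)N"        # planted SIRT2 signal (branch SMILES)
    pharmacophore_smarts: str = "S(=O)(=O)N"
    offtarget_group: str = "C(=O)O"          # planted selectivity signal
    offtarget_smarts: str = "C(=O)[OX2H1]"
    label_noise: float = 0.0
    potency_base: float = 5.1
    potency_effect: float = 0.6
    potency_sub_prob: float = 0.5
    noise_sd: float = 0.25
    inactive_mean: float = 4.2
    inactive_sd: float = 0.4
    inh_fraction: float = 0.25
    assay_conc_uM: float = 200.0
    offtarget_record_prob: float = 0.6       # share with a SIRT1 or SIRT3 record
    offtarget_active_prob: float = 0.4       # share carrying the selectivity group
    salt_fraction: float = 0.03
    duplicate_fraction: float = 0.03
    seed: int = 0

    def __post_init__(self):
        for name in ("active_fraction", "inh_fraction", "offtarget_record_prob",
                     "offtarget_active_prob"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0 and not (name == "active_fraction" and 0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if not 0.0 < self.active_fraction < 1.0:
            raise ValueError("active_fraction must lie in (0, 1)")


ACTIVE_PIC50_FLOOR = 6.0 - np.log10(50.0)    # IC50 <= 50 µM
INACTIVE_PIC50_CEIL = 6.0 - np.log10(90.0)   # IC50 >= 90 µM


def _truncated_normal(rng, mean, sd, low=None, high=None):
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if (low is None or v >= low) and (high is None or v <= high):
            return float(v)
    # Distribution mass in the window is tiny; clamp rather than loop forever.
    return float(min(high, low) if high is not None and low is None else
                 (low if low is not None else high))


def _assemble(rng: np.random.Generator, template: str, subs: dict) -> str | None:
    smi = template.format(**subs)
    mol = Chem.MolFromSmiles(smi)
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


def _sample_compound(rng: np.random.Generator, cfg: SyntheticSARConfig,
                     is_active: bool, off_active: bool):
    """Assemble one molecule; returns (canonical smiles, n_potency_subs)."""
    while True:
        template = ACTIVE_TEMPLATES[rng.integers(len(ACTIVE_TEMPLATES))]
        subs = {}
        n_pot = 0
        for slot in ("r1", "r2", "r3"):
            if rng.uniform() < cfg.potency_sub_prob:
                subs[slot] = POTENCY_SUBS[rng.integers(len(POTENCY_SUBS))]
                n_pot += 1
            else:
                subs[slot] = PLAIN_SUBS[rng.integers(len(PLAIN_SUBS))]
        if off_active:
            # Replace one slot with the selectivity-driving group.
            subs["r1"] = cfg.offtarget_group
            n_pot = sum(subs[s] in POTENCY_SUBS for s in ("r1", "r2", "r3"))
        subs["ph"] = (cfg.pharmacophore if is_active
                      else NEUTRAL_TAILS[rng.integers(len(NEUTRAL_TAILS))])
        smi = _assemble(rng, template, subs)
        if smi is not None:
            return smi, n_pot


def _sirt2_pic50(rng, cfg, is_active, n_pot):
    if is_active:
        mean = cfg.potency_base + cfg.potency_effect * n_pot
        return _truncated_normal(rng, mean, cfg.noise_sd, low=ACTIVE_PIC50_FLOOR)
    return _truncated_normal(rng, cfg.inactive_mean, cfg.inactive_sd,
                             high=INACTIVE_PIC50_CEIL)


def _emit_record(rng, cfg, compound_id, smiles, isoform, pic50, rows, truth_active):
    ic50 = from_pic50(pic50)
    conc = cfg.assay_conc_uM
    inh = 100.0 * conc / (conc + ic50)
    consistent = (truth_active and inh >= 80.0) or (not truth_active and inh <= 40.0)
    if rng.uniform() < cfg.inh_fraction and consistent:
        rows.append({
            "compound_id": compound_id, "smiles": smiles, "isoform": isoform,
            "kind": "PERCENT_INHIBITION", "value": round(inh, 2), "unit": "",
            "assay_conc_uM": conc, "source": "synthetic",
        })
    else:
        rows.append({
            "compound_id": compound_id, "smiles": smiles, "isoform": isoform,
            "kind": "IC50", "value": round(ic50, 4), "unit": "uM",
            "assay_conc_uM": "", "source": "synthetic",
        })


def generate_synthetic_sar(
    config: SyntheticSARConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate raw activity records plus the planted ground truth.

    Returns ``(records, truth)``.  ``records`` follows the raw CSV schema
    (compound_id, smiles, isoform, kind, value, unit, assay_conc_uM,
    source) and includes occasional salt forms and duplicate measurements.
    ``truth`` holds one row per compound with the planted SIRT2 class,
    latent pIC50, potency-substituent count, and off-target activity flags.
    Two runs with the same config (including seed) are identical.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    seen: set[str] = set()
    rows: list[dict] = []
    truth_rows: list[dict] = []
    misses = 0
    while len(truth_rows) < cfg.n_compounds:
        if misses > 50 * max(cfg.n_compounds, 1000):
            raise RuntimeError("scaffold space exhausted; reduce n_compounds")
        planted_active = bool(rng.uniform() < cfg.active_fraction)
        if rng.uniform() < cfg.label_noise:
            planted_active = not planted_active
        has_off_group = bool(rng.uniform() < cfg.offtarget_active_prob)
        smi, n_pot = _sample_compound(rng, cfg, planted_active, has_off_group)
        if smi in seen:
            misses += 1
            continue
        seen.add(smi)
        cid = f"SYN{len(truth_rows):05d}"
        pic50 = _sirt2_pic50(rng, cfg, planted_active, n_pot)
        emitted_smi = smi
        if rng.uniform() < cfg.salt_fraction:
            emitted_smi = smi + ".Cl"
        _emit_record(rng, cfg, cid, emitted_smi, "SIRT2", pic50, rows, planted_active)
        if rng.uniform() < cfg.duplicate_fraction:
            jitter = float(np.clip(pic50 + rng.normal(0, 0.05),
                                   ACTIVE_PIC50_FLOOR if planted_active else 0.0,
                                   np.inf if planted_active else INACTIVE_PIC50_CEIL))
            _emit_record(rng, cfg, cid, smi, "SIRT2", jitter, rows, planted_active)

        off_iso = None
        off_active = None
        if rng.uniform() < cfg.offtarget_record_prob:
            off_iso = "SIRT1" if rng.uniform() < 0.6 else "SIRT3"
            off_active = has_off_group
            if rng.uniform() < cfg.label_noise:
                off_active = not off_active
            off_pic50 = (_truncated_normal(rng, 5.6, 0.5, low=ACTIVE_PIC50_FLOOR)
                         if off_active else
                         _truncated_normal(rng, cfg.inactive_mean, cfg.inactive_sd,
                                           high=INACTIVE_PIC50_CEIL))
            _emit_record(rng, cfg, cid, smi, off_iso, off_pic50, rows, off_active)

        truth_rows.append({
            "compound_id": cid,
            "smiles": smi,
            "planted_active": planted_active,
            "pic50": pic50,
            "n_potency_subs": n_pot,
            "offtarget_isoform": off_iso,
            "offtarget_active": off_active,
        })
    records = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    return records, truth


def generate_candidate_pool(n: int, seed: int) -> list[str]:
    """Unique pharmacophore-free molecules from the pool scaffolds.

    Used as decoy candidates and as a screening library: property ranges
    overlap the active series but the scaffolds are topologically distant,
    keeping ECFP4 similarity to the actives low.
    """
    rng = np.random.default_rng(seed)
    out: list[str] = []
    seen: set[str] = set()
    misses = 0
    while len(out) < n:
        template = POOL_TEMPLATES[rng.integers(len(POOL_TEMPLATES))]
        subs = {
            "r1": POOL_SUBS[rng.integers(len(POOL_SUBS))],
            "r2": POOL_SUBS[rng.integers(len(POOL_SUBS))],
            "r3": POOL_SUBS[rng.integers(len(POOL_SUBS))],
            "t": POOL_TAILS[rng.integers(len(POOL_TAILS))],
        }
        smi = _assemble(rng, template, subs)
        if smi is None or smi in seen:
            misses += 1
            if misses > 50 * max(n, 1000):
                raise RuntimeError(
                    f"candidate space exhausted after {len(out)} unique molecules"
                )
            continue
        seen.add(smi)
        out.append(smi)
    return out


def reference_library(truth: pd.DataFrame, n: int, seed: int) -> pd.DataFrame:
    """A compound_id + SMILES reference table for nearest-neighbor lookup."""
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(truth), size=min(n, len(truth)), replace=False)
    return truth.iloc[np.sort(idx)][["compound_id", "smiles"]].reset_index(drop=True)
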