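"""Curation, activity encoding, splitting, and rebalancing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sirtqsar import datasets as ds
from sirtqsar.datasets import (
    ActivityClass,
    ActivityRecord,
    Isoform,
    MeasurementKind,
    SelectivityClass,
    StandardizationError,
)


def rec(value, kind=MeasurementKind.IC50, conc=None, iso=Isoform.SIRT2,
        smiles="c1ccccc1CCO", cid="C1"):
    return ActivityRecord(compound_id=cid, smiles=smiles, isoform=iso,
                         kind=kind, value=value, assay_conc_uM=conc)


class TestStandardize:
    @pytest.mark.parametrize(
        "smiles,expected",
        [
            ("CCO", "CCO"),
            ("CC(=O)[O-].[Na+]", "CC(=O)O"),  # salt stripped, charge neutralized
            ("OCC", "CCO"),                   # canonical invariance
        ],
    )
    def test_examples(self, smiles, expected):
        assert ds.standardize_structure(smiles) == expected

    def test_invalid_smiles_rejected(self):
        with pytest.raises(StandardizationError):
            ds.standardize_structure("not_a_smiles")

    @given(st.sampled_from([
        "CCO", "c1ccccc1", "CC(=O)Nc1ccc(O)cc1", "C[N+](C)(C)C.[Cl-]",
        "OC(=O)c1ccccc1.[Na+]", "c1ccc2[nH]ccc2c1", "CC(C)CC(N)C(=O)O",
    ]))
    @settings(deadline=None, max_examples=20)
    def test_idempotent(self, smiles):
        once = ds.standardize_structure(smiles)
        assert ds.standardize_structure(once) == once


class TestDeduplicate:
    def test_closest_to_mean_retained(self):
        out = ds.deduplicate([rec(1.0), rec(2.0), rec(6.0)])
        assert len(out) == 1
        assert out[0].records[Isoform.SIRT2].value == 2.0  # mean 3, |2-3| minimal

    def test_ic50_precedence_over_inh(self):
        out = ds.deduplicate([
            rec(10.0),
            rec(90.0, kind=MeasurementKind.PERCENT_INHIBITION, conc=200.0),
        ])
        assert out[0].records[Isoform.SIRT2].kind is MeasurementKind.IC50

    def test_single_record_identity(self):
        out = ds.deduplicate([rec(5.0)])
        assert out[0].records[Isoform.SIRT2].value == 5.0

    def test_tie_keeps_more_potent(self):
        out = ds.deduplicate([rec(2.0), rec(4.0)])  # both 1 from mean 3
        assert out[0].records[Isoform.SIRT2].value == 2.0

    def test_permutation_invariant_and_never_grows(self, rng):
        records = [rec(v, cid=f"C{i}") for i, v in
                   enumerate([1.0, 2.0, 6.0, 9.0, 3.5])]
        records += [rec(12.0, smiles="CCO", cid="X")]
        base = ds.deduplicate(records)
        assert len(base) <= len(records)
        for _ in range(5):
            perm = [records[i] for i in rng.permutation(len(records))]
            out = ds.deduplicate(perm)
            assert [(c.canonical_smiles,
                     c.records[Isoform.SIRT2].value) for c in out] == \
                   [(c.canonical_smiles,
                     c.records[Isoform.SIRT2].value) for c in base]

    def test_salt_form_merges_with_parent(self):
        out = ds.deduplicate([
            rec(1.0, smiles="CC(=O)O"), rec(3.0, smiles="CC(=O)[O-].[Na+]"),
        ])
        assert len(out) == 1


class TestPIC50:
    def test_values(self):
        assert ds.to_pic50(10.0) == pytest.approx(5.0)
        assert ds.to_pic50(100.0) == pytest.approx(4.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            ds.to_pic50(0.0)

    def test_roundtrip(self):
        assert ds.from_pic50(ds.to_pic50(37.0)) == pytest.approx(37.0)


class TestSirt2Class:
    @pytest.mark.parametrize(
        "value,kind,conc,expected",
        [
            (50.0, MeasurementKind.IC50, None, ActivityClass.ACTIVE),
            (70.0, MeasurementKind.IC50, None, ActivityClass.TWILIGHT),
            (90.0, MeasurementKind.IC50, None, ActivityClass.INACTIVE),
            (60.0, MeasurementKind.PERCENT_INHIBITION, 200.0, ActivityClass.TWILIGHT),
            (80.0, MeasurementKind.PERCENT_INHIBITION, 200.0, ActivityClass.ACTIVE),
            (40.0, MeasurementKind.PERCENT_INHIBITION, 150.0, ActivityClass.INACTIVE),
            (70.0, MeasurementKind.PERCENT_INHIBITION, 100.0, ActivityClass.ACTIVE),
            (60.0, MeasurementKind.PERCENT_INHIBITION, 75.0, ActivityClass.ACTIVE),
            (50.0, MeasurementKind.PERCENT_INHIBITION, 25.0, ActivityClass.ACTIVE),
            (45.0, MeasurementKind.PERCENT_INHIBITION, 25.0, ActivityClass.TWILIGHT),
        ],
    )
    def test_rule_table(self, value, kind, conc, expected):
        assert ds.assign_sirt2_class(rec(value, kind=kind, conc=conc)) is expected

    def test_total_and_exclusive_on_grid(self):
        """Every (value, concentration) combination maps to exactly one class."""
        for ic50 in np.arange(0.1, 200.1, 0.9):
            cls = ds.assign_sirt2_class(rec(float(ic50)))
            want = (ActivityClass.ACTIVE if ic50 <= 50
                    else ActivityClass.INACTIVE if ic50 >= 90
                    else ActivityClass.TWILIGHT)
            assert cls is want
        for inh in np.arange(0.0, 100.5, 2.5):
            for conc in [10.0, 25.0, 49.0, 50.0, 75.0, 99.0, 100.0, 150.0,
                         200.0, 250.0]:
                cls = ds.assign_sirt2_class(
                    rec(float(inh), kind=MeasurementKind.PERCENT_INHIBITION,
                        conc=conc))
                assert cls in (ActivityClass.ACTIVE, ActivityClass.INACTIVE,
                               ActivityClass.TWILIGHT)

    def test_inh_record_requires_concentration(self):
        with pytest.raises(ValueError):
            ActivityRecord("C", "CCO", Isoform.SIRT2,
                           MeasurementKind.PERCENT_INHIBITION, 50.0, None)


class TestSelectivity:
    @pytest.mark.parametrize(
        "sirt2,off,expected",
        [
            (ActivityClass.ACTIVE, ActivityClass.INACTIVE, SelectivityClass.SELECTIVE),
            (ActivityClass.ACTIVE, ActivityClass.ACTIVE, SelectivityClass.NONSELECTIVE),
            (ActivityClass.INACTIVE, ActivityClass.INACTIVE, SelectivityClass.INACTIVE),
            (ActivityClass.TWILIGHT, ActivityClass.ACTIVE, SelectivityClass.EXCLUDED),
            (ActivityClass.ACTIVE, ActivityClass.TWILIGHT, SelectivityClass.EXCLUDED),
            (ActivityClass.INACTIVE, ActivityClass.ACTIVE, SelectivityClass.EXCLUDED),
        ],
    )
    def test_table(self, sirt2, off, expected):
        assert ds.assign_selectivity_class(sirt2, off) is expected


class TestStratifiedSplit:
    def test_proportional_allocation(self):
        labels = ["ACTIVE"] * 60 + ["INACTIVE"] * 40
        a = ds.stratified_split(labels, 0.3, seed=5)
        test = np.asarray(labels)[a == "TEST"]
        assert (test == "ACTIVE").sum() == 18
        assert (test == "INACTIVE").sum() == 12

    def test_deterministic(self):
        labels = ["A"] * 30 + ["B"] * 20
        a1 = ds.stratified_split(labels, 0.3, seed=9)
        a2 = ds.stratified_split(labels, 0.3, seed=9)
        assert (a1 == a2).all()

    def test_partition(self):
        labels = ["A"] * 30 + ["B"] * 20
        a = ds.stratified_split(labels, 0.3, seed=0)
        assert set(a) == {"TRAIN", "TEST"}
        assert len(a) == 50

    def test_regression_quantile_bins(self, rng):
        y = rng.uniform(4, 8, size=200)
        a = ds.stratified_split(y, 0.3, seed=3, regression=True, n_bins=4)
        # brute-force count check: each quantile quarter splits 70/30 +/- 1
        order = np.argsort(y)
        for q in range(4):
            idx = order[q * 50:(q + 1) * 50]
            n_test = (a[idx] == "TEST").sum()
            assert abs(n_test - 15) <= 1

    def test_small_stratum_errors_for_classification(self):
        with pytest.raises(ValueError):
            ds.stratified_split(["A"] * 19 + ["B"], 0.3, seed=0)

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            ds.stratified_split(["A"] * 5, 0.3, seed=0)


class TestRebalance:
    def test_balances_to_majority(self, rng):
        X = rng.normal(size=(150, 4))
        y = np.array(["A"] * 100 + ["B"] * 50)
        Xo, yo, flag = ds.rebalance_train(X, y, seed=0)
        assert (yo == "A").sum() == (yo == "B").sum() == 100
        assert flag.sum() == 50
        assert not flag[:150].any()  # originals never flagged

    def test_three_classes(self, rng):
        X = rng.normal(size=(210, 3))
        y = np.array(["A"] * 120 + ["B"] * 60 + ["C"] * 30)
        _, yo, _ = ds.rebalance_train(X, y, seed=1)
        assert all((yo == c).sum() == 120 for c in "ABC")

    def test_already_balanced_unchanged(self, rng):
        X = rng.normal(size=(40, 2))
        y = np.array(["A"] * 20 + ["B"] * 20)
        Xo, yo, flag = ds.rebalance_train(X, y, seed=2)
        assert len(yo) == 40 and not flag.any()
        np.testing.assert_array_equal(Xo, X)

    def test_synthetic_rows_interpolate_originals(self, rng):
        X = np.vstack([rng.normal(size=(30, 2)), rng.normal(size=(10, 2)) + 50])
        y = np.array(["A"] * 30 + ["B"] * 10)
        Xo, yo, flag = ds.rebalance_train(X, y, seed=3)
        synth = Xo[flag]
        # interpolations stay inside the minority class's bounding box
        assert synth.min() > 40 and (yo[flag] == "B").all()

    def test_tiny_class_k_reduced(self, rng, caplog):
        X = rng.normal(size=(23, 2))
        y = np.array(["A"] * 20 + ["B"] * 3)
        _, yo, _ = ds.rebalance_train(X, y, seed=4, k_neighbors=5)
        assert (yo == "B").sum() == 20


class TestLipinski:
    def test_small_molecules_pass(self):
        assert ds.lipinski_violations("CCO") == 0
        assert ds.lipinski_violations("O") == 0

    def test_c40_hydrocarbon_violates_mw_and_logp(self):
        c40 = "C" * 40
        assert ds.lipinski_violations(c40) >= 2


class TestCSVRoundTrip:
    def test_read_reject_and_curate(self, tmp_path):
        df = pd.DataFrame([
            {"compound_id": "A", "smiles": "CCO", "isoform": "SIRT2",
             "kind": "IC50", "value": 10, "unit": "uM", "assay_conc_uM": "",
             "source": "t"},
            {"compound_id": "B", "smiles": "CCN", "isoform": "SIRT2",
             "kind": "IC50", "value": 2000, "unit": "nM", "assay_conc_uM": "",
             "source": "t"},
            {"compound_id": "C", "smiles": "xxx", "isoform": "SIRT2",
             "kind": "IC50", "value": 1, "unit": "uM", "assay_conc_uM": "",
             "source": "t"},
            {"compound_id": "D", "smiles": "CCCC", "isoform": "SIRT2",
             "kind": "PERCENT_INHIBITION", "value": 90, "unit": "",
             "assay_conc_uM": 200, "source": "t"},
        ])
        path = tmp_path / "raw.csv"
        df.to_csv(path, index=False)
        records, rejects = ds.read_activity_csv(path)
        assert len(records) == 3 and len(rejects) == 1
        nm = [r for r in records if r.compound_id == "B"][0]
        assert nm.value == pytest.approx(2.0)  # nM converted to µM
        compounds, log = ds.curate(path, tmp_path / "curated.csv")
        assert log["n_rejected_rows"] == 1
        assert (tmp_path / "curated.csv").exists()
        assert (tmp_path / "curated.rejects.csv").exists()
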