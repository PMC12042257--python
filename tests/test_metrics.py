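"""Evaluation metrics against brute-force and library oracles."""

import numpy as np
import pytest
from lifelines.utils import concordance_index as lifelines_ci

from atomspan import chem
from atomspan.covalent import CovalentRecord, build_adduct_example
from atomspan.metrics import (
    adduct_task_accuracy,
    auprc,
    concordance_index,
    f_max,
    regression_suite,
)


# ---- F_max ------------------------------------------------------------------

def brute_force_fmax(truth, scores):
    """Naive sweep over every distinct score value (test oracle)."""
    truth = np.asarray(truth, bool)
    scores = np.asarray(scores, float)
    best = 0.0
    for t in np.unique(scores):
        precisions, recalls = [], []
        for i in range(truth.shape[0]):
            pred = (scores[i] >= t) & (scores[i] > 0)
            tp = int((pred & truth[i]).sum())
            if pred.sum() > 0:
                precisions.append(tp / pred.sum())
            if truth[i].sum() > 0:
                recalls.append(tp / truth[i].sum())
        pr = float(np.mean(precisions)) if precisions else 0.0
        rc = float(np.mean(recalls)) if recalls else 0.0
        if pr + rc > 0:
            best = max(best, 2 * pr * rc / (pr + rc))
    return best


def test_fmax_perfect_and_zero_scores():
    truth = np.array([[1, 0, 1], [0, 1, 0]], bool)
    perfect = truth.astype(float)
    assert f_max(truth, perfect)[0] == pytest.approx(1.0)
    zero = np.zeros_like(perfect)
    # a zero score is no prediction, so every threshold yields F1 = 0
    assert f_max(truth, zero)[0] == 0.0


def test_fmax_matches_brute_force_on_random_instances(rng):
    for _ in range(100):
        n, c = int(rng.integers(2, 6)), int(rng.integers(2, 5))
        truth = rng.random((n, c)) < 0.4
        if not truth.any():
            truth[0, 0] = True
        scores = np.round(rng.random((n, c)), 2)
        assert f_max(truth, scores)[0] == pytest.approx(
            brute_force_fmax(truth, scores))


def test_fmax_requires_positives():
    with pytest.raises(ValueError):
        f_max(np.zeros((2, 3), bool), np.random.rand(2, 3))


# ---- AUPRC ------------------------------------------------------------------

def test_auprc_perfect_separation():
    truth = np.array([[1, 1, 0, 0]], bool)
    scores = np.array([[0.9, 0.8, 0.2, 0.1]])
    assert auprc(truth, scores) == pytest.approx(1.0)


def test_auprc_six_point_step_integration():
    # hand-integrated step curve: ranked labels 1,0,1,1,0,0
    truth = np.array([[1, 0, 1, 1, 0, 0]], bool)
    scores = np.array([[0.9, 0.8, 0.7, 0.6, 0.5, 0.4]])
    # AP = sum over positive ranks of precision@k * (1/n_pos)
    expected = (1 / 1 + 2 / 3 + 3 / 4) / 3
    assert auprc(truth, scores) == pytest.approx(expected)


def test_auprc_random_scores_approach_prevalence(rng):
    truth = rng.random((50, 100)) < 0.2
    scores = rng.random((50, 100))
    assert auprc(truth, scores) == pytest.approx(truth.mean(), abs=0.03)


# ---- concordance index ------------------------------------------------------

def brute_force_ci(y_true, y_pred):
    num = z = 0.0
    n = len(y_true)
    for i in range(n):
        for j in range(n):
            if y_true[i] > y_true[j]:
                z += 1
                if y_pred[i] > y_pred[j]:
                    num += 1
                elif y_pred[i] == y_pred[j]:
                    num += 0.5
    return num / z


def test_ci_trivial_cases():
    y = np.array([1.0, 2.0, 3.0, 4.0])
    assert concordance_index(y, np.exp(y)) == pytest.approx(1.0)  # monotone
    assert concordance_index(y, np.full(4, 7.0)) == pytest.approx(0.5)  # ties


def test_ci_matches_brute_force_and_lifelines(rng):
    for _ in range(100):
        n = int(rng.integers(5, 50))
        yt = np.round(rng.normal(size=n), 1)
        yp = np.round(rng.normal(size=n), 1)
        if np.ptp(yt) == 0:
            yt[0] += 1.0
        ours = concordance_index(yt, yp)
        assert ours == pytest.approx(brute_force_ci(yt, yp))
        assert ours == pytest.approx(lifelines_ci(yt, yp))


def test_ci_invariant_under_monotone_transform(rng):
    yt = rng.normal(size=40)
    yp = rng.normal(size=40)
    base = concordance_index(yt, yp)
    assert concordance_index(yt, 3 * yp + 2) == pytest.approx(base)
    assert concordance_index(yt, np.tanh(yp)) == pytest.approx(base)


def test_ci_rejects_degenerate_input():
    with pytest.raises(ValueError):
        concordance_index([1.0, 1.0], [0.3, 0.4])


# ---- regression suite -------------------------------------------------------

def test_regression_identity():
    y = np.array([1.0, 2.0, 3.5, 4.0, 5.5])
    rep = regression_suite(y, y)
    assert rep.rmse == pytest.approx(0.0)
    assert rep.r_squared == pytest.approx(1.0)
    assert rep.r0_squared == pytest.approx(1.0)
    assert rep.rm_squared == pytest.approx(1.0)


def test_rm_squared_equals_r_squared_when_origin_fit_matches(rng):
    # predictions proportional to truth through the origin: r0^2 = r^2 = 1
    y = np.linspace(1, 9, 12)
    rep = regression_suite(y, 2.0 * y)
    assert rep.r0_squared == pytest.approx(rep.r_squared)
    assert rep.rm_squared == pytest.approx(rep.r_squared)


def test_regression_ten_point_instance_matches_independent_fits(rng):
    yt = np.array([4.2, 5.1, 6.3, 4.8, 5.9, 7.2, 6.8, 5.5, 4.9, 6.1])
    yp = np.array([4.0, 5.4, 6.0, 5.2, 5.7, 6.9, 7.1, 5.0, 5.3, 5.8])
    rep = regression_suite(yt, yp)
    assert rep.rmse == pytest.approx(float(np.sqrt(np.mean((yt - yp) ** 2))))
    # independent through-origin fit via lstsq
    k = float(np.linalg.lstsq(yp[:, None], yt, rcond=None)[0][0])
    ss0 = float(np.sum((yt - k * yp) ** 2))
    sst = float(np.sum((yt - yt.mean()) ** 2))
    assert rep.r0_squared == pytest.approx(1 - ss0 / sst)
    r = float(np.corrcoef(yt, yp)[0, 1])
    assert rep.r_squared == pytest.approx(r * r)
    assert rep.rm_squared == pytest.approx(
        r * r * (1 - np.sqrt(max(r * r - rep.r0_squared, 0))))


def test_rm_squared_never_exceeds_r_squared(rng):
    for _ in range(50):
        yt = rng.normal(size=20)
        yp = 0.5 * yt + rng.normal(size=20)
        rep = regression_suite(yt, yp)
        assert rep.rm_squared <= rep.r_squared + 1e-12


def test_regression_rejects_degenerate():
    with pytest.raises(ValueError):
        regression_suite([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        regression_suite([1.0, 2.0], [1.0, 2.0])


# ---- adduct / position accuracy --------------------------------------------

def _targets(n=5):
    nitrile = chem.AdductSpec("[*]CC#N")
    recs = [CovalentRecord("GAC" + "G" * i, "CCO", 3, nitrile) for i in range(n)]
    return [build_adduct_example(r)[1] for r in recs]


def test_accuracy_identical_predictions():
    refs = _targets()
    assert adduct_task_accuracy(refs, refs) == (1.0, 1.0)


def test_accuracy_all_malformed():
    refs = _targets()
    preds = ["garbage"] * len(refs)
    assert adduct_task_accuracy(preds, refs) == (0.0, 0.0)


def test_accuracy_canonicalization_of_reordered_smiles():
    refs = _targets(1)
    pos, smi = 3, chem.graft_adduct("C", chem.AdductSpec("[*]CC#N")).product_smiles
    # re-express the same molecule with a different atom ordering
    from rdkit import Chem as rdchem
    mol = rdchem.MolFromSmiles(smi)
    alt = rdchem.MolToSmiles(mol, rootedAtAtom=mol.GetNumAtoms() - 1, canonical=False)
    assert alt != smi
    pred = f"GA<extra_id_99>{alt}<extra_id_98>"
    a, p = adduct_task_accuracy([pred], refs)
    assert a == 1.0 and p == 1.0


def test_accuracy_length_mismatch():
    with pytest.raises(ValueError):
        adduct_task_accuracy(["x"], _targets(2))
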