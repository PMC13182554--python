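"""Curation tests: canonicalization, keyword mapping, filters, merge, agreement."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score

from odorstrength import curation as cur


class TestCanonicalize:
    def test_equivalent_strings_coincide(self):
        assert cur.canonicalize("OCC") == cur.canonicalize("CCO")

    def test_unparseable_yields_marker(self):
        assert cur.canonicalize("C(") == cur.CANONICALIZATION_FAILED

    def test_idempotent_on_generated_set(self, small_smiles):
        for smi in small_smiles:
            once = cur.canonicalize(smi)
            assert cur.canonicalize(once) == once


class TestMapDescription:
    table = cur.KeywordTable((("odorless", 0), ("strong", 3)))

    def test_first_match_wins_and_case_insensitive(self):
        assert cur.map_description("Colorless, odorless gas.", self.table) == 0
        assert cur.map_description("has a strong pungent smell", self.table) == 3

    def test_no_keyword_gives_absent(self):
        assert cur.map_description("pleasant fruity aroma", self.table) is None

    def test_table_rejects_duplicates_and_empties(self):
        with pytest.raises(ValueError):
            cur.KeywordTable((("x", 0), ("x", 1)))
        with pytest.raises(ValueError):
            cur.KeywordTable((("", 0),))

    def test_order_decides_conflicts(self):
        t = cur.KeywordTable((("strong", 3), ("odorless", 0)))
        assert cur.map_description("strong but odorless?", t) == 3


class TestFilters:
    def _records(self):
        return cur.annotate(
            [
                cur.MoleculeRecord("CC(=O)[O-].[Na+]", "B", description="odorless"),
                cur.MoleculeRecord("CCO", "B", description="strong smell"),
                cur.MoleculeRecord("OCC", "B", description="faint smell"),  # dup canonical of CCO
                cur.MoleculeRecord("C(", "A", description="medium"),
                cur.MoleculeRecord("CCC", "A", description="very high"),
                cur.MoleculeRecord("CCCC", "B", description="no mappable words here"),
            ]
        )

    def test_filters_and_audit_conservation(self):
        records = self._records()
        retained, audit = cur.apply_filters(records)
        reasons = ["invalid_smiles", "dot_smiles", "duplicate", "unmapped_description"]
        assert audit["input"] == len(records)
        assert audit["input"] == audit["retained"] + sum(audit[r] for r in reasons)
        assert audit["dot_smiles"] == 1
        assert audit["duplicate"] == 1
        assert audit["invalid_smiles"] == 1
        assert audit["unmapped_description"] == 1
        assert {r.smiles_canonical for r in retained} == {"CCO", "CCC"}

    def test_very_high_reclassified_to_high_with_flag(self):
        retained, audit = cur.apply_filters(self._records())
        rec = next(r for r in retained if r.smiles_canonical == "CCC")
        assert rec.strength == 3
        assert "reclassified_very_high" in rec.audit_flags
        assert audit["reclassified_very_high"] == 1

    def test_filter_idempotence(self):
        retained, _ = cur.apply_filters(self._records())
        again, audit2 = cur.apply_filters(retained)
        assert [r.smiles_canonical for r in again] == [r.smiles_canonical for r in retained]
        assert audit2["retained"] == audit2["input"]

    def test_duplicates_removed_only_within_source_b(self):
        recs = cur.annotate(
            [
                cur.MoleculeRecord("CCO", "A", description="medium"),
                cur.MoleculeRecord("OCC", "A", description="high"),
            ]
        )
        retained, _ = cur.apply_filters(recs)
        assert len(retained) == 2  # cross-source/same-source-A dupes resolved at merge


class TestMerge:
    def _rec(self, smi, source, strength):
        r = cur.MoleculeRecord(smi, source, strength=strength)
        r.smiles_canonical = cur.canonicalize(smi)
        return r

    def test_precedence_rule_and_overlap_table(self):
        merged, overlap = cur.merge_sources(
            [self._rec("CCO", "A", 2)], [self._rec("CCO", "B", 3)], precedence="A"
        )
        assert len(merged) == 1 and merged[0].strength == 2
        assert overlap == [(2, 3)]

    def test_disjoint_union(self):
        merged, overlap = cur.merge_sources(
            [self._rec("CCO", "A", 2)], [self._rec("CCC", "B", 1)]
        )
        assert len(merged) == 2 and overlap == []

    def test_empty_side_identity(self):
        merged, _ = cur.merge_sources([], [self._rec("CCC", "B", 1)])
        assert len(merged) == 1 and merged[0].strength == 1


class TestKappa:
    def test_perfect_agreement(self):
        assert cur.quadratic_weighted_kappa([(0, 0), (1, 1), (2, 2), (3, 3)]) == pytest.approx(1.0)

    def test_maximal_weighted_disagreement(self):
        # observed weighted disagreement 1, expected 0.5 -> kappa = -1
        assert cur.quadratic_weighted_kappa([(0, 3), (0, 3), (3, 0), (3, 0)]) == pytest.approx(-1.0)

    def test_matches_sklearn_on_random_instances(self, rng):
        for _ in range(200):
            n = int(rng.integers(5, 40))
            a = rng.integers(0, 4, size=n)
            b = rng.integers(0, 4, size=n)
            if len(set(a.tolist()) | set(b.tolist())) < 2:
                continue
            ours = cur.quadratic_weighted_kappa(list(zip(a, b)))
            ref = cohen_kappa_score(a, b, labels=[0, 1, 2, 3], weights="quadratic")
            assert ours == pytest.approx(ref, abs=1e-10)

    def test_symmetry(self, rng):
        a = rng.integers(0, 4, size=50)
        b = rng.integers(0, 4, size=50)
        assert cur.quadratic_weighted_kappa(list(zip(a, b))) == pytest.approx(
            cur.quadratic_weighted_kappa(list(zip(b, a)))
        )

    def test_degenerate_all_one_category(self):
        rep = cur.agreement([(2, 2), (2, 2)])
        assert np.isnan(rep.kappa_quadratic)
        assert rep.degenerate


def _alpha_bruteforce(table):
    """Independent ordinal-alpha oracle by explicit pairable-pair enumeration."""
    table = np.asarray(table, dtype=float)
    pairs = []  # all ordered pairs of values within a unit, weighted 1/(m-1)
    weights = []
    for unit in table:
        vals = unit[np.isfinite(unit)]
        m = len(vals)
        if m < 2:
            continue
        for i, j in itertools.permutations(range(m), 2):
            pairs.append((vals[i], vals[j]))
            weights.append(1.0 / (m - 1))
    if not pairs:
        return float("nan")
    pairs, weights = np.asarray(pairs), np.asarray(weights)
    values = np.unique(pairs)
    marg = {v: weights[(pairs[:, 0] == v)].sum() for v in values}

    def delta2(c, k):
        lo, hi = min(c, k), max(c, k)
        span = sum(marg[v] for v in values if lo <= v <= hi)
        return (span - (marg[c] + marg[k]) / 2.0) ** 2

    n = weights.sum()
    d_obs = sum(w * delta2(a, b) for (a, b), w in zip(pairs, weights)) / n
    d_exp = sum(
        marg[c] * marg[k] * delta2(c, k) for c in values for k in values if c != k
    ) / (n * (n - 1))
    return 1.0 - d_obs / d_exp if d_exp > 0 else float("nan")


class TestKrippendorffAlpha:
    def test_three_item_table_matches_bruteforce(self):
        table = np.array([[0, 0], [1, 1], [2, 3]], dtype=float)
        ours = cur.krippendorff_alpha_ordinal(table)
        assert ours == pytest.approx(_alpha_bruteforce(table), abs=1e-12)

    def test_random_tables_with_missing_match_bruteforce(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 25))
            table = rng.integers(0, 4, size=(n, 2)).astype(float)
            miss = rng.random(table.shape) < 0.2
            table[miss] = np.nan
            ours = cur.krippendorff_alpha_ordinal(table)
            ref = _alpha_bruteforce(table)
            if np.isnan(ref):
                assert np.isnan(ours)
            else:
                assert ours == pytest.approx(ref, abs=1e-10)

    def test_perfect_agreement_gives_one(self):
        table = np.array([[0, 0], [1, 1], [2, 2], [3, 3], [1, 1]], dtype=float)
        assert cur.krippendorff_alpha_ordinal(table) == pytest.approx(1.0)


def test_agreement_decreases_with_label_noise():
    """Both chance-corrected coefficients fall as generator label noise rises."""
    from odorstrength import synthetic

    kappas, alphas = [], []
    for noise in (0.0, 0.15, 0.3):
        cfg = synthetic.GeneratorConfig(
            n_molecules=500, seed=17, label_noise=noise, overlap_fraction=1.0, steer_sources=False
        )
        records, _ = synthetic.generate_dataset(cfg)
        merged, audit, rep = cur.curate(records)
        kappas.append(rep.kappa_quadratic)
        alphas.append(rep.krippendorff_alpha)
    assert kappas[0] == pytest.approx(1.0) and alphas[0] == pytest.approx(1.0)
    assert kappas[0] > kappas[1] > kappas[2]
    assert alphas[0] > alphas[1] > alphas[2]
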