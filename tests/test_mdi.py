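"""MDI computation: the discrimination equation, state averaging, exclusion
and breadth rules, and equivalence to a naive reference implementation."""

import numpy as np
import pandas as pd
import pytest

from modrank.io import GeneModule, ModuleCollection
from modrank.mdi import (
    cell_type_mean_scores,
    check_breadth,
    dataset_mdi_term,
    mdi_score,
)

from .conftest import make_dataset, make_matrix


def one_gene_dataset(name, sample_scores, states=None):
    """Dataset whose single gene row makes module scores equal the raw values."""
    spec = [(sid, ct) for sid, ct, _ in sample_scores]
    values = [[v for _, _, v in sample_scores]]
    return make_dataset(name, ["g1"], spec, values, states=states)


MOD = ModuleCollection((GeneModule("M", frozenset({"g1"}), target_cell="T"),))


class TestDatasetTerm:
    def test_direct_substitution(self):
        assert dataset_mdi_term(8.0, [4.0, 4.0, 4.0]) == pytest.approx(0.5, abs=1e-12)

    def test_zero_discrimination_fixed_point(self):
        assert dataset_mdi_term(5.0, [5.0]) == 0.0

    def test_equal_weight_per_cell_type(self):
        # Y = mean(2, 10) = 6 = X, not the pooled-sample mean
        assert dataset_mdi_term(6.0, [2.0, 10.0]) == pytest.approx(0.0, abs=1e-12)

    def test_x_zero_is_undefined(self):
        with pytest.raises(ZeroDivisionError):
            dataset_mdi_term(0.0, [1.0])

    def test_monotone_in_x(self):
        terms = [dataset_mdi_term(x, [3.0, 5.0]) for x in (4.0, 6.0, 9.0)]
        assert terms == sorted(terms)
        assert terms[0] < terms[1] < terms[2]


class TestStateAveraging:
    def test_target_states_averaged_equal_weight(self):
        d = one_gene_dataset(
            "d",
            [("s1", "T", 4.0), ("s2", "T", 6.0), ("s3", "T", 10.0), ("s4", "B", 1.0)],
            states=["resting", "resting", "activated", ""],
        )
        means = cell_type_mean_scores(d, MOD, "T")[0]
        # state means 5 and 10, averaged to 7.5 (not the pooled 20/3)
        assert means.target_mean == pytest.approx(7.5, abs=1e-12)

    def test_single_state_plain_mean(self):
        d = one_gene_dataset("d", [("s1", "T", 3.0), ("s2", "T", 5.0), ("s3", "B", 1.0)])
        assert cell_type_mean_scores(d, MOD, "T")[0].target_mean == pytest.approx(4.0)

    def test_nontarget_conditions_not_collapsed(self):
        d = one_gene_dataset(
            "d",
            [("s1", "T", 9.0), ("s2", "B", 2.0), ("s3", "B", 6.0)],
            states=["", "naive", "memory"],
        )
        means = cell_type_mean_scores(d, MOD, "T")[0]
        assert means.other_means == {"B/naive": 2.0, "B/memory": 6.0}

    def test_absent_target_errors_with_available_labels(self):
        d = one_gene_dataset("d", [("s1", "T", 1.0), ("s2", "B", 2.0)])
        with pytest.raises(ValueError, match="available"):
            cell_type_mean_scores(d, MOD, "NK")


class TestMdiScore:
    def test_mean_of_two_dataset_terms(self):
        d1 = one_gene_dataset("d1", [("a", "T", 8.0), ("b", "B", 4.0)])  # term 0.5
        d2 = one_gene_dataset("d2", [("c", "T", 10.0), ("d", "B", 9.0)])  # term 0.1
        (res,) = mdi_score([d1, d2], MOD, {})
        assert res.mdi == pytest.approx(0.3, abs=1e-12)
        assert res.n_datasets == 2 and not res.excluded

    def test_single_dataset(self):
        d = one_gene_dataset("d", [("a", "T", 10.0), ("b", "B", 5.0)])
        (res,) = mdi_score([d], MOD, {})
        assert res.mdi == pytest.approx(0.5, abs=1e-12)
        assert res.n_datasets == 1

    def test_exclusion_when_target_below_any_cell_type(self):
        d = one_gene_dataset("d", [("a", "T", 5.0), ("b", "B", 6.0), ("c", "NK", 1.0)])
        (res,) = mdi_score([d], MOD, {})
        assert res.excluded and res.mdi is None
        assert "B" in res.exclusion_reason

    def test_no_usable_dataset(self):
        d = one_gene_dataset("d", [("a", "B", 1.0), ("b", "NK", 2.0)])
        (res,) = mdi_score([d], MOD, {})
        assert res.excluded and res.n_datasets == 0
        assert res.exclusion_reason == "no usable dataset"

    def test_pool_samples_option_weights_by_count(self):
        # one B sample at 2, three NK samples at 10:
        # equal-weight Y = 6 -> term 0; pooled Y = 8 -> term -1/3
        d = one_gene_dataset(
            "d",
            [("a", "T", 6.0), ("b", "B", 2.0)]
            + [(f"n{i}", "NK", 10.0) for i in range(3)],
        )
        (eq,) = mdi_score([d], MOD, {})
        assert eq.excluded  # target 6 < NK 10 -> exclusion fires
        assert eq.components[0]["term"] == pytest.approx(0.0, abs=1e-12)
        (pooled,) = mdi_score([d], MOD, {}, pool_samples=True)
        assert pooled.components[0]["term"] == pytest.approx(-1 / 3, abs=1e-12)

    def test_label_harmonization_merges_target_labels(self):
        d1 = one_gene_dataset("d1", [("a", "naive B", 8.0), ("b", "T", 4.0)])
        d2 = one_gene_dataset("d2", [("c", "B cells", 8.0), ("d", "T", 4.0)])
        mod = ModuleCollection((GeneModule("M", frozenset({"g1"}), target_cell="B"),))
        label_map = {"naive B": "B", "B cells": "B"}
        (res,) = mdi_score([d1, d2], mod, {}, label_map=label_map)
        assert res.n_datasets == 2
        assert res.mdi == pytest.approx(0.5, abs=1e-12)

    def test_translation_changes_terms_on_log_scale(self):
        d = one_gene_dataset("d", [("a", "T", 8.0), ("b", "B", 4.0)])
        d_shift = one_gene_dataset("d", [("a", "T", 10.0), ("b", "B", 6.0)])
        (r0,) = mdi_score([d], MOD, {})
        (r1,) = mdi_score([d_shift], MOD, {})
        assert r0.mdi != pytest.approx(r1.mdi)

    def test_linear_scale_invariant_to_multiplicative_rescaling(self):
        # multiplying linear expression by k adds log2(k) to every log2 value
        d = one_gene_dataset("d", [("a", "T", 8.0), ("b", "B", 4.0)])
        d_scaled = one_gene_dataset("d", [("a", "T", 11.0), ("b", "B", 7.0)])
        (r0,) = mdi_score([d], MOD, {}, linear_scale=True)
        (r1,) = mdi_score([d_scaled], MOD, {}, linear_scale=True)
        assert r0.mdi == pytest.approx(r1.mdi, abs=1e-12)

    def test_identical_target_and_nontarget_means_give_zero(self):
        d1 = one_gene_dataset("d1", [("a", "T", 5.0), ("b", "B", 5.0), ("c", "NK", 5.0)])
        d2 = one_gene_dataset("d2", [("d", "T", 5.0), ("e", "B", 5.0)])
        (res,) = mdi_score([d1, d2], MOD, {})
        assert res.mdi == 0.0


class TestBreadth:
    def _dataset(self, n_target, other_types, n_per_other=1):
        spec = [(f"t{i}", "T") for i in range(n_target)]
        for ct in other_types:
            spec += [(f"{ct}{i}", ct) for i in range(n_per_other)]
        values = [[1.0] * len(spec)]
        return make_dataset("d", ["g1"], spec, values)

    def test_breadth_ok(self):
        d = self._dataset(2, ["B", "NK", "Mono", "Neut", "DC"], n_per_other=4)
        rep = check_breadth(d, "T")
        assert rep.breadth_ok
        assert rep.n_nontarget_types == 5
        assert rep.target_fraction == pytest.approx(2 / 22)

    def test_too_few_nontarget_types(self):
        d = self._dataset(1, ["B", "NK", "Mono"])
        assert not check_breadth(d, "T").breadth_ok

    def test_target_fraction_at_20_percent_fails(self):
        d = self._dataset(5, ["B", "NK", "Mono", "Neut", "DC"], n_per_other=3)
        rep = check_breadth(d, "T")
        assert rep.target_fraction == pytest.approx(0.25)
        assert not rep.breadth_ok

    def test_strict_breadth_drops_failing_dataset(self):
        shallow = one_gene_dataset("shallow", [("a", "T", 8.0), ("b", "B", 4.0)])
        (res,) = mdi_score([shallow], MOD, {}, strict_breadth=True)
        assert res.excluded and res.exclusion_reason == "no usable dataset"


def naive_mdi(datasets, modules, min_coverage=0.5):
    """Reference implementation: explicit loops over datasets, cell types, samples."""
    out = {}
    for mod in modules:
        per_ds = []
        for d in datasets:
            present = sorted(g for g in mod.genes if g in d.matrix.data.index)
            if len(present) / len(mod.genes) < min_coverage:
                continue
            ann = d.annotation
            cts = sorted(set(ann["cell_type"]))
            if mod.target_cell not in cts:
                continue
            scores = {}
            for s in d.matrix.sample_ids:
                scores[s] = sum(d.matrix.data.loc[g, s] for g in present) / len(present)
            target_samples = [s for s in d.matrix.sample_ids
                              if ann.loc[s, "cell_type"] == mod.target_cell]
            x = sum(scores[s] for s in target_samples) / len(target_samples)
            others = {}
            for ct in cts:
                if ct == mod.target_cell:
                    continue
                ids = [s for s in d.matrix.sample_ids if ann.loc[s, "cell_type"] == ct]
                others[ct] = sum(scores[s] for s in ids) / len(ids)
            per_ds.append((x, others))
        if not per_ds:
            out[mod.name] = None
            continue
        cross_target = sum(x for x, _ in per_ds) / len(per_ds)
        cross = {}
        for _, o in per_ds:
            for ct, v in o.items():
                cross.setdefault(ct, []).append(v)
        if any(cross_target < sum(v) / len(v) for v in cross.values()):
            out[mod.name] = None
            continue
        terms = [(x - sum(o.values()) / len(o)) / x for x, o in per_ds]
        out[mod.name] = sum(terms) / len(terms)
    return out


def test_oracle_equivalence_on_random_instances():
    rng = np.random.default_rng(42)
    for trial in range(10):
        genes = [f"g{i}" for i in range(30)]
        cts = ["T", "B", "NK"]
        datasets = []
        for k in range(2):
            spec = [(f"d{k}s{j}_{ct}", ct) for ct in cts for j in range(3)]
            vals = rng.normal(8, 1, (30, len(spec)))
            datasets.append(make_dataset(f"d{k}", genes, spec, vals))
        mods = ModuleCollection(
            tuple(
                GeneModule(
                    f"M{j}",
                    frozenset(rng.choice(genes, 5, replace=False)),
                    target_cell=rng.choice(cts),
                )
                for j in range(4)
            )
        )
        expected = naive_mdi(datasets, mods)
        results = {r.module_name: r.mdi for r in mdi_score(datasets, mods, {})}
        for name, exp in expected.items():
            if exp is None:
                assert results[name] is None
            else:
                assert results[name] == pytest.approx(exp, abs=1e-12)
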