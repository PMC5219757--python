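import numpy as np
import pandas as pd
import pytest

from cobind.regions import build_cobinding_regions, build_region_tf_matrix
from cobind.synthetic import (
    GroundTruth,
    SyntheticConfig,
    generate,
    score_recovery,
)
from cobind.topic_model import ModuleTFMatrix


class TestConfigValidation:
    def test_defaults_valid(self):
        SyntheticConfig().validate()

    def test_spacing_too_small(self):
        with pytest.raises(ValueError, match="spacing"):
            SyntheticConfig(anchor_spacing=200).validate()

    def test_too_many_split_factors(self):
        split = {f"TF{i:02d}": 1.0 for i in range(1, 28)}
        with pytest.raises(ValueError, match="pools"):
            SyntheticConfig(split_factors=split).validate()

    def test_bad_divergence(self):
        with pytest.raises(ValueError, match="divergence"):
            SyntheticConfig(split_factors={"TF01": 1.5}).validate()

    def test_unknown_celltype_bias(self):
        with pytest.raises(ValueError, match="cell type"):
            SyntheticConfig(celltype_bias={"nope": [1.0] * 6}).validate()

    def test_bad_module_probs(self):
        with pytest.raises(ValueError, match="module_probs"):
            generate(SyntheticConfig(n_regions=2, module_probs=[1.0]))


class TestGenerate:
    def test_planted_regions_recovered_exactly(self, small_dataset):
        ds = small_dataset
        regions = build_cobinding_regions(ds.calls, expand_bp=50, min_sites=3)
        assert len(regions) == ds.truth.n_regions
        for region, anchor in zip(regions, ds.truth.region_anchor):
            assert region.start <= anchor <= region.end

    def test_zero_multi_fraction_single_labels(self):
        ds = generate(SyntheticConfig(n_regions=50, multi_module_fraction=0.0, seed=1))
        for mods, labels in zip(ds.truth.region_modules, ds.truth.token_labels):
            assert len(mods) == 1
            assert set(labels) == {mods[0]}

    def test_same_seed_identical(self):
        a = generate(SyntheticConfig(n_regions=40, seed=9))
        b = generate(SyntheticConfig(n_regions=40, seed=9))
        assert a.calls == b.calls
        assert np.array_equal(a.truth.phi, b.truth.phi)

    def test_site_count_conserved(self, small_dataset):
        ds = small_dataset
        assert len(ds.calls) == ds.truth.n_sites
        assert ds.truth.n_sites == sum(
            sum(c.values()) for c in ds.truth.region_module_counts
        )

    def test_phi_rows_normalized(self, small_dataset):
        assert np.allclose(small_dataset.truth.phi.sum(axis=1), 1.0)

    def test_multi_module_fraction_close(self):
        ds = generate(SyntheticConfig(n_regions=2000, seed=3))
        frac = np.mean([len(m) > 1 for m in ds.truth.region_modules])
        assert abs(frac - 0.2) < 0.03

    def test_annotations_emitted(self):
        ds = generate(SyntheticConfig(n_regions=60, seed=2, emit_annotations=True))
        assert len(ds.annotations) == 6
        planted = {
            k: {r for r, mods in enumerate(ds.truth.region_modules) if k in mods}
            for k in range(6)
        }
        # tracks should mostly cover regions planted with their module
        for k, track in enumerate(ds.annotations):
            if not planted[k]:
                continue
            spans = set(track.intervals)
            hits = sum(ds.truth.region_span[r] in spans for r in planted[k])
            assert hits / len(planted[k]) > 0.6


class TestDirectIndirectGeneration:
    split = {f"TF{i:02d}": 1.0 for i in range(26, 31)}

    def test_motif_flags_by_variant(self):
        ds = generate(
            SyntheticConfig(
                n_regions=200,
                split_factors=self.split,
                split_factor_weight=0.2,
                partner_pool_size=2,
                multi_module_fraction=0.0,
                seed=4,
            )
        )
        flagged = [c for c in ds.calls if c.factor in self.split]
        assert flagged
        assert all(c.motif_present is not None for c in flagged)
        others = [c for c in ds.calls if c.factor not in self.split]
        assert all(c.motif_present is None for c in others)

    def test_full_divergence_disjoint_partners(self):
        ds = generate(
            SyntheticConfig(
                n_regions=400,
                split_factors=self.split,
                split_factor_weight=0.2,
                partner_pool_size=2,
                multi_module_fraction=0.0,
                seed=4,
            )
        )
        vocab = ds.truth.vocabulary
        for f in self.split:
            k_d = ds.truth.module_names.index(f"direct_{f}")
            k_i = ds.truth.module_names.index(f"indirect_{f}")
            partners_d = {
                vocab[j] for j in np.flatnonzero(ds.truth.phi[k_d]) if vocab[j] != f"d{f}"
            }
            partners_i = {
                vocab[j] for j in np.flatnonzero(ds.truth.phi[k_i]) if vocab[j] != f"i{f}"
            }
            assert partners_d and partners_i
            assert not partners_d & partners_i


class TestCellTypes:
    def test_biased_usage(self):
        bias = {"cellA": [1.0] * 5 + [0.05], "cellB": [0.05] * 5 + [1.0]}
        ds = generate(
            SyntheticConfig(
                n_regions=1000,
                cell_types=("cellA", "cellB"),
                celltype_bias=bias,
                multi_module_fraction=0.0,
                seed=6,
            )
        )
        mod5_types = [
            ct
            for ct, mods in zip(ds.truth.region_cell_type, ds.truth.region_modules)
            if 5 in mods
        ]
        assert len(mod5_types) > 10
        assert np.mean([ct == "cellB" for ct in mod5_types]) > 0.8

    def test_calls_carry_cell_type(self):
        ds = generate(SyntheticConfig(n_regions=30, cell_types=("a", "b"), seed=1))
        assert {c.cell_type for c in ds.calls} == {"a", "b"}


class TestScoreRecovery:
    def perfect_inputs(self, ds):
        truth = ds.truth
        K = truth.phi.shape[0]
        V = len(truth.vocabulary)
        counts = np.zeros((K, V), dtype=np.int64)
        records = []
        for r, (words, labels) in enumerate(zip(truth.token_words, truth.token_labels)):
            for i, (w, k) in enumerate(zip(words, labels)):
                counts[k, w] += 1
                records.append((f"r{r}", i, truth.vocabulary[w], int(k)))
        mtm = ModuleTFMatrix(counts=counts, factors=list(truth.vocabulary))
        table = pd.DataFrame(
            records, columns=["region_id", "site_index", "factor", "module"]
        )
        return mtm, table

    def test_perfect_recovery(self, small_dataset):
        mtm, table = self.perfect_inputs(small_dataset)
        rec = score_recovery(small_dataset.truth, mtm, table)
        assert rec.token_accuracy == pytest.approx(1.0)
        assert rec.mean_cosine > 0.99

    def test_relabeling_invariance(self, small_dataset):
        mtm, table = self.perfect_inputs(small_dataset)
        K = mtm.counts.shape[0]
        rng = np.random.default_rng(0)
        perm = rng.permutation(K)
        mtm2 = ModuleTFMatrix(counts=mtm.counts[perm], factors=mtm.factors)
        relabel = np.argsort(perm)
        table2 = table.assign(module=relabel[table["module"].to_numpy()])
        a = score_recovery(small_dataset.truth, mtm, table)
        b = score_recovery(small_dataset.truth, mtm2, table2)
        assert a.mean_cosine == pytest.approx(b.mean_cosine)
        assert a.token_accuracy == pytest.approx(b.token_accuracy)

    def test_random_assignment_chance_level(self, small_dataset):
        truth = small_dataset.truth
        rng = np.random.default_rng(1)
        K = truth.phi.shape[0]
        mtm, table = self.perfect_inputs(small_dataset)
        table = table.assign(module=rng.integers(0, K, size=len(table)))
        counts = np.zeros_like(mtm.counts)
        vidx = {w: i for i, w in enumerate(truth.vocabulary)}
        for f, k in zip(table["factor"], table["module"]):
            counts[k, vidx[f]] += 1
        rec = score_recovery(truth, ModuleTFMatrix(counts=counts, factors=mtm.factors), table)
        assert abs(rec.token_accuracy - 1 / K) < 0.1

    def test_vocabulary_mismatch_error(self, small_dataset):
        mtm, table = self.perfect_inputs(small_dataset)
        bad = ModuleTFMatrix(counts=mtm.counts, factors=["x"] * len(mtm.factors))
        with pytest.raises(ValueError):
            score_recovery(small_dataset.truth, bad, table)
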